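"""Raster containers and plain-text grid I/O.

All spatial data in this package live on a single rectangular fine grid of
square cells, indexed ``[row, col]`` with row 0 at the southern edge.  The
:class:`EnvStack` bundles the co-registered environmental layers (climate and
topography) that the species distribution models consume.  Rasters are stored
on disk as headered ESRI ASCII grids so every artefact is plain text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: canonical layer names, with units
LAYER_UNITS = {
    "elevation": "m",
    "slope": "degrees",
    "aspect": "degrees",
    "northness": "dimensionless",
    "annual_mean_temp": "degC",
    "temp_seasonality": "degC",
    "temp_warmest_q": "degC",
    "temp_coldest_q": "degC",
    "annual_precip": "mm",
    "precip_wettest_q": "mm",
    "precip_driest_q": "mm",
}


@dataclass
class EnvStack:
    """Co-registered environmental raster layers on the fine analysis grid.

    Parameters
    ----------
    cell_area : float
        Area of one fine cell in km^2 (default 0.1, i.e. ~316 m cell side).
    layers : dict[str, np.ndarray]
        Named 2-D float arrays, all with identical shape.
    """

    cell_area: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers differ in shape: {shapes}")
        if "elevation" in self.layers and np.any(self.layers["elevation"] < 0):
            raise ValueError("elevation must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_side_km(self) -> float:
        return math.sqrt(self.cell_area)

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"environmental layer not found: {name!r}") from None

    def predictor_matrix(self, rows, cols, names=None) -> np.ndarray:
        """Extract an (n_sites, p) predictor matrix at grid positions."""
        names = list(names) if names is not None else list(self.layers)
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.cell_side_km)
        manifest = {
            "cell_area_km2": self.cell_area,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "layers": {n: LAYER_UNITS.get(n, "") for n in self.layers},
        }
        (directory / "envstack.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnvStack":
        directory = Path(directory)
        manifest = json.loads((directory / "envstack.json").read_text())
        layers = {
            name: read_ascii_grid(directory / f"{name}.asc")[0]
            for name in manifest["layers"]
        }
        return cls(cell_area=manifest["cell_area_km2"], layers=layers)


def write_ascii_grid(
    path: str | Path, array: np.ndarray, cellsize: float, nodata: float = -9999.0
) -> None:
    """Write a 2-D array as a headered ESRI ASCII grid (row 0 = north row)."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise ValueError("ASCII grids are 2-D")
    nrows, ncols = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        # our row 0 is south; ASC stores north row first
        for row in array[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array with row 0 = south, cellsize)."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"not an ASCII grid: {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array(" ".join(lines[body_start:]).split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"ASCII grid {path}: expected {nrows * ncols} values, got {values.size}"
        )
    array = values.reshape(nrows, ncols)[::-1]  # back to row 0 = south
    return array, header.get("cellsize", 1.0)
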
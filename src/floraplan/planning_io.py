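"""Planning units, amount matrices, targets, and Marxan-format file I/O.

Reserve selection runs on a coarse lattice of square planning units (PUs)
laid over the fine analysis grid: each PU is an f x f block of fine cells.
Species "amounts" are the km^2 of each species' binary range inside each PU.
Problems round-trip through the four classic Marxan 2.43 planning files
(pu.dat, spec.dat, puvspr.dat, bound.dat) so external reserve-selection
software can consume them.

Status codes follow Marxan: 0 = available, 2 = locked into every solution,
3 = locked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack

STATUS_AVAILABLE = 0
STATUS_LOCKED_IN = 2
STATUS_LOCKED_OUT = 3
_ALLOWED_STATUS = {STATUS_AVAILABLE, STATUS_LOCKED_IN, STATUS_LOCKED_OUT}


@dataclass
class PlanningGrid:
    """A rectangular lattice of uniform square planning units.

    PU ids are 1-based, row-major from the south-west corner.  The boundary
    list holds one row per rook-adjacent pair (id1 < id2) with the shared
    edge length, plus self-pairs (id1 == id2) carrying each PU's exposed
    landscape-edge length.
    """

    n_rows: int
    n_cols: int
    pu_side_km: float
    cost: np.ndarray
    status: np.ndarray
    boundary_id1: np.ndarray = field(default=None)
    boundary_id2: np.ndarray = field(default=None)
    boundary_len: np.ndarray = field(default=None)
    include_exposure: bool = True

    def __post_init__(self) -> None:
        n = self.n_pu
        if self.cost is None:
            self.cost = np.full(n, self.pu_area_km2)
        if self.status is None:
            self.status = np.zeros(n, dtype=int)
        self.cost = np.asarray(self.cost, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.cost.size != n or self.status.size != n:
            raise ValueError("cost/status length must equal the PU count")
        if not set(np.unique(self.status)).issubset(_ALLOWED_STATUS):
            raise ValueError(f"status codes must be from {_ALLOWED_STATUS}")
        if self.boundary_id1 is None:
            self._build_boundary()
        if np.any(self.boundary_len <= 0):
            raise ValueError("boundary lengths must be positive")

    @property
    def n_pu(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pu_area_km2(self) -> float:
        return self.pu_side_km**2

    @property
    def pu_ids(self) -> np.ndarray:
        return np.arange(1, self.n_pu + 1)

    def _build_boundary(self) -> None:
        rows = build_boundary_list(
            self.n_rows, self.n_cols, self.pu_side_km, self.include_exposure
        )
        self.boundary_id1 = rows[:, 0].astype(int)
        self.boundary_id2 = rows[:, 1].astype(int)
        self.boundary_len = rows[:, 2].astype(float)


def build_boundary_list(
    n_rows: int, n_cols: int, side_km: float, include_exposure: bool = True
) -> np.ndarray:
    """Boundary rows (id1, id2, length_km) for a full PU lattice.

    Rook adjacency only: each internal pair shares one edge of length
    ``side_km``; corner contacts share no edge and contribute nothing.
    Landscape-edge exposure is emitted as id1 == id2 self-pairs.
    """
    rows = []
    def pid(r, c):
        return r * n_cols + c + 1

    for r in range(n_rows):
        for c in range(n_cols):
            a = pid(r, c)
            if c + 1 < n_cols:
                rows.append((a, pid(r, c + 1), side_km))
            if r + 1 < n_rows:
                rows.append((a, pid(r + 1, c), side_km))
            if include_exposure:
                exposed = (r == 0) + (r == n_rows - 1) + (c == 0) + (c == n_cols - 1)
                if exposed:
                    rows.append((a, a, exposed * side_km))
    return np.array(rows, dtype=float).reshape(-1, 3)


@dataclass
class AmountMatrix:
    """Per-(species, PU) range amounts in km^2, stored as fine-cell counts.

    Keeping integer cell counts makes the bookkeeping identity
    sum_u amount(s, u) == range_area(s) exact in count arithmetic.
    """

    species_ids: list[str]
    cell_counts: np.ndarray   # (S, n_pu) int
    cell_area: float

    @property
    def amounts(self) -> np.ndarray:
        return self.cell_counts * self.cell_area

    @property
    def range_area_km2(self) -> np.ndarray:
        return self.cell_counts.sum(axis=1) * self.cell_area

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


def aggregate_to_planning_units(
    ranges: dict[str, "np.ndarray | object"],
    env: EnvStack,
    pu_side_cells: int,
    cost: np.ndarray | None = None,
) -> tuple[AmountMatrix, PlanningGrid]:
    """Aggregate fine-grid binary ranges onto f x f planning-unit blocks.

    ``ranges`` maps species id to a boolean raster (or an object with a
    ``mask`` attribute).  The fine grid must tile exactly into PU blocks.
    PU cost defaults to PU area (a uniform cost surface).
    """
    if pu_side_cells < 1:
        raise ValueError("pu_side_cells must be >= 1")
    n_rows, n_cols = env.shape
    if n_rows % pu_side_cells or n_cols % pu_side_cells:
        raise ValueError(
            f"grid {n_rows}x{n_cols} does not tile into {pu_side_cells}-cell PU blocks"
        )
    pr, pc = n_rows // pu_side_cells, n_cols // pu_side_cells
    species_ids = list(ranges)
    counts = np.zeros((len(species_ids), pr * pc), dtype=int)
    for i, sp in enumerate(species_ids):
        mask = getattr(ranges[sp], "mask", ranges[sp])
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_rows, n_cols):
            raise ValueError(f"range mask for {sp} is not on the fine grid")
        blocks = mask.reshape(pr, pu_side_cells, pc, pu_side_cells)
        counts[i] = blocks.sum(axis=(1, 3)).ravel()
    side_km = pu_side_cells * env.cell_side_km
    grid = PlanningGrid(
        n_rows=pr, n_cols=pc, pu_side_km=side_km, cost=cost, status=None
    )
    amounts = AmountMatrix(
        species_ids=species_ids, cell_counts=counts, cell_area=env.cell_area
    )
    return amounts, grid


def pa_coverage_fraction(pa_mask: np.ndarray, pu_side_cells: int) -> np.ndarray:
    """Fraction of each PU's fine cells covered by the PA mask (flat, row-major)."""
    n_rows, n_cols = pa_mask.shape
    if n_rows % pu_side_cells or n_cols % pu_side_cells:
        raise ValueError("PA mask does not tile into PU blocks")
    pr, pc = n_rows // pu_side_cells, n_cols // pu_side_cells
    blocks = pa_mask.reshape(pr, pu_side_cells, pc, pu_side_cells)
    return blocks.mean(axis=(1, 3)).ravel()


def mark_status(
    grid: PlanningGrid,
    pa_mask: np.ndarray | None,
    mode: str,
    pu_side_cells: int | None = None,
    coverage_cutoff: float = 0.5,
) -> PlanningGrid:
    """Set PU statuses: 'lock_in' locks PUs with PA coverage >= cutoff; 'free'
    leaves every PU available.  Returns a new grid; the input is not changed."""
    if mode not in {"lock_in", "free"}:
        raise ValueError("mode must be 'lock_in' or 'free'")
    status = np.zeros(grid.n_pu, dtype=int)
    if mode == "lock_in":
        if pa_mask is None or pu_side_cells is None:
            raise ValueError("lock_in mode needs pa_mask and pu_side_cells")
        frac = pa_coverage_fraction(np.asarray(pa_mask, dtype=bool), pu_side_cells)
        status[frac >= coverage_cutoff] = STATUS_LOCKED_IN
    return PlanningGrid(
        n_rows=grid.n_rows,
        n_cols=grid.n_cols,
        pu_side_km=grid.pu_side_km,
        cost=grid.cost.copy(),
        status=status,
        boundary_id1=grid.boundary_id1,
        boundary_id2=grid.boundary_id2,
        boundary_len=grid.boundary_len,
        include_exposure=grid.include_exposure,
    )


@dataclass
class TargetSpec:
    """Per-species representation targets (proportion of range) and penalties."""

    prop: np.ndarray   # (S,) in [0, 1]
    spf: np.ndarray    # (S,) > 0

    def __post_init__(self) -> None:
        self.prop = np.asarray(self.prop, dtype=float)
        self.spf = np.asarray(self.spf, dtype=float)
        if np.any((self.prop < 0) | (self.prop > 1)):
            raise ValueError("target proportions must lie in [0, 1]")
        if np.any(self.spf <= 0):
            raise ValueError("species penalty factors must be positive")

    @classmethod
    def uniform(cls, n_species: int, p: float, spf: float = 100.0) -> "TargetSpec":
        return cls(prop=np.full(n_species, p), spf=np.full(n_species, spf))

    @classmethod
    def tiered(
        cls,
        group_flags: list[frozenset],
        endangered: float = 0.5,
        endemic_bio: float = 0.3,
        other: float = 0.1,
        spf: float = 100.0,
    ) -> "TargetSpec":
        """Tiered targets: endangered > endemic/biological-resource > other."""
        prop = []
        for flags in group_flags:
            if "endangered" in flags:
                prop.append(endangered)
            elif flags & {"endemic", "bio_resource"}:
                prop.append(endemic_bio)
            else:
                prop.append(other)
        return cls(prop=np.array(prop), spf=np.full(len(prop), spf))


@dataclass
class ConservationProblem:
    """A complete reserve-selection instance."""

    grid: PlanningGrid
    amounts: AmountMatrix
    targets: TargetSpec
    blm: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.blm) or self.blm < 0:
            raise ValueError("BLM must be finite and non-negative")
        if self.targets.prop.size != self.amounts.n_species:
            raise ValueError("targets and amounts disagree on species count")

    @property
    def target_area_km2(self) -> np.ndarray:
        return self.targets.prop * self.amounts.range_area_km2


# ---------------------------------------------------------------------------
# Marxan file formats (tab-delimited, Marxan 2.43 dialect)


def write_marxan_files(problem: ConservationProblem, directory: str | Path) -> None:
    """Emit pu.dat, spec.dat, puvspr.dat and bound.dat."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid, amounts, targets = problem.grid, problem.amounts, problem.targets

    pu = pd.DataFrame(
        {"id": grid.pu_ids, "cost": grid.cost, "status": grid.status}
    )
    pu.to_csv(directory / "pu.dat", sep="\t", index=False)

    spec = pd.DataFrame(
        {
            "id": np.arange(1, amounts.n_species + 1),
            "name": amounts.species_ids,
            "prop": targets.prop,
            "spf": targets.spf,
        }
    )
    spec.to_csv(directory / "spec.dat", sep="\t", index=False)

    s_idx, u_idx = np.nonzero(amounts.cell_counts)
    puvspr = pd.DataFrame(
        {
            "species": s_idx + 1,
            "pu": u_idx + 1,
            "amount": amounts.cell_counts[s_idx, u_idx] * amounts.cell_area,
        }
    ).sort_values(["pu", "species"], kind="stable")
    puvspr.to_csv(directory / "puvspr.dat", sep="\t", index=False)

    bound = pd.DataFrame(
        {
            "id1": problem.grid.boundary_id1,
            "id2": problem.grid.boundary_id2,
            "boundary": problem.grid.boundary_len,
        }
    )
    bound.to_csv(directory / "bound.dat", sep="\t", index=False)

    meta = pd.Series(
        {
            "n_rows": grid.n_rows,
            "n_cols": grid.n_cols,
            "pu_side_km": grid.pu_side_km,
            "cell_area": amounts.cell_area,
            "blm": problem.blm,
        }
    )
    meta.to_csv(directory / "gridmeta.dat", sep="\t", header=False)


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing planning file: {path.name}")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed content
        raise ValueError(f"{path.name}: cannot parse ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    bad = df[df[required].isna().any(axis=1)]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path.name}: malformed row at line {bad.index[0] + 2}")
    return df


def read_marxan_files(directory: str | Path, blm: float | None = None) -> ConservationProblem:
    """Read a Marxan planning directory back into a ConservationProblem.

    Accepts puvspr rows in any order (the writer always emits them sorted by
    pu, then species).  Unknown species or PU ids raise a parse error naming
    the offending line.
    """
    directory = Path(directory)
    pu = _read_table(directory / "pu.dat", ["id", "cost", "status"])
    spec = _read_table(directory / "spec.dat", ["id", "name", "prop", "spf"])
    puvspr = _read_table(directory / "puvspr.dat", ["species", "pu", "amount"])
    bound = _read_table(directory / "bound.dat", ["id1", "id2", "boundary"])
    meta = pd.read_csv(
        directory / "gridmeta.dat", sep="\t", header=None, index_col=0
    )[1]

    n_rows, n_cols = int(meta["n_rows"]), int(meta["n_cols"])
    cell_area = float(meta["cell_area"])
    n_pu = n_rows * n_cols
    if len(pu) != n_pu or set(pu["id"]) != set(range(1, n_pu + 1)):
        raise ValueError("pu.dat: ids do not form the expected 1..n lattice")
    pu = pu.sort_values("id")

    sp_ids = spec.sort_values("id")
    species_ids = list(sp_ids["name"].astype(str))
    valid_sp = set(sp_ids["id"].astype(int))
    counts = np.zeros((len(species_ids), n_pu), dtype=int)
    for line, rec in enumerate(puvspr.itertuples(index=False), start=2):
        s, u, amt = int(rec.species), int(rec.pu), float(rec.amount)
        if s not in valid_sp:
            raise ValueError(f"puvspr.dat: unknown species id {s} at line {line}")
        if not 1 <= u <= n_pu:
            raise ValueError(f"puvspr.dat: unknown pu id {u} at line {line}")
        counts[s - 1, u - 1] = int(round(amt / cell_area))

    grid = PlanningGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        pu_side_km=float(meta["pu_side_km"]),
        cost=pu["cost"].to_numpy(float),
        status=pu["status"].to_numpy(int),
        boundary_id1=bound["id1"].to_numpy(int),
        boundary_id2=bound["id2"].to_numpy(int),
        boundary_len=bound["boundary"].to_numpy(float),
    )
    amounts = AmountMatrix(
        species_ids=species_ids, cell_counts=counts, cell_area=cell_area
    )
    targets = TargetSpec(
        prop=sp_ids["prop"].to_numpy(float), spf=sp_ids["spf"].to_numpy(float)
    )
    return ConservationProblem(
        grid=grid,
        amounts=amounts,
        targets=targets,
        blm=float(meta["blm"]) if blm is None else blm,
    )
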
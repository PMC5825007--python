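"""Gap-analysis statistics: representation, stratified comparisons, geometry.

Representation of a species by a network is the percentage of its modelled
(binary) range area falling inside the selected planning units.  Group means
are reported for the four classic conservation groups (all, endangered,
endemic, biological-resource species).  Stratified comparisons split species
into equal-width classes of range size or mean range elevation and test the
per-class difference between two networks with the Wilcoxon rank-sum test
(exact permutation null for small samples, tie-corrected normal
approximation with continuity correction otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .grids import EnvStack
from .planning_io import AmountMatrix, PlanningGrid

logger = logging.getLogger(__name__)

GROUPS = ("all", "endangered", "endemic", "bio_resource")


@dataclass
class RepresentationTable:
    """Per-species representation plus group means for one network."""

    table: pd.DataFrame          # species_id, range_area_km2, amount_inside_km2, percent_inside
    group_means: dict[str, float]

    def percent(self, species_id: str) -> float:
        row = self.table[self.table["species_id"] == species_id]
        return float(row["percent_inside"].iloc[0])


def representation(
    amounts: AmountMatrix,
    network: np.ndarray,
    group_flags: dict[str, frozenset] | None = None,
) -> RepresentationTable:
    """percent_s = 100 * amount of s inside the network / range_area_s.

    Species with zero modelled range are excluded with a warning.  Group
    means are unweighted arithmetic means over group members.
    """
    sel = np.asarray(network, dtype=bool)
    inside = amounts.amounts @ sel
    total = amounts.range_area_km2
    keep = total > 0
    if not keep.all():
        excluded = [s for s, k in zip(amounts.species_ids, keep) if not k]
        logger.warning("excluding %d zero-range species: %s", len(excluded), excluded)
    ids = [s for s, k in zip(amounts.species_ids, keep) if k]
    pct = 100.0 * inside[keep] / total[keep]
    table = pd.DataFrame(
        {
            "species_id": ids,
            "range_area_km2": total[keep],
            "amount_inside_km2": inside[keep],
            "percent_inside": pct,
        }
    )
    group_flags = group_flags or {}
    means = {"all": float(pct.mean()) if len(ids) else float("nan")}
    for g in GROUPS[1:]:
        members = [i for i, s in enumerate(ids) if g in group_flags.get(s, frozenset())]
        means[g] = float(pct[members].mean()) if members else float("nan")
    return RepresentationTable(table=table, group_means=means)


def stratify(values, n_classes: int = 10) -> np.ndarray:
    """Equal-width class assignment over [min, max] of the classing variable.

    Internal boundary values go to the lower class; the global maximum goes
    to the top class.  If all values are equal, everything lands in a single
    class (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("classing values must be finite")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        logger.warning("degenerate classing variable: single class")
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, n_classes + 1)
    cls = np.searchsorted(edges, x, side="left") - 1
    return np.clip(cls, 0, n_classes - 1)


def wilcoxon_rank_sum(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Rank-sum statistic W (midranks) of sample a and a two-sided p-value.

    With ``method='auto'`` the p-value is exact for n_a + n_b <= 12: the
    permutation distribution of W over all C(N, n_a) group assignments,
    two-sided by doubling the smaller tail (capped at 1).  Larger samples
    use the normal approximation with tie-corrected variance and a 0.5
    continuity correction.  ``method='exact'`` or ``'normal'`` forces a path.
    """
    if method not in {"auto", "exact", "normal"}:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    w = float(ranks[:n_a].sum())

    if method == "exact" or (method == "auto" and N <= 12):
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(N), n_a)]
        )
        n_perm = comb(N, n_a)
        lo = (sums <= w + 1e-9).sum() / n_perm
        hi = (sums >= w - 1e-9).sum() / n_perm
        p = min(1.0, 2.0 * min(lo, hi))
        return w, float(p)

    mean_w = n_a * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_w = n_a * n_b / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_w) if diff != 0 else 0.0
    p = 2.0 * norm.sf(abs(z))
    return w, float(min(1.0, p))


@dataclass
class StratifiedComparison:
    """Per-class mean representation of two networks with rank-sum tests."""

    classing_variable: str
    table: pd.DataFrame  # class_index, n_species, mean_a, mean_b, W, p, significance


def compare_stratified(
    rep_a: RepresentationTable,
    rep_b: RepresentationTable,
    class_values: dict[str, float],
    classing_variable: str = "range_size",
    n_classes: int = 10,
) -> StratifiedComparison:
    """Classwise comparison of two networks' representation percentages.

    ``class_values`` maps species_id to the classing value (range area or
    mean range elevation); classes are equal-width.  Significance stars mark
    p <= 0.05 (*) and p <= 0.01 (**).
    """
    ids = [s for s in rep_a.table["species_id"] if s in class_values]
    vals = np.array([class_values[s] for s in ids])
    cls = stratify(vals, n_classes)
    pa = rep_a.table.set_index("species_id")["percent_inside"]
    pb = rep_b.table.set_index("species_id")["percent_inside"]
    rows = []
    for c in range(int(cls.max()) + 1):
        members = [s for s, k in zip(ids, cls) if k == c]
        if not members:
            continue
        xa = pa.loc[members].to_numpy()
        xb = pb.loc[members].to_numpy()
        w, p = wilcoxon_rank_sum(xa, xb)
        stars = "**" if p <= 0.01 else ("*" if p <= 0.05 else "")
        rows.append(
            {
                "class_index": c,
                "n_species": len(members),
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "W": w,
                "p": p,
                "significance": stars,
            }
        )
    return StratifiedComparison(
        classing_variable=classing_variable, table=pd.DataFrame(rows)
    )


def perimeter_area_ratio(network: np.ndarray, grid: PlanningGrid) -> float:
    """Exterior boundary length of the selected set over its area (km^-1).

    Shared internal edges cancel; landscape-edge exposure counts as
    perimeter when the grid's boundary list carries self-pairs.
    """
    sel = np.asarray(network, dtype=bool)
    if not sel.any():
        raise ValueError("perimeter/area ratio of an empty network is undefined")
    id1, id2 = grid.boundary_id1 - 1, grid.boundary_id2 - 1
    internal = id1 != id2
    cross = sel[id1[internal]] != sel[id2[internal]]
    perim = float(grid.boundary_len[internal][cross].sum())
    self_rows = ~internal
    perim += float(grid.boundary_len[self_rows][sel[id1[self_rows]]].sum())
    area = float(sel.sum() * grid.pu_area_km2)
    return perim / area


def network_overlap(network_a: np.ndarray, network_b: np.ndarray) -> float:
    """Percent of network a's area that lies inside network b."""
    a = np.asarray(network_a, dtype=bool)
    b = np.asarray(network_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("networks are not on the same grid")
    if not a.any():
        raise ValueError("network a is empty")
    return 100.0 * float((a & b).sum()) / float(a.sum())


def elevation_summary(
    network: np.ndarray, grid: PlanningGrid, env: EnvStack, pu_side_cells: int
) -> tuple[float, float]:
    """Mean and sample SD of fine-cell elevation inside the selected PUs."""
    sel = np.asarray(network, dtype=bool)
    if not sel.any():
        raise ValueError("elevation summary of an empty network is undefined")
    fine_mask = pu_mask_to_fine(sel, grid, pu_side_cells)
    vals = env["elevation"][fine_mask]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def pu_mask_to_fine(
    selected: np.ndarray, grid: PlanningGrid, pu_side_cells: int
) -> np.ndarray:
    """Expand a PU selection to the fine grid (boolean raster)."""
    sel = np.asarray(selected, dtype=bool).reshape(grid.n_rows, grid.n_cols)
    return np.kron(sel, np.ones((pu_side_cells, pu_side_cells), dtype=bool))
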
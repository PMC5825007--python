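"""Binary range maps from occurrence-probability rasters.

The default thresholding rule is data-driven and presence-only friendly: a
species' cut-off is the mean of its modelled probabilities at its own
occurrence points minus one sample standard deviation.  The classical
max-SSS rule (maximize sensitivity + specificity against the pseudo-absences)
is available as an alternative.  Both are floored at a small epsilon so a
clamped-to-zero model cannot produce an all-landscape range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import EnvStack

logger = logging.getLogger(__name__)


@dataclass
class ThresholdRule:
    """kind: 'sd_below_mean' (mean - 1 SD at occurrence points, default) or
    'max_sss'; ``floor`` is the minimum allowed threshold."""

    kind: str = "sd_below_mean"
    floor: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in {"sd_below_mean", "max_sss"}:
            raise ValueError(f"unknown threshold rule: {self.kind}")
        if not 0 <= self.floor < 1:
            raise ValueError("floor must be in [0, 1)")


def sd_threshold(prob_at_occurrences, floor: float = 0.001) -> float:
    """theta = max(floor, mean(p_occ) - sd(p_occ)), sample SD (n-1)."""
    p = np.asarray(prob_at_occurrences, dtype=float)
    if p.size < 2:
        raise ValueError("sd_threshold needs >= 2 occurrence probabilities")
    return float(max(floor, p.mean() - p.std(ddof=1)))


def max_sss_threshold(presence_scores, absence_scores) -> float:
    """Threshold maximizing sensitivity + specificity (presence rule p >= t).

    Candidates are the distinct observed scores; ties in the criterion are
    broken by the lowest such threshold.
    """
    pres = np.asarray(presence_scores, dtype=float)
    absn = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or absn.size == 0:
        raise ValueError("max_sss_threshold needs scores on both sides")
    candidates = np.unique(np.concatenate([pres, absn]))
    best_t, best_sss = None, -np.inf
    for t in candidates:  # ascending, so first max wins the tie rule
        sens = float((pres >= t).mean())
        spec = float((absn < t).mean())
        if sens + spec > best_sss + 1e-12:
            best_sss = sens + spec
            best_t = float(t)
    return best_t


@dataclass
class BinaryRange:
    """A species' thresholded range with its bookkeeping summaries."""

    species_id: str
    mask: np.ndarray          # boolean raster
    threshold: float
    range_area_km2: float
    mean_range_elevation_m: float  # NaN for an empty range

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def binarize(
    prob_raster: np.ndarray,
    threshold: float,
    env: EnvStack,
    species_id: str = "",
) -> BinaryRange:
    """mask = (p >= threshold); area = cell count x cell_area."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    mask = np.asarray(prob_raster) >= threshold
    n = int(mask.sum())
    mean_elev = float(env["elevation"][mask].mean()) if n else float("nan")
    return BinaryRange(
        species_id=species_id,
        mask=mask,
        threshold=float(threshold),
        range_area_km2=n * env.cell_area,
        mean_range_elevation_m=mean_elev,
    )


def build_ranges(
    prob_rasters: dict[str, np.ndarray],
    matrix,
    env: EnvStack,
    rule: ThresholdRule | None = None,
) -> dict[str, BinaryRange]:
    """Threshold every species' probability raster per the chosen rule.

    ``matrix`` is the fitted SiteSpeciesMatrix; occurrence-point
    probabilities (and, for max-SSS, pseudo-absence probabilities) are read
    off the raster at the matrix sites.
    """
    rule = rule or ThresholdRule()
    out: dict[str, BinaryRange] = {}
    rows, cols = matrix.sites[:, 0], matrix.sites[:, 1]
    for j, sp in enumerate(matrix.species_ids):
        raster = prob_rasters[sp]
        site_p = raster[rows, cols]
        pres = matrix.Y[:, j] == 1
        if rule.kind == "sd_below_mean":
            theta = sd_threshold(site_p[pres], floor=rule.floor)
        else:
            theta = max(rule.floor, max_sss_threshold(site_p[pres], site_p[~pres]))
        out[sp] = binarize(raster, theta, env, species_id=sp)
    return out


def richness_map(
    ranges: dict[str, BinaryRange], group: list[str] | None = None
) -> np.ndarray:
    """Integer raster counting how many (group) species' masks cover each cell."""
    members = list(ranges) if group is None else [s for s in group if s in ranges]
    shapes = {ranges[s].mask.shape for s in ranges}
    if len(shapes) > 1:
        raise ValueError("range masks are not co-registered")
    shape = shapes.pop()
    if not members:
        logger.warning("richness_map: empty species group")
        return np.zeros(shape, dtype=int)
    out = np.zeros(shape, dtype=int)
    for s in members:
        out += ranges[s].mask.astype(int)
    return out
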
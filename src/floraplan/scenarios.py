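"""Conservation scenarios: equal-area alternatives and area-capped additions.

A scenario fixes three choices: whether existing protected areas are locked
into every solution, the per-species representation targets, and an extent
cap.  Because the annealer optimizes representation rather than a fixed
area, the final network is cut from the *summed solution*: planning units
are ranked by selection frequency (locked-in PUs first) and accumulated
until the total area most closely matches the extent target, never exceeding
it when the two nearest prefixes are equidistant.  Ties between equal summed
scores are broken by ascending PU id, which makes the cut deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .planning_io import (
    STATUS_LOCKED_IN,
    ConservationProblem,
    PlanningGrid,
    TargetSpec,
    mark_status,
)
from .reserve_anneal import AnnealConfig, SelectionResult, run_repeats


@dataclass
class ScenarioSpec:
    """One scenario: lock-in flag, targets, BLM and extent cap (km^2)."""

    name: str
    lock_in: bool
    targets: TargetSpec
    blm: float
    extent_target_km2: float


@dataclass
class CappedNetwork:
    """An area-capped network cut from a ranked summed solution."""

    selected: np.ndarray        # (n_pu,) bool
    achieved_area_km2: float
    achieved_fraction: float
    rank_cutoff: int            # number of PUs taken from the ranking

    @property
    def n_pu(self) -> int:
        return int(self.selected.sum())


def area_cap_selection(
    summed: np.ndarray,
    grid: PlanningGrid,
    extent_target_km2: float,
    landscape_area_km2: float | None = None,
) -> CappedNetwork:
    """Cut the top of the summed-solution ranking to match an extent target.

    PUs are ordered by summed score descending with locked-in PUs ranked
    first; within equal scores, ascending PU id.  The prefix whose cumulative
    area is nearest the target wins; when the prefixes just below and just
    above the target are equidistant, the smaller (not exceeding) one is
    kept.
    """
    summed = np.asarray(summed)
    locked = grid.status == STATUS_LOCKED_IN
    areas = np.full(grid.n_pu, grid.pu_area_km2)
    locked_area = float(areas[locked].sum())
    if extent_target_km2 < locked_area - 1e-9:
        raise ValueError(
            f"extent target {extent_target_km2} km^2 is below the locked-in "
            f"area {locked_area} km^2"
        )
    # sort key: locked first, then score desc, then id asc
    order = np.lexsort((grid.pu_ids, -summed, ~locked))
    cum = np.cumsum(areas[order])
    diffs = np.abs(cum - extent_target_km2)
    k = int(np.argmin(diffs))  # argmin takes the first (smaller) of equal diffs
    if cum[k] > extent_target_km2 and k > 0 and np.isclose(
        diffs[k], abs(cum[k - 1] - extent_target_km2)
    ):
        k -= 1
    n_take = k + 1
    sel = np.zeros(grid.n_pu, dtype=bool)
    sel[order[:n_take]] = True
    achieved = float(cum[k])
    total = landscape_area_km2 if landscape_area_km2 else float(areas.sum())
    return CappedNetwork(
        selected=sel,
        achieved_area_km2=achieved,
        achieved_fraction=achieved / total,
        rank_cutoff=n_take,
    )


def run_scenario(
    grid: PlanningGrid,
    amounts,
    spec: ScenarioSpec,
    config: AnnealConfig,
    pa_mask: np.ndarray | None = None,
    pu_side_cells: int | None = None,
) -> tuple[CappedNetwork, SelectionResult]:
    """Run one scenario end to end: statuses, repeat runs, area cap."""
    mode = "lock_in" if spec.lock_in else "free"
    sgrid = mark_status(grid, pa_mask, mode, pu_side_cells)
    problem = ConservationProblem(
        grid=sgrid, amounts=amounts, targets=spec.targets, blm=spec.blm
    )
    result = run_repeats(problem, config)
    network = area_cap_selection(result.summed, sgrid, spec.extent_target_km2)
    return network, result


def preset_scenarios(
    n_species: int,
    existing_pa_area_km2: float,
    landscape_area_km2: float,
    blm: float = 0.0007,
    uniform_target: float = 0.15,
    spf: float = 100.0,
) -> dict[str, ScenarioSpec]:
    """The three named scenario presets.

    - ``equal_area``: free statuses, extent equal to the existing PA estate.
    - ``additional_lockin``: existing PAs locked in, extent 17 % of land
      (the Aichi Target 11 level); ``additional_lockin_double`` doubles the
      existing estate instead.
    - ``additional_free``: the same extents with nothing locked in.
    """
    targets = TargetSpec.uniform(n_species, uniform_target, spf=spf)
    aichi = 0.17 * landscape_area_km2
    return {
        "equal_area": ScenarioSpec(
            "equal_area", False, targets, blm, existing_pa_area_km2
        ),
        "additional_lockin": ScenarioSpec(
            "additional_lockin", True, targets, blm, aichi
        ),
        "additional_lockin_double": ScenarioSpec(
            "additional_lockin_double", True, targets, blm, 2 * existing_pa_area_km2
        ),
        "additional_free": ScenarioSpec(
            "additional_free", False, targets, blm, aichi
        ),
    }


def uniform_target_sweep(start: float = 0.10, stop: float = 0.30, step: float = 0.05):
    """The uniform representation-target grid (10 %...30 % in 5 % steps)."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def common_selection(networks: list[CappedNetwork], grid: PlanningGrid) -> np.ndarray:
    """PUs selected in every given network (the high-priority intersection)."""
    if len(networks) < 2:
        raise ValueError("need at least two networks to intersect")
    masks = []
    for nw in networks:
        if nw.selected.size != grid.n_pu:
            raise ValueError("networks are not on the same planning grid")
        masks.append(nw.selected)
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out
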
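"""End-to-end study pipeline on a synthetic world.

Chains every stage: world generation -> site-by-species matrix ->
multi-response MARS fits -> probability rasters -> thresholded binary
ranges -> planning-unit aggregation -> two area-capped scenarios (existing
PAs locked in vs free selection) -> gap-analysis summaries.  This is the
programmatic equivalent of the `floraplan run-study` command and the basis
of the package's reproducibility script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gap_report, range_maps, scenarios, sdm_mars, synthgeo
from .planning_io import TargetSpec, aggregate_to_planning_units, pa_coverage_fraction
from .reserve_anneal import AnnealConfig
from .synthgeo import World


@dataclass
class StudyResult:
    """Everything the default study computes, for reporting and testing."""

    world: World
    matrix: sdm_mars.SiteSpeciesMatrix
    evals: list[sdm_mars.ModelEval]
    ranges: dict[str, range_maps.BinaryRange]
    amounts: object
    grid: object
    pu_side_cells: int
    networks: dict[str, scenarios.CappedNetwork]
    representations: dict[str, gap_report.RepresentationTable]
    network_elevation: dict[str, tuple[float, float]]
    elevation_classes: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        aucs = np.concatenate([e.auc for e in self.evals])
        return float(np.nanmean(aucs))

    def elevation_class_means(self, scenario: str, n_classes: int = 10):
        """Mean representation per mean-range-elevation class."""
        rep = self.representations[scenario]
        ids = list(rep.table["species_id"])
        elev = np.array([self.ranges[s].mean_range_elevation_m for s in ids])
        ok = np.isfinite(elev)
        ids = [s for s, k in zip(ids, ok) if k]
        cls = gap_report.stratify(elev[ok], n_classes)
        pct = rep.table.set_index("species_id")["percent_inside"]
        out = {}
        for c in np.unique(cls):
            members = [s for s, k in zip(ids, cls) if k == c]
            out[int(c)] = float(pct.loc[members].mean())
        return out


def run_default_study(
    seed: int = 0,
    n_rows: int = 120,
    n_cols: int = 120,
    n_species: int = 60,
    pu_side_cells: int = 6,
    uniform_target: float = 0.15,
    blm: float = 0.0007,
    extent_fraction: float = 0.17,
    n_runs: int = 100,
    iter_factor: int = 1000,
    mars_config: sdm_mars.MarsConfig | None = None,
) -> StudyResult:
    """Run the whole pipeline on the default desk-scale synthetic world.

    Two scenarios are compared, both targeting ``uniform_target`` of every
    species' range with the same BLM and a 17 %-of-landscape extent cap:
    one locks the elevation-biased existing PAs into every solution, the
    other selects freely from all land.
    """
    world = synthgeo.default_world(
        seed=seed, n_rows=n_rows, n_cols=n_cols, n_species=n_species
    )
    matrix = sdm_mars.build_site_species_matrix(world.occurrences, world.env)
    fits = sdm_mars.fit_grouped(matrix, seed=seed, config=mars_config)

    prob_rasters: dict[str, np.ndarray] = {}
    ranges: dict[str, range_maps.BinaryRange] = {}
    evals = []
    for model, sub in fits:
        evals.append(sdm_mars.evaluate_model(model, sub))
        probs = sdm_mars.predict_probabilities(model, world.env)
        prob_rasters.update(probs)
        ranges.update(range_maps.build_ranges(probs, sub, world.env))
    # drop species whose thresholded range is empty: they carry no amounts
    ranges = {s: r for s, r in ranges.items() if r.n_cells > 0}

    amounts, grid = aggregate_to_planning_units(ranges, world.env, pu_side_cells)
    landscape_area = world.env.total_area_km2
    pa_pu_area = float(
        (pa_coverage_fraction(world.pa_mask, pu_side_cells) >= 0.5).sum()
        * grid.pu_area_km2
    )
    extent = max(extent_fraction * landscape_area, pa_pu_area)
    targets = TargetSpec.uniform(amounts.n_species, uniform_target)
    config = AnnealConfig(n_runs=n_runs, iter_factor=iter_factor, seed=seed)

    specs = {
        "lockin": scenarios.ScenarioSpec("lockin", True, targets, blm, extent),
        "free": scenarios.ScenarioSpec("free", False, targets, blm, extent),
    }
    flags = {sp.species_id: sp.group_flags for sp in world.species}
    networks, reps, elev_summary = {}, {}, {}
    for name, sspec in specs.items():
        network, _ = scenarios.run_scenario(
            grid, amounts, sspec, config,
            pa_mask=world.pa_mask, pu_side_cells=pu_side_cells,
        )
        networks[name] = network
        reps[name] = gap_report.representation(amounts, network.selected, flags)
        elev_summary[name] = gap_report.elevation_summary(
            network.selected, grid, world.env, pu_side_cells
        )

    result = StudyResult(
        world=world,
        matrix=matrix,
        evals=evals,
        ranges=ranges,
        amounts=amounts,
        grid=grid,
        pu_side_cells=pu_side_cells,
        networks=networks,
        representations=reps,
        network_elevation=elev_summary,
    )
    for name in specs:
        result.elevation_classes[name] = result.elevation_class_means(name)
    return result
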
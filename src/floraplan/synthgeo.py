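"""Synthetic landscapes, virtual species, surveys and existing protected areas.

This module stands in for the field data of a national plant survey: a
mountainous temperate landscape, a flora of virtual species with Gaussian
environmental niches spanning tiny to country-wide ranges, mountain-transect
survey sampling, and an existing protected-area (PA) network biased toward
high elevation.  Every generator is a pure function of its parameters and a
seed, so whole worlds are reproducible bit-for-bit.

The climate layers are *derived deterministically* from elevation and
position (a lapse-rate model plus smooth gradients) rather than sampled
independently.  That makes temperature and elevation strongly collinear on
purpose: the downstream distribution models then face the same
predictor-redundancy structure that real mountain floras produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EnvStack

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# landscape


@dataclass
class ReliefParams:
    """Parameters of the deterministic relief + climate construction.

    The defaults sketch a temperate, monsoon-influenced peninsula: a major
    mountain range running north-south near the eastern coast, a secondary
    inland range, coastal plains in the west and south, and roughly 70 % of
    the land in hill or mountain terrain.
    """

    max_elev: float = 1600.0          # m, tallest ridge crest
    secondary_elev: float = 900.0     # m, inland range
    ridge_pos: float = 0.72           # main ridge, fraction of east-west extent
    ridge_width: float = 0.10         # gaussian half-width, fraction of extent
    secondary_pos: float = 0.35
    secondary_width: float = 0.14
    noise_sd: float = 90.0            # m, smoothed random hill texture
    noise_scale: float = 4.0          # cells, gaussian smoothing radius
    sea_temp: float = 14.0            # degC, annual mean at sea level, south edge
    lapse_rate: float = 6.5           # degC per 1000 m
    lat_temp_range: float = 3.0       # degC drop from south to north edge
    base_precip: float = 1100.0       # mm, annual at sea level
    orographic: float = 0.55          # mm per m of elevation
    monsoon_gradient: float = 250.0   # mm extra from north to south edge


def make_landscape(
    n_rows: int = 120,
    n_cols: int = 120,
    seed: int = 0,
    relief: ReliefParams | None = None,
    cell_area: float = 0.1,
) -> EnvStack:
    """Build a synthetic mountainous landscape with derived climate layers.

    Elevation is a sum of deterministic ridge functions plus seeded, smoothed
    noise, clipped at sea level.  Temperature layers follow
    ``T = T_sea - lapse_rate * (elev / 1000) - lat_gradient * latitude`` so
    that two cells at the same latitude differing by 1000 m differ by exactly
    ``lapse_rate`` degrees.  Precipitation increases orographically with
    elevation and toward the south.  Slope and aspect come from finite
    differences of elevation; northness is sin(aspect), with flat cells
    assigned aspect 0 (hence northness 0).
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("landscape must be at least 8x8 cells")
    relief = relief or ReliefParams()
    for name in ("lapse_rate", "max_elev", "noise_sd"):
        if not math.isfinite(getattr(relief, name)):
            raise ValueError(f"relief parameter {name} must be finite")

    rng = np.random.default_rng(seed)
    rows = np.arange(n_rows, dtype=float)[:, None]  # row 0 = south
    cols = np.arange(n_cols, dtype=float)[None, :]
    y = rows / max(n_rows - 1, 1)
    x = cols / max(n_cols - 1, 1)

    main = relief.max_elev * np.exp(-0.5 * ((x - relief.ridge_pos) / relief.ridge_width) ** 2)
    # the main range is taller in the north, tapering south
    main = main * (0.55 + 0.45 * y)
    secondary = relief.secondary_elev * np.exp(
        -0.5 * ((x - relief.secondary_pos) / relief.secondary_width) ** 2
    ) * (0.7 + 0.3 * np.sin(2.2 * np.pi * y))
    noise = rng.standard_normal((n_rows, n_cols))
    if relief.noise_scale > 0:
        noise = ndimage.gaussian_filter(noise, relief.noise_scale)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    elevation = np.maximum(0.0, main + secondary + relief.noise_sd * noise - 40.0)

    annual_mean_temp = (
        relief.sea_temp
        - relief.lapse_rate * elevation / 1000.0
        - relief.lat_temp_range * y
        + 0.0 * x
    )
    temp_seasonality = 7.0 + 1.5 * elevation / 1000.0 + 2.0 * y + 0.0 * x
    temp_warmest_q = annual_mean_temp + 9.5 - 0.4 * elevation / 1000.0
    temp_coldest_q = annual_mean_temp - 11.0 - 0.8 * elevation / 1000.0

    annual_precip = (
        relief.base_precip
        + relief.orographic * elevation
        + relief.monsoon_gradient * (1.0 - y)
        + 0.0 * x
    )
    precip_wettest_q = 0.45 * annual_precip
    precip_driest_q = 0.08 * annual_precip

    slope_deg, aspect_deg, northness = _terrain_derivatives(
        elevation, math.sqrt(cell_area) * 1000.0
    )

    layers = {
        "elevation": elevation,
        "slope": slope_deg,
        "aspect": aspect_deg,
        "northness": northness,
        "annual_mean_temp": annual_mean_temp,
        "temp_seasonality": temp_seasonality,
        "temp_warmest_q": temp_warmest_q,
        "temp_coldest_q": temp_coldest_q,
        "annual_precip": annual_precip,
        "precip_wettest_q": precip_wettest_q,
        "precip_driest_q": precip_driest_q,
    }
    return EnvStack(cell_area=cell_area, layers=layers)


def _terrain_derivatives(elevation: np.ndarray, cell_side_m: float):
    """Slope (deg), aspect (deg) and northness from finite differences.

    Aspect is the compass direction of steepest descent, measured clockwise
    from north (row direction).  Flat cells (zero gradient) get aspect 0 by
    convention, hence northness sin(0) = 0; this is logged once per call.
    """
    dz_dy, dz_dx = np.gradient(elevation, cell_side_m)  # row (northward), col (eastward)
    grad = np.hypot(dz_dx, dz_dy)
    slope_deg = np.degrees(np.arctan(grad))
    flat = grad < 1e-12
    aspect_rad = np.arctan2(-dz_dx, -dz_dy)  # 0 = descent toward north
    aspect_rad = np.where(flat, 0.0, aspect_rad)
    aspect_deg = np.degrees(aspect_rad) % 360.0
    aspect_deg = np.where(flat, 0.0, aspect_deg)
    northness = np.sin(np.radians(aspect_deg))
    northness = np.where(flat, 0.0, northness)
    if flat.any():
        logger.info("flat-aspect convention applied to %d cells (aspect=0)", int(flat.sum()))
    return slope_deg, aspect_deg, northness


# ---------------------------------------------------------------------------
# virtual species


@dataclass
class VirtualSpecies:
    """A simulated species with a Gaussian environmental niche.

    ``suitability`` is the product of per-predictor Gaussian kernels rescaled
    so its landscape maximum is 1; the *true range* is the set of cells with
    suitability >= 0.5.
    """

    species_id: str
    group_flags: frozenset[str]
    niche_center: dict[str, float]
    niche_width: dict[str, float]
    prevalence: float
    suitability: np.ndarray = field(repr=False)
    true_range: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.niche_width.values()):
            raise ValueError(f"{self.species_id}: niche widths must be positive")

    def range_area_km2(self, cell_area: float) -> float:
        return int(self.true_range.sum()) * cell_area

    def mean_range_elevation(self, env: EnvStack) -> float:
        if not self.true_range.any():
            return float("nan")
        return float(env["elevation"][self.true_range].mean())


@dataclass
class NicheSpec:
    """Distributional recipe for a simulated flora.

    Niche centers are anchored at real landscape cells whose elevations span
    the 2nd-98th landscape percentiles, so the flora always contains both
    lowland and high-mountain specialists.  Niche widths (as multiples of
    each predictor's landscape SD) are spread geometrically from
    ``min_width_factor`` to ``max_width_factor``, which makes true range
    areas span several orders of magnitude.
    """

    predictors: tuple[str, ...] = ("annual_mean_temp", "annual_precip", "northness")
    min_width_factor: float = 0.05
    max_width_factor: float = 2.5
    frac_endangered: float = 0.15
    frac_endemic: float = 0.20
    frac_bio_resource: float = 0.25

    def __post_init__(self) -> None:
        if self.min_width_factor <= 0 or self.max_width_factor <= 0:
            raise ValueError("niche width factors must be positive")


def suitability_from_niche(
    env: EnvStack, center: dict[str, float], width: dict[str, float]
) -> np.ndarray:
    """Product-of-Gaussians suitability, rescaled to a landscape maximum of 1."""
    if any(w <= 0 for w in width.values()):
        raise ValueError("niche widths must be positive")
    log_suit = np.zeros(env.shape)
    for p, c_v in center.items():
        log_suit += -0.5 * ((env[p] - c_v) / width[p]) ** 2
    return np.exp(log_suit - log_suit.max())


def simulate_species(
    env: EnvStack,
    n_species: int = 60,
    seed: int = 0,
    niche_spec: NicheSpec | None = None,
) -> list[VirtualSpecies]:
    """Simulate a flora of virtual species with per-cell true suitability.

    suitability(cell) = prod_v exp(-0.5 ((x_v - c_v) / w_v)^2), rescaled to a
    landscape maximum of 1.  Width factors and elevation anchors are paired
    by a seeded shuffle, so small and large ranges occur at all elevations.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    spec = niche_spec or NicheSpec()
    rng = np.random.default_rng(seed)
    elev = env["elevation"].ravel()
    order = np.argsort(elev, kind="stable")
    n_cells = elev.size

    # anchor cells: elevation quantiles evenly spread over [0.02, 0.98]
    quantiles = np.linspace(0.02, 0.98, n_species)
    anchor_flat = order[np.clip((quantiles * (n_cells - 1)).astype(int), 0, n_cells - 1)]
    width_factors = np.geomspace(spec.min_width_factor, spec.max_width_factor, n_species)
    rng.shuffle(width_factors)

    pred_arrays = {p: env[p] for p in spec.predictors}
    pred_sd = {p: max(float(a.std()), 1e-12) for p, a in pred_arrays.items()}

    species: list[VirtualSpecies] = []
    n_digits = len(str(n_species))
    for i in range(n_species):
        r, c = np.unravel_index(anchor_flat[i], env.shape)
        center = {}
        width = {}
        for p in spec.predictors:
            center[p] = float(pred_arrays[p][r, c]) + 0.05 * pred_sd[p] * rng.standard_normal()
            # per-predictor jitter of the common width factor keeps niches anisotropic
            width[p] = float(width_factors[i] * pred_sd[p] * math.exp(0.3 * rng.standard_normal()))
        suit = suitability_from_niche(env, center, width)
        true_range = suit >= 0.5
        flags = set()
        if rng.random() < spec.frac_endangered:
            flags.add("endangered")
        if rng.random() < spec.frac_endemic:
            flags.add("endemic")
        if rng.random() < spec.frac_bio_resource:
            flags.add("bio_resource")
        species.append(
            VirtualSpecies(
                species_id=f"sp{i + 1:0{n_digits}d}",
                group_flags=frozenset(flags),
                niche_center=center,
                niche_width=width,
                prevalence=float(true_range.mean()),
                suitability=suit,
                true_range=true_range,
            )
        )
    return species


# ---------------------------------------------------------------------------
# survey sampling


@dataclass
class SurveySpec:
    """Mountain-transect survey design.

    The landscape is tiled into ``n_transects`` blocks; within each block
    ``sites_per_transect`` distinct cells are drawn with probability
    proportional to ``(elevation rank)^elevation_bias`` — the field crews of
    the emulated survey walked a representative mountain path per grid, so
    the default bias of 1 weights sites linearly by elevation rank.  At a
    surveyed cell inside a species' true range the species is recorded with
    probability ``detection_prob * u_s ** detection_heterogeneity`` where
    u_s ~ Uniform(0, 1) is a fixed per-species detectability; outside its
    range it is never recorded.  Heterogeneous detectability reproduces a
    well-known feature of large floristic surveys: some species with very
    few records are widespread but inconspicuous, not rare.  Set
    ``detection_heterogeneity = 0`` for a survey where every species is
    detected with exactly ``detection_prob``.
    """

    n_transects: int = 15
    sites_per_transect: int = 40
    detection_prob: float = 0.9
    elevation_bias: float = 1.0
    detection_heterogeneity: float = 1.0


@dataclass
class OccurrenceTable:
    """Point records (species_id, row, col) plus the distinct site index."""

    records: "np.ndarray"  # (n_records, 2) int (row, col)
    species_ids: list[str]
    rows: np.ndarray
    cols: np.ndarray
    dropped_species: list[str]
    survey_sites: np.ndarray = None  # (n_surveyed, 2); includes empty sites

    @property
    def n_records(self) -> int:
        return len(self.species_ids)

    def sites(self) -> np.ndarray:
        """Distinct (row, col) sites, lexicographically sorted."""
        pairs = np.stack([self.rows, self.cols], axis=1)
        return np.unique(pairs, axis=0)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"species_id": self.species_ids, "row": self.rows, "col": self.cols}
        )

    def records_for(self, species_id: str) -> np.ndarray:
        mask = np.array([s == species_id for s in self.species_ids])
        return np.stack([self.rows[mask], self.cols[mask]], axis=1)


def _block_partition(n_rows: int, n_cols: int, n_blocks: int):
    """Tile the grid into ~square blocks; yields (row_slice, col_slice)."""
    br = int(math.sqrt(n_blocks))
    while n_blocks % br != 0:
        br -= 1
    bc = n_blocks // br
    if n_cols < n_rows:
        br, bc = bc, br
    row_edges = np.linspace(0, n_rows, br + 1).astype(int)
    col_edges = np.linspace(0, n_cols, bc + 1).astype(int)
    for i in range(br):
        for j in range(bc):
            yield (
                slice(row_edges[i], row_edges[i + 1]),
                slice(col_edges[j], col_edges[j + 1]),
            )


def sample_occurrences(
    species: list[VirtualSpecies],
    env: EnvStack,
    seed: int = 0,
    survey: SurveySpec | None = None,
) -> OccurrenceTable:
    """Simulate survey point records with mountain-biased site placement.

    Species that end up with fewer than 2 records are dropped (the survey's
    observed minimum per species is 2) and reported in ``dropped_species``
    and the log.
    """
    survey = survey or SurveySpec()
    if survey.n_transects < 1:
        raise ValueError("survey must have at least one transect")
    rng = np.random.default_rng(seed)
    elev = env["elevation"]

    site_rows: list[np.ndarray] = []
    site_cols: list[np.ndarray] = []
    for rsl, csl in _block_partition(env.n_rows, env.n_cols, survey.n_transects):
        block_elev = elev[rsl, csl]
        n_block = block_elev.size
        k = min(survey.sites_per_transect, n_block)
        ranks = np.empty(n_block)
        ranks[np.argsort(block_elev.ravel(), kind="stable")] = np.arange(1, n_block + 1)
        weights = ranks ** survey.elevation_bias
        weights = weights / weights.sum()
        chosen = rng.choice(n_block, size=k, replace=False, p=weights)
        rr, cc = np.unravel_index(chosen, block_elev.shape)
        site_rows.append(rr + rsl.start)
        site_cols.append(cc + csl.start)
    rows = np.concatenate(site_rows)
    cols = np.concatenate(site_cols)

    detectability = survey.detection_prob * (
        rng.random(len(species)) ** survey.detection_heterogeneity
    )
    rec_species: list[str] = []
    rec_rows: list[int] = []
    rec_cols: list[int] = []
    for sp, det in zip(species, detectability):
        in_range = sp.true_range[rows, cols]
        detected = in_range & (rng.random(rows.size) < det)
        idx = np.nonzero(detected)[0]
        rec_species.extend([sp.species_id] * idx.size)
        rec_rows.extend(rows[idx].tolist())
        rec_cols.extend(cols[idx].tolist())

    counts: dict[str, int] = {}
    for s in rec_species:
        counts[s] = counts.get(s, 0) + 1
    dropped = [sp.species_id for sp in species if counts.get(sp.species_id, 0) < 2]
    if dropped:
        logger.warning("dropping %d species with < 2 records: %s", len(dropped), dropped)
    keep = np.array([counts.get(s, 0) >= 2 for s in rec_species])
    rec_rows = np.asarray(rec_rows, dtype=int)
    rec_cols = np.asarray(rec_cols, dtype=int)
    kept_species = [s for s, k in zip(rec_species, keep) if k]
    return OccurrenceTable(
        records=np.stack([rec_rows[keep], rec_cols[keep]], axis=1),
        species_ids=kept_species,
        rows=rec_rows[keep],
        cols=rec_cols[keep],
        dropped_species=dropped,
        survey_sites=np.stack([rows, cols], axis=1),
    )


# ---------------------------------------------------------------------------
# existing protected areas


def make_existing_pas(
    env: EnvStack,
    target_fraction: float = 0.057,
    elevation_bias: float = 6.0,
    seed: int = 0,
    n_patches: int = 5,
) -> np.ndarray:
    """Grow a contiguous existing-PA mask biased toward high elevation.

    Patches are grown cell-by-cell from ``n_patches`` seed cells; both seed
    placement and frontier growth weight cells by
    ``exp(elevation_bias * normalized elevation rank)``.  With bias 0 the
    mask is an unbiased contiguous sample of the landscape; with the default
    bias the mask concentrates on mountains, mirroring real PA systems that
    over-represent high ground.  The mask covers exactly
    ``round(target_fraction * n_cells)`` cells.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = env.shape
    n_cells = n_rows * n_cols
    n_target = int(round(target_fraction * n_cells))
    if n_target < n_patches:
        n_patches = max(1, n_target)

    elev = env["elevation"].ravel()
    rank = np.empty(n_cells)
    rank[np.argsort(elev, kind="stable")] = np.arange(n_cells)
    rank_norm = rank / max(n_cells - 1, 1)
    weight = np.exp(elevation_bias * rank_norm)

    mask = np.zeros(n_cells, dtype=bool)
    p = weight / weight.sum()
    seeds = rng.choice(n_cells, size=n_patches, replace=False, p=p)
    frontier: set[int] = set()

    def neighbors(flat: int):
        r, c = divmod(flat, n_cols)
        if r > 0:
            yield flat - n_cols
        if r < n_rows - 1:
            yield flat + n_cols
        if c > 0:
            yield flat - 1
        if c < n_cols - 1:
            yield flat + 1

    def add(flat: int):
        mask[flat] = True
        frontier.discard(flat)
        for nb in neighbors(flat):
            if not mask[nb]:
                frontier.add(nb)

    for s in seeds[: n_target]:
        if not mask[s]:
            add(int(s))
    while mask.sum() < n_target:
        if not frontier:  # exhausted (cannot happen on a connected grid)
            raise RuntimeError("PA growth frontier exhausted")
        cand = np.fromiter(frontier, dtype=int)
        w = weight[cand]
        pick = int(cand[rng.choice(cand.size, p=w / w.sum())])
        add(pick)
    return mask.reshape(n_rows, n_cols)


# ---------------------------------------------------------------------------
# default world


@dataclass
class World:
    """A fully generated study system: landscape, flora, survey and PAs."""

    env: EnvStack
    species: list[VirtualSpecies]
    occurrences: OccurrenceTable
    pa_mask: np.ndarray
    seed: int

    @property
    def surveyed_species(self) -> list[VirtualSpecies]:
        recorded = set(self.occurrences.species_ids)
        return [sp for sp in self.species if sp.species_id in recorded]


def default_world(
    seed: int = 0,
    n_rows: int = 120,
    n_cols: int = 120,
    n_species: int = 60,
    pa_fraction: float = 0.057,
    survey: SurveySpec | None = None,
) -> World:
    """Generate the default desk-scale study system.

    A 120x120 grid of 0.1 km^2 cells (a 1,440 km^2 'country'), 60 species and
    a 15-transect survey stand in for the national survey this package
    emulates.  After generation the world is checked for the structural
    feature the analysis probes: at the default elevation bias, at least one
    species' true range is missed entirely by the existing-PA mask (the
    lowland gap).
    """
    env = make_landscape(n_rows=n_rows, n_cols=n_cols, seed=seed)
    species = simulate_species(env, n_species=n_species, seed=seed + 1)
    occurrences = sample_occurrences(species, env, seed=seed + 2, survey=survey)
    pa_mask = make_existing_pas(env, target_fraction=pa_fraction, seed=seed + 3)

    areas = np.array([sp.true_range.sum() for sp in species], dtype=float)
    areas = areas[areas > 0]
    if areas.size and areas.max() / max(areas.min(), 1) < 1e3:
        logger.warning(
            "range-area spread below 3 orders of magnitude (%.0fx)",
            areas.max() / max(areas.min(), 1),
        )
    missed = [
        sp.species_id
        for sp in species
        if sp.true_range.any() and not (sp.true_range & pa_mask).any()
    ]
    if not missed:
        raise AssertionError(
            "generated world lacks a lowland-gap species (all true ranges "
            "intersect the existing-PA mask)"
        )
    logger.info("lowland-gap species entirely outside existing PAs: %s", missed)
    return World(env=env, species=species, occurrences=occurrences, pa_mask=pa_mask, seed=seed)
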
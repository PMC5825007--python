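"""Printed figures of the South Korean study system and their identities.

These constants describe the real national study system that the synthetic
worlds in this package are scaled-down stand-ins for: the mainland extent,
the existing protected-area estate, and the national plant survey.  The
functions recompute the derived percentages and extents from those printed
inputs — simple arithmetic identities that document how the headline numbers
relate to one another.
"""

from __future__ import annotations

MAINLAND_AREA_KM2 = 95_219.0
ISLAND_AREA_KM2 = 4_814.0
EXISTING_PA_AREA_KM2 = 5_463.20
DOUBLE_PA_AREA_KM2 = 10_926.08
COMMON_PLUS_EXISTING_KM2 = 6_192.47
AICHI_FRACTION = 0.17

N_OCCURRENCE_RECORDS = 150_959
N_SPECIES_MODELLED = 2_297
N_SPECIES_UNRECORDED = 1_833
N_SURVEY_GRIDS = 7_425
SURVEY_GRID_AREA_KM2 = 17.3
N_SDM_GROUPS = 15
MAX_BATCH_SPECIES = 300
PU_AREA_KM2 = 4.0
BLM_OPTIONS = (0.0, 0.0007)


def pa_percent_of_mainland(pa_area_km2: float = EXISTING_PA_AREA_KM2) -> float:
    """Percent of the mainland covered by a PA estate (5.74 for the existing one)."""
    return 100.0 * pa_area_km2 / MAINLAND_AREA_KM2


def aichi_extent_km2() -> float:
    """17 % of the mainland — the Aichi Target 11 extent (16,187.23 km^2)."""
    return AICHI_FRACTION * MAINLAND_AREA_KM2


def mean_records_per_species() -> float:
    """Average survey records per modelled species (rounds to 66)."""
    return N_OCCURRENCE_RECORDS / N_SPECIES_MODELLED


def survey_coverage_percent() -> float:
    """Percent of the known flora documented by the survey (rounds to 56)."""
    return 100.0 * N_SPECIES_MODELLED / (N_SPECIES_MODELLED + N_SPECIES_UNRECORDED)
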
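import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from thermaffin.synthetic_ocean import (
    SpeciesParams,
    WorldConfig,
    make_thermal_limits,
    make_world,
    sample_occurrences,
    truth_to_attributes,
)


@pytest.fixture(scope="session")
def small_world():
    """A 10x10 world with land, shelves and two years of monthly data."""
    return make_world(
        WorldConfig(n_lat=10, n_lon=10, land_fraction=0.3, year_range=(2000, 2001), seed=11)
    )


@pytest.fixture(scope="session")
def small_study(small_world):
    """Occurrences + limits for a handful of species on the small world."""
    species = [
        SpeciesParams(
            species_id=f"sp{i}",
            n=60,
            preferred_temp=5.0 + 4.0 * i,
            niche_sd=3.0,
            group_key=g,
            depth_max=300.0,
            missing_depth_rate=0.3,
            negative_depth_rate=0.05,
            missing_date_rate=0.1,
            out_of_range_date_rate=0.05,
        )
        for i, g in enumerate(
            ["benthos", "macroalgae", "fish:pelagic", "fish:demersal", "fish:reef-associated", "benthos"]
        )
    ]
    occurrences, truth = sample_occurrences(small_world, species, seed=5)
    limits = make_thermal_limits(truth, seed=5)
    return {
        "occurrences": occurrences,
        "truth": truth,
        "limits": limits,
        "attributes": truth_to_attributes(truth),
    }
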
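import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from helpers import make_universe  # noqa: F401  (re-exported for tests)

from ruralscale.geodata import ZipUniverse, apply_rural_designation
from ruralscale.scale import build_scale
from ruralscale.simulate import GeneratorConfig


@pytest.fixture
def toy_universe():
    """Two ZIPs in one prefix: 10,000 urban + 5,000 rural -> 33.33% rural."""
    return make_universe(
        [("85001", 10000, False), ("85002", 5000, True)]
    )


@pytest.fixture
def small_config():
    """Generator config scaled down for fast unit tests."""
    return GeneratorConfig(seed=7, n_prefixes=40, n_participants=2000)


@pytest.fixture
def small_world(small_config):
    """(universe, scale, participants, responses) from the small config."""
    from ruralscale.simulate import generate_cohort, generate_zip_universe

    population, rural = generate_zip_universe(small_config)
    universe = ZipUniverse(records=population.assign(is_rural=False))
    universe = apply_rural_designation(universe, rural["zip5"])
    scale = build_scale(universe)
    participants, responses = generate_cohort(small_config, scale)
    return universe, scale, participants, responses
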
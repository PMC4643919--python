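import pytest
from hypothesis import HealthCheck, settings

import plastomics as pm

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


SMALL_CONFIG = dict(
    lsc_length=18_000,
    ssc_length=5_000,
    ir_length=6_000,
    n_repeat_loci=60,
    junction_overlap=36,
)


@pytest.fixture(scope="session")
def small_truth() -> pm.SyntheticTruth:
    """One compact simulated plastome family shared across tests.

    Region lengths are scaled down ~5× from a real plastome to keep the
    session fast; branch lengths keep the low-divergence regime.
    """
    return pm.simulate(pm.SimulationConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_root(small_truth):
    return small_truth.root, small_truth.root_structure


def make_alignment(**rows) -> pm.AlignmentMatrix:
    return pm.AlignmentMatrix.from_dict(rows)
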
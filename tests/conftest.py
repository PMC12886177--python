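import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def single_pop_truth():
    """One bulk population with known growth/grazing/lysis rates."""
    from ksw.synthetic import CommunityTruth

    return CommunityTruth(
        asv_ids=["bulk"],
        mu=np.array([0.05]),
        g=np.array([0.08]),
        v=np.array([0.03]),
        n0=np.array([1e6]),
        prmdt=np.array([3.0]),
        winner_flags=np.array(["select-winner"]),
    )


@pytest.fixture
def noiseless_experiment(single_pop_truth):
    from ksw.synthetic import NoiseSpec, simulate_dilution_experiment

    return simulate_dilution_experiment(
        single_pop_truth, noise=NoiseSpec(count_cv=0.0, read_depth=None)
    )


@pytest.fixture
def small_community():
    from ksw.synthetic import simulate_community

    return simulate_community(12, seed=7, grazing_rate=0.05, lysis_rate=0.02)
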
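import numpy as np
import pytest

from popsweep.synth import RegionSpec, SweepSpec, simulate_region_sample


def small_spec(seed: int, sweep: bool = True) -> RegionSpec:
    """Reduced sample size for fast unit tests (defaults elsewhere)."""
    spec = RegionSpec(seed=seed)
    spec.populations = {"pop1": 10, "pop2": 10, "pop3": 8}
    spec.sweep.present = sweep
    return spec


@pytest.fixture(scope="session")
def swept_region():
    return simulate_region_sample(small_spec(seed=202))


@pytest.fixture(scope="session")
def neutral_region():
    return simulate_region_sample(small_spec(seed=203, sweep=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
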
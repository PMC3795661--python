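import numpy as np
import pytest

from scalescape import AnalysisConfig, CommunityTimeSeries


@pytest.fixture
def small_cts() -> CommunityTimeSeries:
    """A tiny 6-step, 3-taxon community with positive biovolume everywhere."""
    rng = np.random.default_rng(42)
    return CommunityTimeSeries(
        site_id="T1",
        state_id="wet",
        times=np.arange(1, 7),
        taxa=["alpha", "beta", "gamma"],
        biovolume=rng.lognormal(0.0, 0.5, size=(6, 3)),
    )


@pytest.fixture
def fast_config() -> AnalysisConfig:
    """Config with the minimum permutation count, for quick pipeline runs."""
    return AnalysisConfig(n_permutations=199, seed=0)
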
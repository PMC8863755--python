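import pytest
from hypothesis import settings

from phonelog.simulate import (
    ArtifactParams,
    BehaviorParams,
    inject_artifacts,
    simulate_usage_log,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim30():
    """30 days at default behavioral parameters, fixed seed: (params, stream, truth)."""
    params = BehaviorParams(n_days=30, seed=7)
    stream, truth = simulate_usage_log(params)
    return params, stream, truth


@pytest.fixture(scope="session")
def sim60_dirty():
    """60 days with injected duplicates and clock-on nights: (clean, dirty, truth)."""
    params = BehaviorParams(n_days=60, seed=19)
    stream, truth = simulate_usage_log(params)
    dirty = inject_artifacts(
        stream,
        truth,
        ArtifactParams(duplicate_prob=0.05, clock_on_prob=0.3, seed=23),
    )
    return stream, dirty, truth
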
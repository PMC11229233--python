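import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promevol.coords import AnalysisWindow

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_window() -> AnalysisWindow:
    """A 15-position window (offsets -10..-1, +1..+5; promoter -8..-3)."""
    return AnalysisWindow(upstream=10, downstream=5, promoter_start=-8, promoter_end=-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240708)
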
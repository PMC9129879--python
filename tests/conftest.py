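import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epimemory.synthetic_data import DEFAULT_LOCUS
from epimemory.trace_io import TraceSignal

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def locus():
    return DEFAULT_LOCUS


def make_flat_trace(called_bases: str, spacing: int = 10, value: float = 1.0) -> TraceSignal:
    """A trace with uniform intensities; useful for basecall-level tests."""
    n = len(called_bases)
    L = n * spacing
    return TraceSignal(
        intensities=np.full((4, L), value),
        called_bases=tuple(called_bases),
        peak_positions=spacing // 2 + spacing * np.arange(n),
    )
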
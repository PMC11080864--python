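import pytest
from hypothesis import HealthCheck, settings

from evstereo import PancakeCell

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cell24() -> PancakeCell:
    """The standard pancake model: 24 μm diameter, 4 μm height."""
    return PancakeCell(24.0, 4.0)
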
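import pytest
from hypothesis import HealthCheck, settings

from mutdiff import CodingGenome

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_genome() -> CodingGenome:
    """Minimal genome with exactly one TTCGT and one GATGT window."""
    return CodingGenome({"g1": "TTCGTAAAGATGT"})


@pytest.fixture
def flanked_genome() -> CodingGenome:
    return CodingGenome(
        {"g1": "TGCATT"},
        {"g1": ("GGCA", "ACGG")},
    )
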
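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
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_ped(tmp_path):
    """Smallest nuclear family: two founders and two children."""
    p = tmp_path / "tiny.ped"
    p.write_text(
        "FAM1 F 0 0 1 1 0.1\n"
        "FAM1 M 0 0 2 2 -0.4\n"
        "FAM1 C1 F M 1 2 2.0\n"
        "FAM1 C2 F M 2 1 0.7\n"
    )
    return p
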
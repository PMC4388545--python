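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


@pytest.fixture()
def rng():
    return np.random.default_rng(20150407)


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """A small synthetic dataset directory (traces + cohort + truth)."""
    from disctilt import write_fixture_dir

    path = tmp_path_factory.mktemp("fixtures")
    return write_fixture_dir(path / "data", n_eyes=10, seed=42, with_images=False)
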
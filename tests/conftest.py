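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


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_site():
    """One small synthetic site (2 recordings x 10 epochs), preprocessed."""
    from somnet.synthetic_psg import SimConfig, SiteConfig, site_patterns

    cfg = SimConfig(
        n_recordings=2, epochs_per_recording=10,
        site=SiteConfig(name="tiny", fs=128), seed=42,
    )
    return site_patterns(cfg)
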
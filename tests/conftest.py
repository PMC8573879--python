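import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Noise-free 3+3 cohort over a reduced tracer panel."""
    from aminoflux import CohortConfig, simulate_cohort
    cfg = CohortConfig(n_cn=3, n_cd=3, noise_cv=0.0, seed=42,
                       tracers=("Phe", "Tyr", "Leu"),
                       conversion_pairs=(("Phe", "Tyr"),))
    return simulate_cohort(cfg)


@pytest.fixture
def noisy_cohort():
    """Default-noise 12+8 cohort over a reduced tracer panel."""
    from aminoflux import CohortConfig, simulate_cohort
    cfg = CohortConfig(n_cn=12, n_cd=8, noise_cv=0.03, seed=7,
                       tracers=("Phe", "Tyr", "Leu"),
                       conversion_pairs=(("Phe", "Tyr"),))
    return simulate_cohort(cfg)
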
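import pytest
from hypothesis import HealthCheck, settings

from actibigram import (
    ConfounderSpec,
    SyntheticCohortConfig,
    cohort_features,
    simulate_outcomes,
    simulate_sequences,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_table():
    """A realistic simulated cohort table: features + confounders + outcome."""
    cfg = SyntheticCohortConfig(
        n_participants=150,
        seed=11,
        confounders=(
            ConfounderSpec(name="z", dist="normal", params=(0.0, 1.0), beta=-1.0),
            ConfounderSpec(name="female", dist="bernoulli", params=(0.5,), beta=0.6),
        ),
    )
    cohort = simulate_sequences(cfg)
    features = cohort_features(cohort)
    return simulate_outcomes(features, cfg)
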
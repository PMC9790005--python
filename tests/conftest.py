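import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # fixtures used under @given are read-only objects
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def toy_clock():
    from epimobility import ClockDefinition

    return ClockDefinition(
        name="toy", intercept=10.0, coefficients={"cgA": 2.0, "cgB": -1.0, "cgC": 0.5}
    )


@pytest.fixture
def beta_frame():
    """3 probes x 2 samples, plain fractions."""
    return pd.DataFrame(
        {"s1": [0.5, 0.2, 0.8], "s2": [0.1, 0.4, 0.6]}, index=["cgA", "cgB", "cgC"]
    )


@pytest.fixture
def small_cohort():
    """Balanced 3x3 cohort, 4 persons per cell, deterministic outcome."""
    from epimobility import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(
        cell_counts=tuple((4, 4, 4) for _ in range(3)),
        p=0.5,
        delta=(1.0, 0.0, -1.0),
        sigma=0.3,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def drm_cohort():
    """Study-shaped cohort with known DRM truth (p = 0.67)."""
    from epimobility import GeneratorConfig, generate_cohort, standardize_covariates

    cfg = GeneratorConfig(p=0.67, delta=(0.5, 0.0, -0.5), sigma=1.0, seed=3)
    return standardize_covariates(generate_cohort(cfg))
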
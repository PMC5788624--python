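import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from renalmir import panel
from renalmir.quantify import StandardCurve
from renalmir.synthetic import CohortConfig, generate_expression_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_curve() -> StandardCurve:
    """A 100%-efficiency standard curve: Ct = -ln(x)/ln(2) + 40."""
    return StandardCurve("miR-222", slope=-1.4427, intercept=40.0, r_squared=1.0)


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """Synthetic cohort at the study's group sizes (27/29/19/11), seed 7."""
    return generate_expression_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """A big labelled cohort (200/group) for threshold-derivation tests."""
    cfg = CohortConfig(group_sizes={g: 200 for g in panel.SUBTYPES}, seed=11)
    return generate_expression_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
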
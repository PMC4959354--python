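import numpy as np
import pytest

from psamine import Pattern, SimConfig, generate_cohort
from psamine.transform import DiscretizationScheme

# The four-sequence walkthrough cohort used to illustrate pattern growth:
# states are velocity bins (L low ... H high), elements time-ordered.
TABLE_SEQUENCES = [
    ("L", "L", "L", "MH", "M"),
    ("L", "M", "ML", "L"),
    ("H", "ML", "M", "M", "ML"),
    ("H", "M", "L", "M", "ML", "M"),
]


@pytest.fixture(scope="session")
def walkthrough_sequences():
    return TABLE_SEQUENCES


@pytest.fixture(scope="session")
def published_schemes():
    """After-nadir discretization schemes with the published interval layout."""
    eq = DiscretizationScheme(
        method="equal_frequency",
        boundaries=(-0.005, 0.005, 0.068, 0.454),
        labels=("L_q", "ML_q", "M_q", "MH_q", "H_q"),
        frequencies=(0.2, 0.2, 0.2, 0.2, 0.2),
    )
    en = DiscretizationScheme(
        method="entropy_mdlp",
        boundaries=(-0.048, 5.43),
        labels=("L_e", "M_e", "H_e"),
        frequencies=(0.141, 0.851, 0.008),
    )
    return {"equal_frequency": eq, "entropy_mdlp": en}


@pytest.fixture(scope="session")
def published_predictive_patterns():
    """The five predictive candidates with their class supports."""
    return [
        Pattern(("L_q",), "nonevent", 0.51, scheme="equal_frequency"),
        Pattern(("L_q", "L_q"), "nonevent", 0.34, scheme="equal_frequency"),
        Pattern(("L_e",), "nonevent", 0.49, scheme="entropy_mdlp"),
        Pattern(("L_e", "L_e"), "nonevent", 0.33, scheme="entropy_mdlp"),
        Pattern(("M_e", "L_e"), "nonevent", 0.49, scheme="entropy_mdlp"),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
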
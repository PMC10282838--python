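import numpy as np
import pandas as pd
import pytest

import panssboost as pb
from panssboost.design import EncodedDesign


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Default synthetic cohort (n=320) with its truth sidecar."""
    df = pb.generate_cohort(seed=3)
    return pb.split_truth(df)


@pytest.fixture(scope="session")
def cohort(cohort_and_truth):
    return cohort_and_truth[0]


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for cheap fitting tests."""
    df = pb.generate_cohort(n=120, seed=11)
    return pb.split_truth(df)[0]


def single_column_design(x: np.ndarray) -> EncodedDesign:
    """A bare one-column design for tests with hand-built base learners."""
    return EncodedDesign(np.column_stack([np.asarray(x, dtype=float)]), centers={})
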
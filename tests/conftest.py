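import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nsbc import RawTable, SynthSpec, generate, make_worked_example

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_example():
    return make_worked_example()


@pytest.fixture
def mixed_table() -> RawTable:
    """A small mixed-type table with missing cells, as strings like a CSV."""
    frame = pd.DataFrame(
        {
            "age": ["63", "45", "", "71", "52", "39", "60", "48"],
            "marker": ["1.131", "-0.010", "1.351", "-0.110", "0.660", "1.411", "0.2", "0.3"],
            "smoker": ["yes", "no", "no", "?", "yes", "no", "no", "yes"],
            "class": ["pos", "neg", "neg", "pos", "pos", "neg", "neg", "pos"],
        }
    )
    return RawTable.from_dataframe(frame, label_column="class")


@pytest.fixture
def separable_table() -> RawTable:
    """Well-separated clusters, no missing data: learnable to BA = 1."""
    return generate(
        SynthSpec(
            n_samples=120,
            n_numeric=4,
            n_categorical=2,
            n_classes=2,
            ir=3.0,
            class_sep=8.0,
            spread=0.3,
            missing_rate=0.0,
            seed=3,
        )
    )
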
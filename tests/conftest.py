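import numpy as np
import pandas as pd
import pytest

from mirpain.screen import ExpressionMatrix


def make_matrix(values: dict, groups: dict, timepoint: str = "PID-8") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from dicts of columns and group labels."""
    frame = pd.DataFrame(values)
    design = pd.DataFrame(
        {
            "array_id": list(frame.columns),
            "group": [groups[c] for c in frame.columns],
            "replicate": list(range(1, len(frame.columns) + 1)),
            "timepoint": timepoint,
        }
    )
    return ExpressionMatrix(values=frame, design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """Two sham + two tumour arrays, three miRNAs, one clear up-regulation."""
    return make_matrix(
        {
            "s1": [100.0, 50.0, 10.0],
            "s2": [110.0, 55.0, 12.0],
            "t1": [300.0, 52.0, 11.0],
            "t2": [310.0, 51.0, 10.0],
        },
        {"s1": "sham", "s2": "sham", "t1": "tumour", "t2": "tumour"},
    )
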
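import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coredeg.io import NOTEST, TESTED, ContrastTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(rows, contrast_id="c", tuber_side="b") -> ContrastTable:
    """Build a ContrastTable from (locus, log2fc, p, q, status) tuples."""
    df = pd.DataFrame(
        rows, columns=["locus_id", "log2_fold_change", "p_value", "q_value", "status"]
    )
    df.insert(1, "fpkm_tuber", np.nan)
    df.insert(2, "fpkm_thin", np.nan)
    return ContrastTable(contrast_id, tuber_side, df)


@pytest.fixture
def four_locus_tables():
    """The hand-enumerable four-locus pair: directions (UP,UP,DOWN,NS) vs
    (UP,DOWN,DOWN,UP)."""
    t1 = make_table(
        [
            ("g1", 1.0, 0.001, 0.01, TESTED),
            ("g2", 2.0, 0.002, 0.01, TESTED),
            ("g3", -1.5, 0.003, 0.01, TESTED),
            ("g4", 0.5, 0.4, 0.6, TESTED),
        ],
        contrast_id="c1",
    )
    t2 = make_table(
        [
            ("g1", 0.8, 0.001, 0.01, TESTED),
            ("g2", -1.0, 0.002, 0.01, TESTED),
            ("g3", -2.0, 0.003, 0.01, TESTED),
            ("g4", 1.2, 0.004, 0.01, TESTED),
        ],
        contrast_id="c2",
    )
    return t1, t2


@pytest.fixture
def mixed_status_table():
    return make_table(
        [
            ("g1", 2.0, 0.001, 0.004, TESTED),
            ("g2", 3.0, 0.2, 0.2, TESTED),
            ("g3", np.nan, np.nan, np.nan, NOTEST),
            ("g4", -1.0, 0.01, 0.04, TESTED),
        ]
    )
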
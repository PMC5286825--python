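import numpy as np
import pandas as pd
import pytest

from panminer.io_formats import CASE, CONTROL, OmicsMatrix
from panminer.activity import BinaryTransactionMatrix, DiscretizedActivity


def two_class_labels(n_case, n_control, case_prefix="case", ctrl_prefix="ctrl"):
    samples = [f"{case_prefix}_{i+1}" for i in range(n_case)] \
        + [f"{ctrl_prefix}_{i+1}" for i in range(n_control)]
    labels = {s: (CASE if s.startswith(case_prefix) else CONTROL)
              for s in samples}
    return samples, labels


@pytest.fixture
def small_matrix():
    """10 genes x 12 samples (6/6), two genes shifted up in cases."""
    rng = np.random.default_rng(123)
    samples, labels = two_class_labels(6, 6)
    vals = rng.normal(0, 1, (10, 12))
    vals[0, :6] += 3.0
    vals[1, :6] += 3.0
    df = pd.DataFrame(vals, index=[f"g{i+1}" for i in range(10)],
                      columns=samples)
    return OmicsMatrix(df, labels)


@pytest.fixture
def toy_states():
    """4 pathways x 6 samples of hand-written -1/+1 states."""
    states = pd.DataFrame(
        [[+1, +1, +1, -1, -1, -1],
         [+1, +1, -1, -1, -1, +1],
         [-1, -1, -1, +1, +1, +1],
         [+1, -1, +1, -1, +1, -1]],
        index=["A", "B", "C", "D"],
        columns=[f"s{i+1}" for i in range(6)],
    )
    return DiscretizedActivity(states)


def transactions(rows: dict[str, list[int]], samples=None) -> BinaryTransactionMatrix:
    """Build a transaction matrix from raw 0/1 item rows (helper for tests
    that do not need the up/down pairing)."""
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i+1}" for i in range(df.shape[1])]
    return BinaryTransactionMatrix(df, n_pathways=df.shape[0] // 2 or 1)
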
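import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

# make the oracle helpers importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from mirnet.quant import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220722)


@pytest.fixture
def samples12():
    """4 stages x 3 replicates sample table."""
    rows = [
        {"sample": f"{st}_{r}", "stage": st, "replicate": r}
        for st in ("EndodorI", "EndodorII", "Ecodor", "BFlush")
        for r in (1, 2, 3)
    ]
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture
def count_matrix(rng, samples12):
    vals = pd.DataFrame(
        rng.poisson(100, size=(20, 12)).astype(float),
        index=[f"g{i:02d}" for i in range(20)],
        columns=samples12.index,
    )
    return ExpressionMatrix(vals, samples12, "count")


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
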
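import numpy as np
import pandas as pd
import pytest

from neutronet.io_formats import ExpressionMatrix, SampleDesign, TargetMap
from neutronet.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Compact bundle with every effect class planted."""
    return generate_dataset(SimConfig(n_genes=300, n_mirnas=20, targets_per_mirna=15, seed=1))


@pytest.fixture
def tiny_design():
    return SampleDesign({"s1": "JIA", "s2": "JIA", "s3": "JIA", "s4": "HC", "s5": "HC", "s6": "HC"})


def make_matrix(values, feature_ids=None, sample_ids=None, kind="gene"):
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids), kind)


@pytest.fixture
def make_expr():
    return make_matrix
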
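import numpy as np
import pandas as pd
import pytest

from droughtcross.expression import ExpressionMatrix


def make_metadata(species="Ath", conditions=("WW", "WD"),
                  timepoints=("T0", "T5", "T11", "T14"), replicates=3):
    rows = []
    for cond in conditions:
        for tp in timepoints:
            for rep in range(1, replicates + 1):
                sid = f"{species}_{cond}_{tp}_R{rep}"
                rows.append({"sample_id": sid, "species": species,
                             "condition": cond, "timepoint": tp,
                             "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def make_matrix(values, metadata, feature_ids=None, scale="tpm"):
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=feature_ids, columns=metadata.index)
    return ExpressionMatrix(df, metadata, scale)


@pytest.fixture
def meta24():
    """Standard single-species design: 2 conditions x 4 timepoints x 3 reps."""
    return make_metadata()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
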
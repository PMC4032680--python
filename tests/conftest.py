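import numpy as np
import pandas as pd
import pytest

from felicity import EPOCH_LABELS


@pytest.fixture(scope="session")
def toy_table() -> pd.DataFrame:
    """Four subjects x three epochs with a clear monotone epoch effect."""
    values = {"s1": (1, 2, 3), "s2": (2, 3, 5), "s3": (1, 1, 2), "s4": (3, 4, 6)}
    rows = []
    for subj, vals in values.items():
        for lab, v in zip(EPOCH_LABELS, vals):
            rows.append({"subject": subj, "epoch": lab, "score": float(v)})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_wide(toy_table) -> np.ndarray:
    return (toy_table.pivot(index="subject", columns="epoch", values="score")
            [list(EPOCH_LABELS)].to_numpy())
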
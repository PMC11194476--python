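import numpy as np
import pytest

from omicsubtypes.datamodel import MultiOmicsDataset, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, name="m", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return OmicsMatrix(
        name,
        [f"S{i + 1}" for i in range(n)],
        [f"{prefix}{j + 1}" for j in range(d)],
        values,
    )


@pytest.fixture
def tiny_dataset(rng):
    """One-view dataset, N=12, 3 of them lacking protein data."""
    X = rng.standard_normal((12, 6))
    P = X @ rng.standard_normal((6, 4))
    mask = np.ones(12, dtype=bool)
    mask[[2, 5, 9]] = False
    view = make_matrix(X, "view1")
    protein = make_matrix(P * mask[:, None], "protein", prefix="p")
    return MultiOmicsDataset([view], protein, mask)
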
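import numpy as np
import pytest

from tightscale import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs(rng, centers, sizes, sd, d=None):
    """Gaussian blobs around given centers; returns (matrix, labels)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    d = centers.shape[1] if d is None else d
    rows, labels = [], []
    sds = np.broadcast_to(np.asarray(sd, dtype=float), (len(sizes),))
    for i, (c, m) in enumerate(zip(centers, sizes)):
        rows.append(c + rng.normal(0, sds[i], size=(m, d)))
        labels.append(np.full(m, i + 1))
    X = np.vstack(rows)
    lab = np.concatenate(labels)
    return ExpressionMatrix(X), lab


@pytest.fixture
def blob_builder():
    return make_blobs
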
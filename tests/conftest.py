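import numpy as np
import pytest

from scsga.signal_io import Recording
from scsga.simulate import EASY_REGIME, sample_sparse_var, simulate_var


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_rec(rng):
    """4-channel Gaussian recording."""
    return Recording(data=rng.normal(size=(4, 300)), srate=200.0)


@pytest.fixture(scope="session")
def easy_truth():
    return sample_sparse_var(EASY_REGIME)


@pytest.fixture(scope="session")
def easy_rec(easy_truth):
    rec = simulate_var(easy_truth, EASY_REGIME)
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return Recording(data=data, srate=rec.srate, channel_names=rec.channel_names)


def support_f1(G: np.ndarray, true_support: np.ndarray, percentile: float = 90.0) -> float:
    """Edge-support F1 after thresholding the network at a percentile."""
    thr = np.percentile(G, percentile)
    pred = G > thr
    np.fill_diagonal(pred, False)
    truth = true_support.copy()
    np.fill_diagonal(truth, False)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0
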
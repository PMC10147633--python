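import numpy as np
import pytest

import qmcscope as q


@pytest.fixture()
def rng():
    return np.random.default_rng(20230428)


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless simulated acquisition plus its ground truth."""
    cfg = q.SimConfig(n_frames=400, region_shape=(12, 10), mu_coin=0.3, seed=3)
    left, right, truth = q.simulate_stacks(cfg)
    return cfg, left, right, truth


@pytest.fixture(scope="session")
def default_point():
    """Default operating-point acquisition (0.49 photon budget split)."""
    cfg = q.default_config(20000, (24, 24), seed=5)
    left, right, truth = q.simulate_stacks(cfg)
    return cfg, left, right, truth


def two_pass_covariance(left, right, chunk=2000):
    """Independent oracle: naive two-pass population covariance of the
    full-flip registered pair, cov(L(p), R(S-p)) with S the full flip.
    Processed in frame blocks only to bound memory; the arithmetic is the
    plain textbook two-pass formula."""
    l = np.asarray(left)
    r = np.asarray(right)[:, ::-1, ::-1]
    n = l.shape[0]
    mean_l = np.zeros(l.shape[1:])
    mean_r = np.zeros(r.shape[1:])
    for i in range(0, n, chunk):
        mean_l += l[i : i + chunk].astype(np.float64).sum(axis=0)
        mean_r += r[i : i + chunk].astype(np.float64).sum(axis=0)
    mean_l /= n
    mean_r /= n
    acc = np.zeros(l.shape[1:])
    for i in range(0, n, chunk):
        dl = l[i : i + chunk].astype(np.float64) - mean_l
        dr = r[i : i + chunk].astype(np.float64) - mean_r
        acc += (dl * dr).sum(axis=0)
    return acc / n
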
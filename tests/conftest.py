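import numpy as np
import pytest

from dfcrnn import model as M
from dfcrnn import synthetic as S
from dfcrnn.io_cohort import trim_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A scaled-down architecture for fast exact checks (no dropout)."""
    return M.CrnnConfig(
        s1=2, s2=2, s3=3, k1=2, k2=3, k3=4, stride3_time=2,
        lstm_hidden=5, fc_sizes=(4, 3), n_classes=2, dropout_rate=0.0,
    )


@pytest.fixture
def tiny_batch(rng, tiny_cfg):
    """Random symmetric (B, T, N, N) batch compatible with tiny_cfg."""
    B, T, N = 3, 10, 4
    X = rng.standard_normal((B, T, N, N))
    return (X + X.transpose(0, 1, 3, 2)) / 2


@pytest.fixture(scope="session")
def small_separable_cohort():
    """Trimmed two-group cohort with a strong injected covariance difference
    (8 subjects per group, 12 ROIs) — small enough for unit tests."""
    cfg = S.separable_config(n_subjects_per_group=8, n_rois=12, delta=0.8, seed=7)
    return trim_cohort(S.simulate_cohort(cfg), 3)
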
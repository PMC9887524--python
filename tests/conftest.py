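import numpy as np
import pytest

from spcnv import Bin

# ten 2-D objects used throughout the scoring tests; object 1 (index 0)
# has nearest neighbours 6, 7, 8, 5, 4 at k = 5
TEN_POINTS = [
    (0.5, 0.5),
    (0.13, 0.78),
    (0.18, 0.13),
    (0.2, 0.4),
    (0.32, 0.38),
    (0.47, 0.44),
    (0.56, 0.6),
    (0.6, 0.56),
    (0.87, 0.5),
    (0.91, 0.93),
]


@pytest.fixture
def ten_points():
    return list(TEN_POINTS)


def make_bins(rcs, chrom="chr1", bin_size=1000, gcs=None, has_n=None):
    """Build a uniform bin list from bare read counts."""
    n = len(rcs)
    gcs = gcs if gcs is not None else [0.5] * n
    has_n = has_n if has_n is not None else [False] * n
    return [
        Bin(
            chrom=chrom,
            start=i * bin_size,
            end=(i + 1) * bin_size,
            gc=float(gcs[i]),
            has_n=bool(has_n[i]),
            rc=float(rcs[i]),
        )
        for i in range(n)
    ]


@pytest.fixture
def bin_factory():
    return make_bins


def tv_oracle(y, lam):
    """Independent fused-lasso minimizer via the dual box-constrained QP.

    x minimises (1/2)||x-y||^2 + lam*TV(x) iff x = y - D^T z with z the
    projection solving min ||D^T z - y||^2 over the box |z_i| <= lam.
    """
    from scipy.optimize import lsq_linear

    y = np.asarray(y, dtype=float)
    n = y.size
    if lam == 0 or n == 1:
        return y.copy()
    D = np.zeros((n - 1, n))
    for i in range(n - 1):
        D[i, i] = -1.0
        D[i, i + 1] = 1.0
    res = lsq_linear(D.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=1000)
    return y - D.T @ res.x


@pytest.fixture
def tv_brute_force():
    return tv_oracle
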
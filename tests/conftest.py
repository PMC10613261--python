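"""Shared fixtures: small synthetic datasets and independent oracles."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from xpfine.io import AlignedDataset, LDMatrix, SummaryStats


def make_aligned(p=6, seed=1, rho=(0.3, 0.8), n=(5000, 8000),
                 c=(1.0, 1.0), signal=None):
    """Two-population null dataset with AR(1) LD and equal per-SNP SEs.

    ``signal``: optional {snp_index: (b1_shift, b2_shift)} added to the
    marginal effects after the null draw.
    """
    r = np.random.default_rng(seed)
    ids = np.array([f"s{i}" for i in range(p)], dtype=object)
    stats, lds = [], []
    for t in range(2):
        R = rho[t] ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        L = np.linalg.cholesky(R)
        s = 1.0 / np.sqrt(n[t])
        bhat = np.sqrt(c[t]) * s * (L @ r.standard_normal(p))
        if signal:
            for j, shifts in signal.items():
                bhat[j] += shifts[t]
        stats.append(SummaryStats(ids, np.full(p, "A"), np.full(p, "G"),
                                  bhat, np.full(p, s), np.full(p, n[t])))
        lds.append(LDMatrix(ids, R))
    return AlignedDataset(stats=stats, lds=lds)


def enumeration_posterior(data, Sigma1, c=(1.0, 1.0)):
    """Exact single-effect posterior and log evidence by enumerating the p
    causal configurations under the multivariate-normal summary likelihood
    with bivariate effect prior N(0, Sigma1).  Independent of the VEM."""
    p = data.p
    bstack = np.concatenate([st.bhat for st in data.stats])
    V0 = np.zeros((2 * p, 2 * p))
    for t in range(2):
        s2 = data.stats[t].se[0] ** 2
        V0[t * p:(t + 1) * p, t * p:(t + 1) * p] = c[t] * s2 * data.lds[t].R
    loglik = np.zeros(p)
    for j in range(p):
        A = np.zeros((2 * p, 2))
        for t in range(2):
            A[t * p:(t + 1) * p, t] = data.lds[t].R[:, j]
        V = V0 + A @ Sigma1 @ A.T
        loglik[j] = multivariate_normal.logpdf(bstack, mean=np.zeros(2 * p), cov=V)
    logpost = loglik - np.log(p)
    logev = logsumexp(logpost)
    return np.exp(logpost - logev), float(logev)


@pytest.fixture
def aligned_factory():
    return make_aligned


@pytest.fixture
def enum_oracle():
    return enumeration_posterior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
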
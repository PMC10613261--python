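"""LD score regression: polygenic (co)variance and inflation constants.

The first stage of the two-step fitting procedure.  Genome-wide chi-square
statistics are regressed on LD scores; the intercept ``c`` measures
confounding inflation and the slope gives the per-SNP heritability
``omega``.  The cross-population analogue regresses ``z1*z2`` on
cross-population LD scores ``ell_cross_j = sum_l r1_jl * r2_jl`` through the
origin (no shared samples across populations), yielding the per-SNP
co-heritability ``omega12``.  The resulting 2x2 polygenic covariance and
the intercepts are then held fixed while the sparse causal components are
fitted at the target locus.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError
from .io import LDMatrix

log = logging.getLogger(__name__)

_MIN_SNPS = 50


@dataclass
class LDScores:
    """Per-SNP LD scores, optionally with a cross-population column."""

    snp_id: np.ndarray
    ell: np.ndarray
    ell_cross: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ell = np.asarray(self.ell, dtype=float)
        if self.ell.shape[0] != self.snp_id.shape[0]:
            raise InputError("LD score length does not match SNP list")
        if self.ell_cross is not None:
            self.ell_cross = np.asarray(self.ell_cross, dtype=float)
            if self.ell_cross.shape != self.ell.shape:
                raise InputError("cross LD score length mismatch")


@dataclass
class PolygenicParams:
    """Fixed hyper-parameters of the dense background component.

    ``omega`` is the 2x2 per-SNP polygenic covariance (PSD); ``c`` holds the
    per-population inflation constants (LDSC intercepts, > 0).  An all-zero
    ``omega`` disables the polygenic component.
    """

    omega: np.ndarray
    c: np.ndarray
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.omega.shape != (self.T, self.T):
            raise ConfigurationError("omega must be T x T")
        if np.max(np.abs(self.omega - self.omega.T)) > 1e-12:
            raise ConfigurationError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(self.omega) < -1e-15):
            raise ConfigurationError("omega must be positive semi-definite")
        if np.any(self.c <= 0):
            raise ConfigurationError("inflation constants must be > 0")

    @property
    def T(self) -> int:
        return self.c.shape[0]

    @property
    def polygenic_enabled(self) -> bool:
        return bool(np.any(self.omega != 0.0))

    @classmethod
    def disabled(cls, c: tuple[float, float] = (1.0, 1.0)) -> "PolygenicParams":
        """Parameters with the polygenic component switched off (omega = 0)."""
        T = len(c)
        return cls(omega=np.zeros((T, T)), c=np.asarray(c, dtype=float))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "omega": self.omega.tolist(),
            "c": self.c.tolist(),
            "se": {k: float(v) for k, v in self.se.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PolygenicParams":
        payload = json.loads(Path(path).read_text())
        return cls(omega=np.asarray(payload["omega"], dtype=float),
                   c=np.asarray(payload["c"], dtype=float),
                   se=payload.get("se", {}))


@dataclass
class LDSCFit:
    """Univariate LDSC result: intercept ``c`` and per-SNP heritability."""

    c: float
    omega: float
    c_se: float
    omega_se: float
    n_snps: int
    n_blocks: int


@dataclass
class BivariateLDSCFit:
    """Bivariate LDSC result: per-SNP co-heritability across populations."""

    omega12: float
    omega12_se: float
    n_snps: int
    n_blocks: int


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------


def compute_ld_scores(R: LDMatrix, R_other: LDMatrix | None = None) -> LDScores:
    """LD scores ``ell_j = sum_l r_jl^2`` (and cross scores when two
    populations are given: ``ell_cross_j = sum_l r1_jl * r2_jl``)."""
    ell = np.einsum("jl,jl->j", R.R, R.R)
    ell_cross = None
    if R_other is not None:
        if not np.array_equal(R.snp_id, R_other.snp_id):
            raise InputError("LD matrices must share one SNP order")
        ell_cross = np.einsum("jl,jl->j", R.R, R_other.R)
    return LDScores(R.snp_id, ell, ell_cross)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


def _outlier_mask(chi2: np.ndarray, n: float) -> np.ndarray:
    """Standard LDSC convention: drop SNPs with chi2 > max(80, 0.001 n)."""
    return chi2 <= max(80.0, 0.001 * n)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T @ y)


def _block_jackknife(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                     n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-block jackknife estimates and SEs of WLS coefficients.

    Blocks are contiguous in the (genome-ordered) SNP sequence, so the
    jackknife respects local LD correlation between chi-square statistics.
    """
    m, k = X.shape
    n_blocks = int(min(n_blocks, max(2, m // 2)))
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    Xw = X * w[:, None]
    xtx_total = X.T @ Xw
    xty_total = Xw.T @ y
    full = np.linalg.solve(xtx_total, xty_total)
    deletions = np.empty((n_blocks, k))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xtx_b = X[sl].T @ Xw[sl]
        xty_b = Xw[sl].T @ y[sl]
        deletions[b] = np.linalg.solve(xtx_total - xtx_b, xty_total - xty_b)
    pseudo = n_blocks * full[None, :] - (n_blocks - 1) * deletions
    est = pseudo.mean(axis=0)
    se = np.sqrt(pseudo.var(axis=0, ddof=1) / n_blocks)
    return est, se


def fit_univariate_ldsc(z: np.ndarray, scores: LDScores, n: float,
                        M: int | None = None, n_blocks: int = 200) -> LDSCFit:
    """Regress chi-square statistics on LD scores.

    Fitted model: ``chi2_j ~ c + n * omega * ell_j`` by weighted least
    squares with 1/max(ell, 1) heteroskedasticity weights and one
    reweighting pass; the slope estimate is floored at zero.  ``M`` is
    unused in the per-SNP parameterization and accepted for interface
    compatibility with total-heritability reporting.
    """
    z = np.asarray(z, dtype=float)
    ell = scores.ell
    if z.shape != ell.shape:
        raise InputError("z and LD scores must have equal length")
    if z.shape[0] < _MIN_SNPS:
        warnings.warn(f"only {z.shape[0]} SNPs for LDSC; estimates are unstable",
                      stacklevel=2)
    chi2 = z ** 2
    keep = _outlier_mask(chi2, n) & np.isfinite(chi2) & np.isfinite(ell)
    x, y = ell[keep], chi2[keep]
    m = x.shape[0]
    if m < 2 or np.ptp(x) < 1e-12:
        warnings.warn("constant LD scores: slope unidentifiable, omega set to 0",
                      stacklevel=2)
        w = 1.0 / np.maximum(x, 1.0) if m else np.ones(1)
        c = float(np.average(y, weights=w)) if m else 1.0
        return LDSCFit(c=c, omega=0.0, c_se=float("nan"),
                       omega_se=float("nan"), n_snps=m, n_blocks=0)

    X = np.column_stack([np.ones(m), x])
    w = 1.0 / np.maximum(x, 1.0)
    coef = _wls(X, y, w)
    fitted = np.maximum(X @ coef, 0.1)
    w = 1.0 / (np.maximum(x, 1.0) * fitted ** 2)
    (c, slope), (c_se, slope_se) = _block_jackknife(X, y, w, n_blocks)
    return LDSCFit(c=float(c), omega=float(max(slope, 0.0) / n),
                   c_se=float(c_se), omega_se=float(slope_se / n),
                   n_snps=m, n_blocks=int(min(n_blocks, max(2, m // 2))))


def fit_bivariate_ldsc(z1: np.ndarray, z2: np.ndarray, scores: LDScores,
                       n1: float, n2: float, M: int | None = None,
                       n_blocks: int = 200) -> BivariateLDSCFit:
    """Regress ``z1*z2`` on cross-population LD scores through the origin.

    The intercept is fixed at zero because the two populations' GWAS share
    no samples.  The slope equals ``sqrt(n1*n2) * omega12``.
    """
    if scores.ell_cross is None:
        raise ConfigurationError("cross-population LD scores (ell_cross) required")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape or z1.shape != scores.ell_cross.shape:
        raise InputError("z1, z2 and cross LD scores must share one SNP order")
    y = z1 * z2
    keep = (_outlier_mask(z1 ** 2, n1) & _outlier_mask(z2 ** 2, n2)
            & np.isfinite(y) & np.isfinite(scores.ell_cross))
    x = scores.ell_cross[keep]
    yk = y[keep]
    w = 1.0 / np.maximum(scores.ell[keep], 1.0)
    X = x[:, None]
    (slope,), (slope_se,) = _block_jackknife(X, yk, w, n_blocks)
    scale = np.sqrt(n1 * n2)
    return BivariateLDSCFit(omega12=float(slope / scale),
                            omega12_se=float(slope_se / scale),
                            n_snps=int(keep.sum()),
                            n_blocks=int(min(n_blocks, max(2, keep.sum() // 2))))


def estimate_polygenic_params(z1: np.ndarray, z2: np.ndarray,
                              scores1: LDScores, scores2: LDScores,
                              scores_cross: LDScores,
                              n1: float, n2: float,
                              n_blocks: int = 200,
                              clamp_c: bool = True) -> PolygenicParams:
    """Two univariate fits plus one bivariate fit, assembled into a valid
    (PSD, positive-intercept) parameter set for the fine-mapping stage.

    ``clamp_c`` floors the intercepts at 1: an estimated deflation (c < 1)
    would tighten the GWAS standard errors and overstate the evidence, so by
    default c < 1 is treated as "no confounding".  ``omega12`` is clamped so
    the 2x2 covariance stays PSD.
    """
    fit1 = fit_univariate_ldsc(z1, scores1, n1, n_blocks=n_blocks)
    fit2 = fit_univariate_ldsc(z2, scores2, n2, n_blocks=n_blocks)
    fitx = fit_bivariate_ldsc(z1, z2, scores_cross, n1, n2, n_blocks=n_blocks)
    w1, w2 = fit1.omega, fit2.omega
    if max(w1, w2) > 0:
        # keep the assembled covariance strictly invertible: a zero variance
        # estimate in one population would otherwise make omega singular
        floor = 1e-6 * max(w1, w2)
        w1, w2 = max(w1, floor), max(w2, floor)
    bound = 0.999 * np.sqrt(w1 * w2)
    w12 = float(np.clip(fitx.omega12, -bound, bound))
    c1, c2 = fit1.c, fit2.c
    if clamp_c:
        c1, c2 = max(c1, 1.0), max(c2, 1.0)
    else:
        c1, c2 = max(c1, 1e-6), max(c2, 1e-6)
    return PolygenicParams(
        omega=np.array([[w1, w12], [w12, w2]]),
        c=np.array([c1, c2]),
        se={"c1": fit1.c_se, "c2": fit2.c_se,
            "omega1": fit1.omega_se, "omega2": fit2.omega_se,
            "omega12": fitx.omega12_se},
    )
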
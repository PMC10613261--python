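"""Variational EM for cross-population sum-of-single-effects fine-mapping.

Model (per population t, with LD matrix R_t, marginal effects bhat_t and
standard errors s_t on standardized genotypes):

    bhat_t ~ N( R_t (sum_k gamma_k beta_tk + phi_t),  c_t S_t R_t S_t )

where each of K causal components places exactly one causal SNP through the
categorical indicator gamma_k, the bivariate effect (beta_1k, beta_2k) has
prior N(0, Sigma_k), and the dense polygenic effects phi_tj are bivariate
normal across populations with per-SNP covariance Omega.  The inflation
constants c_t rescale the summary-statistic noise to absorb confounding.

Omega and c are fixed (estimated genome-wide by LDSC beforehand); the VEM
updates the variational posterior and the Sigma_k only.  The variational
family factorizes over components and the polygenic vector; each component
posterior is a categorical over SNPs times a bivariate normal for the
effect given its position, which contains the exact single-effect posterior
and makes the coordinate updates closed-form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import softmax

from .errors import ConfigurationError, InputError, NumericalError
from .io import AlignedDataset
from .ldsc import PolygenicParams

log = logging.getLogger(__name__)

_RIDGE = 1e-10
_FREEZE_TRACE = 1e-12


# ---------------------------------------------------------------------------
# small 2x2 helpers (vectorized over the SNP axis)
# ---------------------------------------------------------------------------


def _inv2(A: np.ndarray) -> np.ndarray:
    """Inverse of a stack of 2x2 matrices."""
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1]
    out[..., 1, 1] = A[..., 0, 0]
    out[..., 0, 1] = -A[..., 0, 1]
    out[..., 1, 0] = -A[..., 1, 0]
    return out / det[..., None, None]


def _logdet2(A: np.ndarray) -> np.ndarray:
    return np.log(A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0])


def _safe_inv_sigma(Sigma_k: np.ndarray) -> np.ndarray:
    """2x2 inverse with a ridge retry for near-singular prior covariances."""
    det = Sigma_k[0, 0] * Sigma_k[1, 1] - Sigma_k[0, 1] * Sigma_k[1, 0]
    if not np.isfinite(det) or det <= 0:
        Sigma_k = Sigma_k + _RIDGE * np.eye(2)
        det = Sigma_k[0, 0] * Sigma_k[1, 1] - Sigma_k[0, 1] * Sigma_k[1, 0]
        if det <= 0:
            raise NumericalError("component covariance not invertible after ridge")
    return _inv2(Sigma_k)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class CausalComponentParams:
    """Per-component 2x2 effect covariances Sigma_k, k = 1..K."""

    Sigma: np.ndarray  # (K, 2, 2)

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.ndim != 3 or self.Sigma.shape[1:] != (2, 2):
            raise ConfigurationError("Sigma must have shape (K, 2, 2)")

    @property
    def K(self) -> int:
        return self.Sigma.shape[0]


@dataclass
class VariationalState:
    """Variational posterior: categorical weights, conditional effect
    moments per component/SNP, and the polygenic posterior mean."""

    pi: np.ndarray        # (K, p) categorical posteriors, rows sum to 1
    mu: np.ndarray        # (K, p, 2) conditional effect means
    Sigma_tilde: np.ndarray  # (K, p, 2, 2) conditional effect covariances
    nu: np.ndarray        # (T, p) polygenic posterior mean

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.pi.shape[1]

    def component_mean(self, k: int) -> np.ndarray:
        """(T, p) posterior mean of gamma_k * beta_tk."""
        return (self.pi[k][:, None] * self.mu[k]).T

    def total_causal_mean(self) -> np.ndarray:
        """(T, p) posterior mean of the summed sparse effects."""
        return np.einsum("kp,kpt->tp", self.pi, self.mu)

    def copy(self) -> "VariationalState":
        return VariationalState(self.pi.copy(), self.mu.copy(),
                                self.Sigma_tilde.copy(), self.nu.copy())


@dataclass
class FitResult:
    """Converged fit: variational state, Sigma estimates, PIPs, diagnostics."""

    state: VariationalState
    Sigma_hat: CausalComponentParams
    elbo_trace: np.ndarray
    pip: np.ndarray
    n_iter: int
    converged: bool
    active: np.ndarray  # (K,) mask; frozen (degenerate) components are False
    snp_id: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# per-fit precomputation
# ---------------------------------------------------------------------------


class PolygenicSolver:
    """Posterior solver for the dense background component.

    The posterior covariance Lambda = (blockdiag(S_t^-1 R_t S_t^-1 / c_t)
    + Omega^-1 kron I_p)^-1 involves only fixed quantities, so its Cholesky
    factorization is computed once per fit; each iteration then solves for
    the posterior mean nu at O(p^2) cost.  ``dense_covariance`` materializes
    Lambda for validation against a direct inverse.
    """

    def __init__(self, W_blocks: list[np.ndarray], omega: np.ndarray) -> None:
        T = len(W_blocks)
        p = W_blocks[0].shape[0]
        try:
            omega_inv = np.linalg.inv(omega)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "singular Omega; pass omega = 0 to disable the polygenic "
                "component") from exc
        M = np.zeros((T * p, T * p))
        for t in range(T):
            sl = slice(t * p, (t + 1) * p)
            M[sl, sl] = W_blocks[t]
        M += np.kron(omega_inv, np.eye(p))
        self.T, self.p = T, p
        self.omega_inv = omega_inv
        self._cho = cho_factor(M, lower=True)
        # log|Lambda| = -log|M|
        self.logdet_lambda = -2.0 * float(np.sum(np.log(np.diag(self._cho[0]))))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """nu = Lambda @ rhs for a stacked (T*p,) right-hand side."""
        return cho_solve(self._cho, rhs)

    def dense_covariance(self) -> np.ndarray:
        return cho_solve(self._cho, np.eye(self.T * self.p))


class _FitContext:
    """Cached per-fit arrays: scaled evidence, per-SNP precisions, solver."""

    def __init__(self, data: AlignedDataset, params: PolygenicParams) -> None:
        if params.T != data.T:
            raise ConfigurationError("params and data disagree on the number "
                                     "of populations")
        self.data = data
        self.params = params
        self.T, self.p = data.T, data.p
        self.R = [ld.R for ld in data.lds]
        self.s = np.stack([st.se for st in data.stats])          # (T, p)
        self.bhat = np.stack([st.bhat for st in data.stats])     # (T, p)
        if not np.all(np.isfinite(self.bhat)) or not np.all(np.isfinite(self.s)):
            raise InputError("non-finite values in harmonized inputs")
        self.c = params.c
        r_diag = np.stack([np.diag(R) for R in self.R])          # (T, p)
        cs2 = self.c[:, None] * self.s ** 2
        self.A = r_diag / cs2                                    # (T, p)
        self.d = self.bhat / cs2                                 # (T, p)
        self.poly_enabled = params.polygenic_enabled
        self.solver: PolygenicSolver | None = None
        if self.poly_enabled:
            W_blocks = [self.R[t] / (self.c[t] * np.outer(self.s[t], self.s[t]))
                        for t in range(self.T)]
            self.solver = PolygenicSolver(W_blocks, params.omega)

    def W_matvec(self, t: int, v: np.ndarray) -> np.ndarray:
        """(S_t^-1 R_t S_t^-1 / c_t) @ v without forming the matrix."""
        return (self.R[t] @ (v / self.s[t])) / (self.s[t] * self.c[t])


def initial_state(data: AlignedDataset, K: int) -> VariationalState:
    """Deterministic start: uniform categorical weights, zero means."""
    p, T = data.p, data.T
    return VariationalState(
        pi=np.full((K, p), 1.0 / p),
        mu=np.zeros((K, p, 2)),
        Sigma_tilde=np.zeros((K, p, 2, 2)),
        nu=np.zeros((T, p)),
    )


# ---------------------------------------------------------------------------
# coordinate updates
# ---------------------------------------------------------------------------


def _estep_component(ctx: _FitContext, k: int, state: VariationalState,
                     Sigma_k: np.ndarray,
                     total_mean: np.ndarray) -> np.ndarray:
    """Update (pi_k, mu_k, Sigma_tilde_k) in place given the other
    components' expected effects; returns the new (T, p) component mean.

    The evidence for SNP j is residualized against all components k' != k
    and the polygenic posterior mean, weighted through the LD matrix.
    """
    T, p = ctx.T, ctx.p
    comp_mean = state.component_mean(k)                    # (T, p)
    resid = total_mean - comp_mean + state.nu              # (T, p)
    numer = np.empty((T, p))
    for t in range(T):
        numer[t] = (ctx.bhat[t] - ctx.R[t] @ resid[t]) / (ctx.c[t] * ctx.s[t] ** 2)

    sig_inv = _safe_inv_sigma(Sigma_k)
    prec = np.broadcast_to(sig_inv, (p, 2, 2)).copy()
    prec[:, 0, 0] += ctx.A[0]
    prec[:, 1, 1] += ctx.A[1]
    Sigma_tilde = _inv2(prec)                              # (p, 2, 2)
    mu = np.einsum("pij,jp->pi", Sigma_tilde, numer)       # (p, 2)
    logits = (-np.log(p) + 0.5 * _logdet2(Sigma_tilde)
              + 0.5 * np.einsum("pi,ip->p", mu, numer))
    pi = softmax(logits)

    state.pi[k] = pi
    state.mu[k] = mu
    state.Sigma_tilde[k] = Sigma_tilde
    return (pi[:, None] * mu).T


def _update_polygenic(ctx: _FitContext, state: VariationalState,
                      total_mean: np.ndarray) -> None:
    """Update the polygenic posterior mean nu in place (Lambda is fixed)."""
    if not ctx.poly_enabled:
        state.nu[:] = 0.0
        return
    rhs = np.empty((ctx.T, ctx.p))
    for t in range(ctx.T):
        rhs[t] = ctx.d[t] - ctx.W_matvec(t, total_mean[t])
    state.nu[:] = ctx.solver.solve(rhs.ravel()).reshape(ctx.T, ctx.p)


def _mstep_sigma(state: VariationalState) -> np.ndarray:
    """Sigma_k <- sum_j pi_kj (mu_kj mu_kj' + Sigma_tilde_kj); PSD by
    construction (posterior-weighted second moments)."""
    outer = np.einsum("kpi,kpj->kpij", state.mu, state.mu)
    return np.einsum("kp,kpij->kij", state.pi, outer + state.Sigma_tilde)


def _compute_elbo(ctx: _FitContext, state: VariationalState,
                  Sigma: np.ndarray, active: np.ndarray) -> float:
    """Evidence lower bound, up to an additive constant that depends only
    on the data and the fixed (Omega, c); see the module docstring."""
    T, p, K = ctx.T, ctx.p, state.K
    comp_means = np.einsum("kp,kpt->ktp", state.pi, state.mu)   # (K, T, p)
    m = comp_means.sum(axis=0) + state.nu                       # (T, p)

    elbo = 0.0
    # linear and quadratic evidence terms
    for t in range(T):
        Wm = ctx.W_matvec(t, m[t])
        elbo += float(m[t] @ ctx.d[t]) - 0.5 * float(m[t] @ Wm)
        for k in range(K):
            Wb = ctx.W_matvec(t, comp_means[k, t])
            elbo += 0.5 * float(comp_means[k, t] @ Wb)
    # exact per-SNP second moments of the one-hot effects
    second = (state.mu ** 2
              + state.Sigma_tilde[..., [0, 1], [0, 1]])          # (K, p, 2)
    elbo -= 0.5 * float(np.einsum("kp,tp,kpt->", state.pi, ctx.A, second))

    # categorical prior + entropy
    with np.errstate(divide="ignore", invalid="ignore"):
        logpi = np.where(state.pi > 0, np.log(np.maximum(state.pi, 1e-300)), 0.0)
    elbo += float(np.sum(state.pi * (-np.log(p) - logpi)))

    # effect prior + conditional entropy (2x2 Gaussians)
    for k in range(K):
        if not active[k]:
            continue
        sig_inv = _safe_inv_sigma(Sigma[k])
        det = Sigma[k][0, 0] * Sigma[k][1, 1] - Sigma[k][0, 1] * Sigma[k][1, 0]
        logdet_sig = (np.log(det) if det > 0
                      else _logdet2(Sigma[k] + _RIDGE * np.eye(2)))
        Mkj = (np.einsum("pi,pj->pij", state.mu[k], state.mu[k])
               + state.Sigma_tilde[k])
        tr = np.einsum("ij,pji->p", sig_inv, Mkj)
        with np.errstate(divide="ignore"):
            logdet_tilde = _logdet2(state.Sigma_tilde[k])
        elbo += float(np.sum(state.pi[k] * (
            0.5 * (logdet_tilde - logdet_sig) - 0.5 * tr + 1.0)))

    # polygenic prior + entropy; trace terms against Lambda are constant
    if ctx.poly_enabled:
        omega_inv = ctx.solver.omega_inv
        elbo -= 0.5 * float(np.einsum("tp,ts,sp->", state.nu, omega_inv, state.nu))
        sign, logdet_omega = np.linalg.slogdet(ctx.params.omega)
        elbo += 0.5 * ctx.solver.logdet_lambda - 0.5 * p * logdet_omega
    return elbo


# ---------------------------------------------------------------------------
# public single-step API (thin wrappers used directly in tests/diagnostics)
# ---------------------------------------------------------------------------


def estep_update_component(k: int, state: VariationalState, data: AlignedDataset,
                           params: PolygenicParams, Sigma_k: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One coordinate update of component k; returns (pi_k, mu_k, Sigma_tilde_k)."""
    ctx = _FitContext(data, params)
    state = state if isinstance(state, VariationalState) else state
    total = state.total_causal_mean()
    _estep_component(ctx, k, state, np.asarray(Sigma_k, dtype=float), total)
    return state.pi[k], state.mu[k], state.Sigma_tilde[k]


def update_polygenic(state: VariationalState, data: AlignedDataset,
                     params: PolygenicParams,
                     ) -> tuple[np.ndarray, np.ndarray | None]:
    """Polygenic posterior update; returns (nu, Lambda) with Lambda dense
    (None when the component is disabled via omega = 0)."""
    ctx = _FitContext(data, params)
    if not ctx.poly_enabled:
        state.nu[:] = 0.0
        return state.nu, None
    _update_polygenic(ctx, state, state.total_causal_mean())
    return state.nu, ctx.solver.dense_covariance()


def compute_elbo(state: VariationalState, data: AlignedDataset,
                 params: PolygenicParams, Sigma: CausalComponentParams,
                 active: np.ndarray | None = None) -> float:
    """ELBO up to the data/(Omega, c)-dependent additive constant."""
    ctx = _FitContext(data, params)
    if active is None:
        active = np.ones(Sigma.K, dtype=bool)
    return _compute_elbo(ctx, state, Sigma.Sigma, active)


def mstep_sigma(state: VariationalState) -> CausalComponentParams:
    """M-step update of every component covariance."""
    return CausalComponentParams(_mstep_sigma(state))


def elbo_constant(data: AlignedDataset, params: PolygenicParams) -> float:
    """The additive constant omitted from :func:`compute_elbo`, valid when
    all populations have equal per-SNP standard errors (then the working
    linear evidence term equals the exact one and ELBO + constant is a true
    lower bound on the log evidence)."""
    const = 0.0
    for t, (st, ld) in enumerate(zip(data.stats, data.lds)):
        s2 = float(st.se[0] ** 2)
        if np.ptp(st.se) > 1e-12 * s2:
            raise ConfigurationError("exact constant requires equal SEs")
        V = params.c[t] * s2 * ld.R
        sign, logdet = np.linalg.slogdet(2 * np.pi * V)
        sol = np.linalg.solve(V, st.bhat)
        const += -0.5 * float(st.bhat @ sol) - 0.5 * logdet
    return const


# ---------------------------------------------------------------------------
# outer fit loop
# ---------------------------------------------------------------------------


def fit_xmap(data: AlignedDataset, K: int, params: PolygenicParams, *,
             tol: float = 1e-4, max_iter: int = 200,
             sigma2_init: float | None = None,
             fix_sigma: bool = False,
             freeze_trace: float = _FREEZE_TRACE) -> FitResult:
    """Fit the cross-population sum-of-single-effects model.

    The polygenic posterior is updated once at initialization (its exact
    conditional optimum given the zero-initialized components), so that the
    dense background is in place before any sparse component updates: with
    the background posterior started at zero, the first component sweep
    would otherwise claim high-LD polygenic signal and coordinate ascent
    would converge to an overconfident basin.  One outer iteration then
    runs sequential coordinate updates of the K causal components (each
    seeing the others' current expected effects), the polygenic posterior
    update, and the M-step for all Sigma_k.  Omega and the inflation
    constants stay fixed throughout (two-step design).
    Components whose Sigma_k collapses below ``freeze_trace`` are frozen as
    inactive: they contribute neither residual evidence nor PIPs.

    Convergence: |delta ELBO| < tol, or ``max_iter`` sweeps (the result is
    then returned with ``converged=False`` and a warning).

    ``fix_sigma`` skips the M-step, keeping every Sigma_k at its
    initialization (useful for diagnostics and for checking the variational
    posterior against exact enumeration at a known prior).
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    ctx = _FitContext(data, params)
    p = ctx.p
    if sigma2_init is None:
        sigma2_init = 1.0 / p
    sigma2_init = np.asarray(sigma2_init, dtype=float)
    if sigma2_init.ndim == 0:
        Sigma = np.tile(np.diag([float(sigma2_init)] * 2), (K, 1, 1))
    else:
        if sigma2_init.shape != (K, 2, 2):
            raise ConfigurationError("sigma2_init must be scalar or (K, 2, 2)")
        Sigma = sigma2_init.copy()
    state = initial_state(data, K)
    active = np.ones(K, dtype=bool)
    _update_polygenic(ctx, state, state.total_causal_mean())

    elbo_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        total = state.total_causal_mean()
        for k in range(K):
            if not active[k]:
                continue
            old = state.component_mean(k)
            new = _estep_component(ctx, k, state, Sigma[k], total)
            total = total - old + new
        _update_polygenic(ctx, state, total)
        new_Sigma = Sigma if fix_sigma else _mstep_sigma(state)
        for k in range(K):
            if active[k]:
                Sigma[k] = new_Sigma[k]
                if np.trace(Sigma[k]) < freeze_trace:
                    active[k] = False
                    state.pi[k] = 1.0 / p
                    state.mu[k] = 0.0
                    state.Sigma_tilde[k] = 0.0
                    log.info("component %d collapsed; frozen as inactive", k)

        elbo = _compute_elbo(ctx, state, Sigma, active)
        if elbo_trace and elbo < elbo_trace[-1] - 1e-6:
            warnings.warn(
                f"ELBO decreased by {elbo_trace[-1] - elbo:.3g} at sweep {it}",
                stacklevel=2)
        elbo_trace.append(elbo)
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"VEM did not converge in {max_iter} sweeps", stacklevel=2)

    from .inference import compute_pip  # local import to avoid a cycle
    pip = compute_pip(state.pi, active=active)
    return FitResult(state=state,
                     Sigma_hat=CausalComponentParams(Sigma),
                     elbo_trace=np.asarray(elbo_trace),
                     pip=pip, n_iter=it, converged=converged,
                     active=active, snp_id=data.snp_id)
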
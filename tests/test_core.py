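"""Variational EM: coordinate updates, ELBO, M-step, and the outer fit."""

import warnings

import numpy as np
import pytest

from xpfine.core import (CausalComponentParams, PolygenicSolver,
                         compute_elbo, elbo_constant, estep_update_component,
                         fit_xmap, initial_state, mstep_sigma,
                         update_polygenic)
from xpfine.errors import ConfigurationError
from xpfine.ldsc import PolygenicParams
from tests.conftest import enumeration_posterior, make_aligned


def _disabled():
    return PolygenicParams.disabled()


def _random_state(data, K, seed, scale=0.01):
    r = np.random.default_rng(seed)
    st = initial_state(data, K)
    st.pi[:] = r.dirichlet(np.ones(data.p), size=K)
    st.mu[:] = r.normal(scale=scale, size=(K, data.p, 2))
    A = r.normal(scale=scale, size=(K, data.p, 2, 2))
    st.Sigma_tilde[:] = np.einsum("kpij,kplj->kpil", A, A) + 1e-8 * np.eye(2)
    return st


class TestEStep:
    def test_single_snp_gets_all_mass(self):
        data = make_aligned(p=1, seed=0)
        st = initial_state(data, 1)
        pi, _, _ = estep_update_component(0, st, data, _disabled(),
                                          np.diag([1e-4, 1e-4]))
        assert pi[0] == pytest.approx(1.0)

    def test_null_symmetric_evidence_is_uniform(self):
        p = 6
        data = make_aligned(p=p, seed=0, rho=(0.0, 0.0))
        for t in range(2):
            data.stats[t].bhat[:] = 0.0
        st = initial_state(data, 1)
        pi, mu, _ = estep_update_component(0, st, data, _disabled(),
                                           np.diag([1e-4, 1e-4]))
        np.testing.assert_allclose(pi, 1.0 / p, atol=1e-12)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_matches_enumeration_identity_ld(self):
        """p=3, R=I, omega=0, K=1: one E-step equals the exact posterior
        from enumerating the three causal configurations."""
        data = make_aligned(p=3, seed=5, rho=(0.0, 0.0),
                            signal={1: (0.03, 0.02)})
        Sigma1 = np.array([[4e-4, 1e-4], [1e-4, 3e-4]])
        st = initial_state(data, 1)
        pi, _, _ = estep_update_component(0, st, data, _disabled(), Sigma1)
        oracle, _ = enumeration_posterior(data, Sigma1)
        np.testing.assert_allclose(pi, oracle, atol=1e-10)

    def test_rows_normalized(self):
        data = make_aligned(p=9, seed=8)
        st = _random_state(data, 3, 2)
        pi, _, _ = estep_update_component(1, st, data, _disabled(),
                                          np.diag([2e-4, 2e-4]))
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)


class TestPolygenicUpdate:
    def test_disabled_gives_zero_mean(self):
        data = make_aligned(p=4, seed=1)
        st = _random_state(data, 2, 3)
        nu, lam = update_polygenic(st, data, _disabled())
        np.testing.assert_array_equal(nu, 0.0)
        assert lam is None

    def test_scalar_ridge_closed_form(self):
        """p=1, R=[1], c=1, diagonal omega: the posterior variance is the
        scalar ridge formula (1/s^2 + 1/omega_t)^-1 per population."""
        data = make_aligned(p=1, seed=2)
        params = PolygenicParams(omega=np.diag([1e-4, 2e-4]),
                                 c=np.array([1.0, 1.0]))
        st = initial_state(data, 1)
        nu, lam = update_polygenic(st, data, params)
        for t in range(2):
            s2 = data.stats[t].se[0] ** 2
            expected = 1.0 / (1.0 / s2 + 1.0 / params.omega[t, t])
            assert lam[t, t] == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("p", [5, 50])
    def test_matches_dense_inverse_oracle(self, p):
        """Structured solver equals a direct dense 2p x 2p inversion."""
        data = make_aligned(p=p, seed=p, rho=(0.4, 0.85), c=(1.2, 1.4))
        params = PolygenicParams(omega=np.array([[1e-4, 5e-5], [5e-5, 1.5e-4]]),
                                 c=np.array([1.2, 1.4]))
        st = _random_state(data, 2, p + 1)
        nu, lam = update_polygenic(st, data, params)
        W = np.zeros((2 * p, 2 * p))
        for t in range(2):
            s = data.stats[t].se
            W[t * p:(t + 1) * p, t * p:(t + 1) * p] = \
                data.lds[t].R / (params.c[t] * np.outer(s, s))
        M = W + np.kron(np.linalg.inv(params.omega), np.eye(p))
        lam_oracle = np.linalg.inv(M)
        d = np.concatenate([data.stats[t].bhat / (params.c[t] * data.stats[t].se ** 2)
                            for t in range(2)])
        Eb = st.total_causal_mean()
        nu_oracle = lam_oracle @ (d - W @ np.concatenate([Eb[0], Eb[1]]))
        scale = np.max(np.abs(lam_oracle))
        assert np.max(np.abs(lam - lam_oracle)) < 1e-8 * max(scale, 1.0)
        assert np.max(np.abs(nu.ravel() - nu_oracle)) < 1e-8

    def test_singular_omega_rejected(self):
        with pytest.raises(ConfigurationError):
            PolygenicSolver([np.eye(3), np.eye(3)],
                            np.array([[1e-4, 1e-4], [1e-4, 1e-4]]))


class TestMStep:
    def test_degenerate_weights(self):
        data = make_aligned(p=4, seed=3)
        st = initial_state(data, 1)
        m = np.array([0.01, -0.02])
        V = np.array([[2e-4, 1e-5], [1e-5, 3e-4]])
        st.pi[0] = [1.0, 0.0, 0.0, 0.0]
        st.mu[0, 0] = m
        st.Sigma_tilde[0, 0] = V
        Sigma = mstep_sigma(st)
        np.testing.assert_allclose(Sigma.Sigma[0], np.outer(m, m) + V, atol=1e-15)

    def test_uniform_weights_identical_covariance(self):
        data = make_aligned(p=5, seed=3)
        st = initial_state(data, 1)
        V = np.array([[2e-4, 5e-5], [5e-5, 1e-4]])
        st.Sigma_tilde[0] = V
        Sigma = mstep_sigma(st)
        np.testing.assert_allclose(Sigma.Sigma[0], V, atol=1e-15)

    def test_matches_loop_oracle(self):
        data = make_aligned(p=10, seed=4)
        st = _random_state(data, 2, 9)
        Sigma = mstep_sigma(st).Sigma
        for k in range(2):
            oracle = np.zeros((2, 2))
            for j in range(10):
                oracle += st.pi[k, j] * (np.outer(st.mu[k, j], st.mu[k, j])
                                         + st.Sigma_tilde[k, j])
            np.testing.assert_allclose(Sigma[k], oracle, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(Sigma)[:, 0] >= -1e-15)


class TestELBO:
    def test_equals_log_evidence_when_family_is_exact(self):
        """K=1, omega=0, equal SEs: the converged ELBO (plus the documented
        constant) equals the enumeration log evidence, because the
        variational family contains the exact posterior."""
        data = make_aligned(p=8, seed=11, signal={3: (0.05, 0.0)})
        Sigma1 = np.array([[4e-4, 1e-4], [1e-4, 3e-4]])
        fit = fit_xmap(data, K=1, params=_disabled(), tol=1e-13, max_iter=50,
                       sigma2_init=Sigma1[None], fix_sigma=True)
        _, logev = enumeration_posterior(data, Sigma1)
        elbo_full = fit.elbo_trace[-1] + elbo_constant(data, _disabled())
        assert elbo_full == pytest.approx(logev, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        """At a fixed variational state, the analytic ELBO gradient in
        Sigma_k (0.5 (S^-1 M S^-1 - S^-1) with M the weighted second
        moment) matches central finite differences."""
        data = make_aligned(p=6, seed=13, signal={2: (0.04, 0.03)})
        Sigma1 = np.array([[5e-4, 1e-4], [1e-4, 4e-4]])
        fit = fit_xmap(data, K=1, params=_disabled(), tol=1e-13, max_iter=50,
                       sigma2_init=Sigma1[None], fix_sigma=True)
        st = fit.state
        M = np.einsum("p,pij->ij",
                      st.pi[0],
                      np.einsum("pi,pj->pij", st.mu[0], st.mu[0])
                      + st.Sigma_tilde[0])
        S_inv = np.linalg.inv(Sigma1)
        grad_analytic = 0.5 * (S_inv @ M @ S_inv - S_inv)
        eps = 1e-9
        grad_fd = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                d = np.zeros((2, 2))
                d[i, j] = d[j, i] = eps  # keep Sigma symmetric
                up = compute_elbo(st, data, _disabled(),
                                  CausalComponentParams((Sigma1 + d)[None]))
                dn = compute_elbo(st, data, _disabled(),
                                  CausalComponentParams((Sigma1 - d)[None]))
                grad_fd[i, j] = (up - dn) / (2 * eps)
        # symmetric perturbation doubles the off-diagonal sensitivity
        grad_sym = grad_analytic + grad_analytic.T - np.diag(np.diag(grad_analytic))
        np.testing.assert_allclose(grad_fd, grad_sym,
                                   rtol=1e-4, atol=1e-4 * np.abs(grad_sym).max())

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_over_sweeps(self, seed):
        r = np.random.default_rng(seed)
        p = int(r.integers(5, 20))
        data = make_aligned(p=p, seed=seed + 100,
                            rho=(r.uniform(0, 0.6), r.uniform(0.3, 0.9)),
                            signal={int(r.integers(p)): (r.normal(scale=0.03),
                                                         r.normal(scale=0.03))})
        params = PolygenicParams(
            omega=np.array([[2e-4, 1e-4], [1e-4, 2e-4]]),
            c=np.array([1.0 + r.uniform(0, 0.5), 1.0 + r.uniform(0, 0.5)]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_xmap(data, K=3, params=params, tol=1e-9, max_iter=60)
        diffs = np.diff(fit.elbo_trace)
        assert np.all(diffs > -1e-6)


class TestFit:
    def test_null_data_uniform_pi(self):
        data = make_aligned(p=10, seed=0, rho=(0.0, 0.0))
        for t in range(2):
            data.stats[t].bhat[:] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_xmap(data, K=2, params=_disabled(), max_iter=30)
        np.testing.assert_allclose(fit.state.pi, 0.1, atol=1e-8)

    def test_permutation_equivariance(self):
        data = make_aligned(p=12, seed=21, signal={4: (0.05, 0.04)})
        perm = np.random.default_rng(0).permutation(12)
        from xpfine.io import AlignedDataset
        data_p = AlignedDataset(
            stats=[st.subset(perm) for st in data.stats],
            lds=[ld.subset(perm) for ld in data.lds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_xmap(data, K=2, params=_disabled(), max_iter=60)
            fit_p = fit_xmap(data_p, K=2, params=_disabled(), max_iter=60)
        np.testing.assert_allclose(fit_p.pip, fit.pip[perm], atol=1e-8)

    def test_pip_bounds_and_sigma_psd(self):
        data = make_aligned(p=15, seed=30, signal={7: (0.06, 0.05)})
        params = PolygenicParams(omega=np.array([[1e-4, 8e-5], [8e-5, 1e-4]]),
                                 c=np.array([1.1, 1.2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_xmap(data, K=4, params=params, max_iter=80)
        assert np.all((fit.pip >= 0) & (fit.pip <= 1))
        np.testing.assert_allclose(fit.state.pi.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(fit.Sigma_hat.Sigma)[:, 0] >= -1e-12)

    def test_k_too_small_rejected(self):
        data = make_aligned(p=4, seed=1)
        with pytest.raises(ConfigurationError):
            fit_xmap(data, K=0, params=_disabled())
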
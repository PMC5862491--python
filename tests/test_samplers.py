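"""Full-conditional updates against closed forms and the enumeration oracle."""

import math

import numpy as np
import pytest

from bayesn.genome import MarkerMap, build_window_partition
from bayesn.priors import ModelSpec
from bayesn import samplers as S
from bayesn.samplers import OracleSpec, enumerate_posterior


def _fixed_spec(method="bayesb", sigma2=0.5, sigma2_e=0.25, **kw):
    """Spec whose initial (fixed) variances are exactly sigma2 / sigma2_e."""
    base = dict(
        method=method,
        S_alpha2=sigma2 / 2,
        S_gamma2=sigma2 / 2,
        S_e2=sigma2_e / 2,
        pi=0.8,
        chain_length=10,
        burn_in=1,
        fit_intercept=False,
        update_variances=False,
        update_sigma_e=False,
    )
    base.update(kw)
    return ModelSpec(**base)


def _state(method="bayesb", n=8, m=3, seed=2, **kw):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    Z -= Z.mean(axis=0)
    y = Z @ np.concatenate([[1.2], np.zeros(m - 1)]) + rng.normal(size=n) * 0.5
    spec = _fixed_spec(method=method, **kw)
    mp = MarkerMap([f"s{j}" for j in range(m)], np.ones(m, int), np.arange(m) * 1000)
    st = S.init_state(y, Z, spec, marker_map=mp, rng=rng)
    return st, spec, rng


class TestMeanUpdate:
    def test_posterior_moments(self):
        st, spec, rng = _state()
        st.ycorr = np.ones(st.n) - st.mu  # ycorr + mu*1 = 1
        st.sigma2_e = 4.0  # conditional: N(1, sigma_e^2/n) = N(1, 0.5)
        draws = []
        for _ in range(20_000):
            # sample_mean keeps ycorr + mu*1 invariant, so the conditional
            # is identical across draws
            S.sample_mean(st, st.y, rng)
            draws.append(st.mu)
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.var() == pytest.approx(st.sigma2_e / st.n, rel=0.05)

    def test_degenerate_small_sigma(self):
        st, spec, rng = _state()
        st.sigma2_e = 1e-12
        target = float(np.mean(st.ycorr) + st.mu)
        S.sample_mean(st, st.y, rng)
        assert st.mu == pytest.approx(target, abs=1e-5)


class TestLocusUpdate:
    def test_pi_one_forces_exclusion(self):
        st, spec, rng = _state()
        st.pi_current = 1.0
        for _ in range(50):
            S.sample_locus_bayesb(st, 0, spec, rng)
            assert st.delta[0] == 0

    def test_huge_effect_always_included(self):
        st, spec, rng = _state()
        st.ycorr = st.Z[:, 0] * 50.0  # overwhelming signal on locus 0
        hits = 0
        for _ in range(200):
            S.sample_locus_bayesb(st, 0, spec, rng)
            hits += int(st.delta[0])
            # withdraw the fitted effect again to keep the signal fixed
            st.ycorr = st.Z[:, 0] * 50.0
            st.delta[0] = 0
            st.alpha[0] = 0.0
        assert hits == 200

    def test_single_snp_matches_enumeration(self, ):
        st, spec, rng = _state(m=1)
        oracle = enumerate_posterior(
            OracleSpec(sigma2=0.5, sigma2_e=0.25, pi=0.8), st.y, st.Z
        )
        hits = 0
        n_iter = 40_000
        for _ in range(n_iter):
            S.sample_locus_bayesb(st, 0, spec, rng)
            hits += int(st.delta[0])
        assert hits / n_iter == pytest.approx(
            oracle["incl_prob_snp"][0], abs=0.02
        )

    def test_ycorr_consistency_maintained(self):
        st, spec, rng = _state(m=3)
        for _ in range(200):
            for j in range(3):
                S.sample_locus_bayesb(st, j, spec, rng)
        assert st.ycorr_drift() < 1e-8


class TestVarianceUpdates:
    def test_locus_variance_posterior_mean_null_effect(self):
        st, spec, rng = _state()
        st.alpha[0] = 0.0
        draws = []
        for _ in range(30_000):
            S.sample_locus_variance(st, 0, spec, rng)
            draws.append(st.sigma2_locus[0])
        expected = spec.nu_alpha * spec.S_alpha2 / (spec.nu_alpha - 1)
        assert np.mean(draws) == pytest.approx(expected, rel=0.03)

    def test_locus_variance_closed_form_mean(self):
        st, spec, rng = _state()
        spec2 = _fixed_spec(S_alpha2=0.2)
        st.alpha[0] = 0.5  # alpha^2 = 0.25
        draws = []
        for _ in range(30_000):
            S.sample_locus_variance(st, 0, spec2, rng)
            draws.append(st.sigma2_locus[0])
        assert np.mean(draws) == pytest.approx((0.8 + 0.25) / 3, rel=0.03)
        assert min(draws) > 0.0

    def test_window_variance_closed_form_mean(self, tiny_instance):
        y, Z, wp = tiny_instance["y"], tiny_instance["Z"], tiny_instance["windows"]
        spec = _fixed_spec(method="bayesn", S_alpha2=0.2, Pi=0.5, pi=None)
        spec.pi_i = np.array([0.5, 0.5])
        rng = np.random.default_rng(0)
        st = S.init_state(y, Z, spec, windows=wp, rng=rng)
        st.alpha[:2] = [0.3, -0.4]
        draws = []
        for _ in range(30_000):
            S.sample_window_variance(st, 0, spec, rng)
            draws.append(st.sigma2_window[0])
        # df nu+m_i = 6, scale sum = 0.8 + 0.25 -> mean 1.05/4
        assert np.mean(draws) == pytest.approx(1.05 / 4, rel=0.03)

    def test_residual_variance_closed_form_mean(self):
        st, spec, rng = _state(n=4, m=1)
        spec2 = _fixed_spec(S_e2=0.5)
        st.ycorr = np.array([1.0, 1.0, 0.0, 0.0])  # ycorr'ycorr = 2
        draws = []
        for _ in range(30_000):
            ycorr = st.ycorr.copy()
            S.sample_residual_variance(st, spec2, rng)
            draws.append(st.sigma2_e)
            st.ycorr = ycorr
        assert np.mean(draws) == pytest.approx((2.0 + 2.0) / 6, rel=0.03)


class TestInclusionProbability:
    @pytest.mark.parametrize(
        "n_zero,n_total,mean", [(10, 10, 11 / 12), (0, 10, 1 / 12), (50, 100, 0.5)]
    )
    def test_beta_posterior_mean(self, n_zero, n_total, mean, rng):
        st, spec, _ = _state()
        draws = [
            S.sample_inclusion_probability(st, (n_zero, n_total), rng)
            for _ in range(20_000)
        ]
        assert np.mean(draws) == pytest.approx(mean, abs=0.01)

    def test_invalid_counts_rejected(self, rng):
        st, _, _ = _state()
        with pytest.raises(ValueError):
            S.sample_inclusion_probability(st, (5, 4), rng)


class TestAntedependence:
    def test_t_zero_reduces_to_independent_prior(self):
        # with t == 0 the conditional prior of every alpha_j is N(0, lam_gj),
        # identical to the single-locus model with that slab
        st, spec, rng = _state(method="antebayesb", m=3, pi=0.8)
        st.t_coef[:] = 0.0
        st2, spec2, rng2 = _state(method="bayesb", m=3, pi=0.8)
        st2.sigma2_locus[:] = st.lambda_gamma
        n_iter = 60_000
        hits_a = np.zeros(3)
        hits_b = np.zeros(3)
        spec_fixed = _fixed_spec(method="antebayesb", fix_t_at_zero=True)
        for _ in range(n_iter):
            for j in range(3):
                S.sample_ante_locus(st, j, spec_fixed, rng)
                S.sample_locus_bayesb(st2, j, spec2, rng2)
            hits_a += st.delta
            hits_b += st2.delta
        assert np.allclose(hits_a / n_iter, hits_b / n_iter, atol=0.02)

    def test_conditional_covariance_matches_matrix_identity(self, rng):
        # Var(alpha | T) = (I-T)^-1 Var(gamma) (I-T)^-T on a 3-SNP chain
        t = np.array([0.0, 0.6, -0.4])
        lam = np.array([0.5, 0.3, 0.7])
        n_mc = 400_000
        g = rng.normal(0, np.sqrt(lam), size=(n_mc, 3))
        a1 = g[:, 0]
        a2 = t[1] * a1 + g[:, 1]
        a3 = t[2] * a2 + g[:, 2]
        A = np.stack([a1, a2, a3], axis=1)
        T = np.zeros((3, 3))
        T[1, 0], T[2, 1] = t[1], t[2]
        V = np.linalg.inv(np.eye(3) - T) @ np.diag(lam) @ np.linalg.inv(
            np.eye(3) - T
        ).T
        assert np.allclose(np.cov(A.T), V, atol=0.01)
        # corner element magnitude is the product of the t's times lam_1
        assert abs(V[2, 0]) == pytest.approx(abs(t[1] * t[2]) * lam[0])

    def test_marginal_variance_grows_along_chain(self, rng):
        # Var(alpha_3) = sig_g^2 (1 + sig_t^2 + sig_t^4) for 3 SNPs
        sig_t2, sig_g2 = 0.2, 1.0
        n_mc = 500_000
        t2 = rng.normal(0, np.sqrt(sig_t2), n_mc)
        t3 = rng.normal(0, np.sqrt(sig_t2), n_mc)
        g = rng.normal(0, np.sqrt(sig_g2), size=(n_mc, 3))
        a3 = t3 * (t2 * g[:, 0] + g[:, 1]) + g[:, 2]
        assert a3.var() == pytest.approx(
            sig_g2 * (1 + sig_t2 + sig_t2**2), rel=0.02
        )

    def test_t_update_regression_limit(self):
        # noiseless alpha_j = c * alpha_{j-1} with a vague prior -> t -> c
        st, spec, rng = _state(method="antebayesb", m=3)
        c = 0.7
        st.alpha[:] = [2.0, 2.0 * c, 0.0]
        st.lambda_gamma[:] = 1e-10
        st.lambda_t[:] = 1e6
        draws = []
        for _ in range(2000):
            S.sample_t_coefficients(st, 1, spec, rng)
            draws.append(st.t_coef[1])
        assert np.mean(draws) == pytest.approx(c, abs=1e-3)

    def test_t_prior_draw_when_antecedent_zero(self):
        st, spec, rng = _state(method="antebayesb", m=3)
        st.alpha[0] = 0.0
        st.lambda_t[1] = 0.35
        draws = []
        for _ in range(30_000):
            S.sample_t_coefficients(st, 1, spec, rng)
            draws.append(st.t_coef[1])
        assert np.mean(draws) == pytest.approx(0.0, abs=0.02)
        assert np.var(draws) == pytest.approx(0.35, rel=0.05)


class TestEnumerationOracle:
    def test_probabilities_sum_to_one(self, tiny_instance):
        res = enumerate_posterior(
            OracleSpec(
                sigma2=0.5,
                sigma2_e=0.25,
                pi_i=np.array([0.5, 0.5]),
                Pi=0.6,
                windows=tiny_instance["windows"],
            ),
            tiny_instance["y"],
            tiny_instance["Z"],
        )
        assert res["prob"].sum() == pytest.approx(1.0)
        assert ((res["incl_prob_snp"] >= 0) & (res["incl_prob_snp"] <= 1)).all()

    def test_pi_one_puts_all_mass_on_null(self, tiny_instance):
        res = enumerate_posterior(
            OracleSpec(sigma2=0.5, sigma2_e=0.25, pi=1.0),
            tiny_instance["y"],
            tiny_instance["Z"],
        )
        assert len(res["configs"]) == 1
        assert res["incl_prob_snp"].max() == 0.0

    def test_single_snp_closed_form_bayes_factor(self):
        rng = np.random.default_rng(3)
        n = 10
        z = rng.normal(size=n)
        z -= z.mean()
        y = 0.8 * z + rng.normal(size=n) * 0.4
        sigma2, sigma2_e, pi = 0.5, 0.16, 0.7
        res = enumerate_posterior(
            OracleSpec(sigma2=sigma2, sigma2_e=sigma2_e, pi=pi), y, z[:, None]
        )
        zz = float(z @ z)
        rhs = float(z @ y)
        v = zz * sigma2 + sigma2_e
        log_bf = 0.5 * (
            math.log(sigma2_e / v) + rhs**2 * sigma2 / (sigma2_e * v)
        )
        odds = (1 - pi) / pi * math.exp(log_bf)
        assert res["incl_prob_snp"][0] == pytest.approx(odds / (1 + odds), rel=1e-9)

    def test_indicator_limit_enforced(self):
        y = np.zeros(4)
        Z = np.zeros((4, 13))
        with pytest.raises(ValueError):
            enumerate_posterior(OracleSpec(sigma2=1, sigma2_e=1, pi=0.5), y, Z)
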
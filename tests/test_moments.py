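"""Model-implied moments: closed forms, Monte-Carlo oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import twinpath as tp
from twinpath.pathmodel import Diag, Factor, FreeCov, PathModel, Simplex, MeanSpec
from twinpath.simulate import draw_pair_scores
from twinpath.zoo import (
    build_autoregression,
    build_common_pathway,
    build_correlated_factors,
    build_dual_change,
    build_independent_pathway,
    build_latent_growth,
    build_univariate_ace,
)
from conftest import mc_cov_check


def ar_cov(innovations, beta, T):
    """Independent closed-form recursion for the simplex covariance."""
    S = np.zeros((T, T))
    for t in range(T):
        for s in range(t, T):
            if t == s:
                S[t, t] = (beta**2 * S[t - 1, t - 1] if t else 0.0) + innovations[t]**2
            else:
                S[t, s] = S[s, t] = beta ** (s - t) * S[t, t]
    return S


class TestSimplexCov:
    def test_no_transmission_gives_identity(self):
        s = Simplex([1.0] * 4, [0.0] * 3)
        assert np.allclose(s.cov({}, 4), np.eye(4))

    def test_first_order_recursion_t3(self):
        # beta=0.8, unit innovations: Var(A1)=1, Cov(A1,A2)=0.8,
        # Var(A2)=1.64, Cov(A1,A3)=0.64
        s = Simplex([1.0, 1.0, 1.0], [0.8, 0.8])
        S = s.cov({}, 3)
        assert S[0, 0] == pytest.approx(1.0)
        assert S[0, 1] == pytest.approx(0.8)
        assert S[1, 1] == pytest.approx(1.64)
        assert S[0, 2] == pytest.approx(0.64)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.2, 1.5), min_size=4, max_size=4),
           st.floats(-0.9, 0.9))
    def test_matches_independent_recursion(self, innov, beta):
        s = Simplex(list(innov), [beta] * 3)
        assert np.allclose(s.cov({}, 4), ar_cov(innov, beta, 4), atol=1e-10)

    def test_monte_carlo_oracle_random_spec(self):
        rng = np.random.default_rng(11)
        innov = rng.uniform(0.3, 1.0, 4)
        beta = 0.65
        s = Simplex(list(innov), [beta] * 3)
        y1, _ = s.draw({}, np.random.default_rng(1), 200_000, 4, 0.5)
        mc_cov_check(y1, s.cov({}, 4), n_se=4.0)


class TestPairMoments:
    def test_univariate_cross_twin_covariances(self):
        # a2=0.5, c2=0.3, e2=0.2: MZ cross-twin = 0.8, DZ = 0.55
        m = build_univariate_ace()
        th = m.theta_from({"a_var": 0.5, "c_var": 0.3, "e_var": 0.2,
                           "mu_1": 0.0, "beta_sex": 0.0})
        mu, Sig, _ = m.implied(th)
        assert Sig[0][0, 1] == pytest.approx(0.8)
        assert Sig[1][0, 1] == pytest.approx(0.55)
        assert Sig[0][0, 0] == pytest.approx(1.0)

    def test_e_only_is_diagonal(self):
        m = build_univariate_ace(drop=("A", "C"))
        th = m.theta_from({"e_var": 1.0, "mu_1": 0.0, "beta_sex": 0.0})
        _, Sig, _ = m.implied(th)
        assert np.allclose(Sig[0], np.eye(2))
        assert np.allclose(Sig[1], np.eye(2))

    def test_sex_definition_variable_shifts_means(self, study_model):
        model, truth = study_model
        th = model.theta_from(truth)
        mm = model.pair_moments(th, "MZ", sex_1=1.0, sex_2=0.0)
        base = model.pair_moments(th, "MZ", sex_1=0.0, sex_2=0.0)
        assert np.allclose(mm.mean[:6] - base.mean[:6], truth["beta_sex"])
        assert np.allclose(mm.mean[6:], base.mean[6:])

    def test_pure_a_mz_cross_block_twice_dz(self):
        m = build_autoregression(T=4, kinds=("A",))
        vals = {l: 0.5 for l in m.labels}
        th = m.theta_from(vals)
        _, Sig, _ = m.implied(th)
        mz_cross, dz_cross = Sig[0][:4, 4:], Sig[1][:4, 4:]
        assert np.allclose(mz_cross, 2.0 * dz_cross)

    def test_within_twin_blocks_equal_across_zygosity(self, study_model):
        model, truth = study_model
        _, Sig, _ = model.implied(model.theta_from(truth))
        T = model.T
        assert np.allclose(Sig[0][:T, :T], Sig[1][:T, :T])
        assert np.allclose(Sig[0][T:, T:], Sig[0][:T, :T])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_psd_and_symmetric_for_nonnegative_paths(self, seed):
        rng = np.random.default_rng(seed)
        m = build_autoregression(T=4)
        vals = {l: float(rng.uniform(0.0, 0.8)) for l in m.labels}
        _, Sig, _ = m.implied(m.theta_from(vals))
        for z in range(2):
            assert np.allclose(Sig[z], Sig[z].T)
            assert np.linalg.eigvalsh(Sig[z]).min() > -1e-10


class TestStandardizedComponents:
    def test_equal_components_quarter_shares(self):
        m = PathModel(
            1, {"A": [FreeCov([[1.0]])], "C": [FreeCov([[1.0]])],
                "E": [FreeCov([[1.0]])]},
            [1.0], MeanSpec.occasion(1), beta_sex=0.0)
        sc = m.standardized_components(m.theta_from({"mu_1": 0.0}))
        for k in ("A", "C", "E", "residual"):
            assert sc["shares"][k][0] == pytest.approx(0.25)

    def test_simplex_longitudinal_correlation(self):
        m = build_autoregression(T=3, kinds=("A",), equal_residual=True)
        vals = {"a_innov_1": 1.0, "a_innov_2": 1.0, "a_innov_3": 1.0,
                "beta_a": 0.8, "res": 1e-6, "mu_1": 0.0, "mu_2": 0.0,
                "mu_3": 0.0, "beta_sex": 0.0}
        sc = m.standardized_components(m.theta_from(vals))
        assert sc["correlations"]["rA"][0, 1] == pytest.approx(0.8 / np.sqrt(1.64),
                                                               abs=1e-9)

    def test_shares_sum_to_one(self, study_model):
        model, truth = study_model
        sc = model.standardized_components(model.theta_from(truth))
        total = sum(sc["shares"][k] for k in ("A", "C", "E", "residual"))
        assert np.allclose(total, 1.0, atol=1e-10)


class TestLimitEquivalences:
    def test_dual_change_beta_zero_equals_linear_growth(self):
        dc = build_dual_change(T=5)
        lg = build_latent_growth(T=5, degree=1)
        rng = np.random.default_rng(3)
        common = {"lvl_lvl": 0.4, "lvl_slp": 0.05, "slp_slp": 0.1}
        dc_vals, lg_vals = {}, {}
        for kl in ("a", "c", "e"):
            for cell, v in common.items():
                dc_vals[f"{kl}_{cell}"] = v
            lg_vals.update({f"{kl}_int_int": common["lvl_lvl"],
                            f"{kl}_lin_int": common["lvl_slp"],
                            f"{kl}_lin_lin": common["slp_slp"]})
            dc_vals[f"{kl}_prop"] = 0.0
            for t in range(5):
                dc_vals[f"{kl}_res_{t+1}"] = 0.3
                lg_vals[f"{kl}_res_{t+1}"] = 0.3
        dc_vals.update({"mean_level": 1.0, "mean_slope": 0.1, "beta_sex": 0.0})
        lg_vals.update({"mean_int": 1.0, "mean_lin": 0.1, "beta_sex": 0.0})
        mu_dc, Sig_dc, _ = dc.implied(dc.theta_from(dc_vals))
        mu_lg, Sig_lg, _ = lg.implied(lg.theta_from(lg_vals))
        assert np.allclose(Sig_dc, Sig_lg, atol=1e-8)
        assert np.allclose(mu_dc, mu_lg, atol=1e-8)

    def test_correlated_factors_t1_equals_univariate(self):
        cf = build_correlated_factors(T=1)
        uni = build_univariate_ace()
        vals_cf = {"a_cov_1_1": 0.5, "c_cov_1_1": 0.3, "e_cov_1_1": 0.2,
                   "mu_1": 1.0, "beta_sex": -0.1}
        vals_u = {"a_var": 0.5, "c_var": 0.3, "e_var": 0.2,
                  "mu_1": 1.0, "beta_sex": -0.1}
        out_cf = cf.implied(cf.theta_from(vals_cf))
        out_u = uni.implied(uni.theta_from(vals_u))
        assert np.allclose(out_cf[1], out_u[1], atol=1e-12)
        assert np.allclose(out_cf[0], out_u[0], atol=1e-12)

    def test_common_pathway_pure_a_factor(self):
        m = build_common_pathway(T=4, k=1)
        vals = {l: 0.0 for l in m.labels}
        lam = [1.0, 0.7, 0.5, 0.3]
        for t in range(1, 4):
            vals[f"cp1_load_{t+1}"] = lam[t]
        vals["cp1_a"] = 1.0
        _, Sig, _ = m.implied(m.theta_from(vals))
        lam = np.array(lam)
        assert np.allclose(Sig[0][:4, 4:], np.outer(lam, lam), atol=1e-12)
        assert np.allclose(Sig[1][:4, 4:], 0.5 * np.outer(lam, lam), atol=1e-12)

    def test_independent_pathway_zero_c_gives_mz_twice_dz(self):
        m = build_independent_pathway(T=3)
        rng = np.random.default_rng(0)
        vals = {l: float(rng.uniform(0.2, 0.6)) for l in m.labels}
        for t in range(3):
            vals[f"c_common_{t+1}"] = 0.0
            vals[f"c_res_{t+1}"] = 0.0
        _, Sig, _ = m.implied(m.theta_from(vals))
        assert np.allclose(Sig[0][:3, 3:], 2.0 * Sig[1][:3, 3:], atol=1e-12)


class TestSerialization:
    def test_yaml_round_trip_preserves_moments(self, study_model):
        model, truth = study_model
        clone = tp.PathModel.from_yaml(model.to_yaml())
        assert clone.labels == model.labels
        th = model.theta_from(truth)
        for a, b in zip(model.implied(th), clone.implied(th)):
            assert np.allclose(a, b)


class TestSimulatorAgreement:
    """Generative/analytic contract: simulated moments match implied moments."""

    @pytest.mark.parametrize("builder,nameit", [
        (lambda: tp.default_truth()[0], "study autoregression"),
    ])
    def test_pair_covariance_matches_implied(self, builder, nameit, study_model):
        model, truth = study_model
        n = 60_000
        rng = np.random.default_rng(99)
        for z, zyg in enumerate(("MZ", "DZ")):
            y1, y2 = draw_pair_scores(model, truth, rng, n, zyg)
            stacked = np.hstack([y1, y2])
            _, Sig, _ = model.implied(model.theta_from(truth))
            mc_cov_check(stacked, Sig[z], n_se=4.5)
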
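"""FIML engine: likelihood oracles, optimization, standard errors, profile CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinpath as tp
from twinpath.fiml import (
    PairData,
    fit,
    make_objective,
    pair_columns,
    pair_loglik,
    profile_ci,
    wald_se,
)
from twinpath.pathmodel import ModelMoments
from twinpath.zoo import build_saturated, build_univariate_ace


def random_pairs(n, T, rng, missing=0.3):
    """Random pair table with NaN holes (no model structure implied)."""
    Y = rng.normal(1.0, 0.8, (n, 2 * T))
    mask = rng.random((n, 2 * T)) < missing
    empty = mask.all(axis=1)
    mask[empty, 0] = False
    Y[mask] = np.nan
    df = pd.DataFrame(Y, columns=pair_columns(T))
    df.insert(0, "sex_2", rng.integers(0, 2, n).astype(float))
    df.insert(0, "sex_1", rng.integers(0, 2, n).astype(float))
    df.insert(0, "zygosity", np.where(rng.random(n) < 0.5, "MZ", "DZ"))
    return df


class TestPairLoglik:
    def test_standard_normal_closed_form(self):
        m = ModelMoments(np.zeros(2), np.eye(2))
        assert pair_loglik(np.zeros(2), m) == pytest.approx(2 * np.log(2 * np.pi))

    def test_one_twin_missing_marginalizes(self):
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        m = ModelMoments(np.array([0.5, 0.5]), cov)
        y = np.array([1.2, np.nan])
        expected = -2.0 * stats.norm.logpdf(1.2, 0.5, 1.0)
        assert pair_loglik(y, m) == pytest.approx(expected, abs=1e-12)

    def test_non_pd_block_is_barrier(self):
        m = ModelMoments(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert pair_loglik(np.zeros(2), m) == np.inf

    def test_oracle_equivalence_200_random_pairs(self):
        """Sum over random complete pairs equals an independent direct
        multivariate-normal density within 1e-8."""
        rng = np.random.default_rng(42)
        T = 3
        A = rng.normal(size=(2 * T, 2 * T))
        cov = A @ A.T + 2 * np.eye(2 * T)
        mean = rng.normal(size=2 * T)
        Y = rng.multivariate_normal(mean, cov, size=200)
        ours = sum(pair_loglik(y, ModelMoments(mean, cov)) for y in Y)
        oracle = -2.0 * stats.multivariate_normal(mean, cov).logpdf(Y).sum()
        assert ours == pytest.approx(oracle, abs=1e-8)


class TestGroupedLikelihood:
    def test_grouped_equals_bruteforce(self, study_pairs, study_model):
        model, truth = study_model
        data = PairData(study_pairs, 6)
        th = model.theta_from(truth)
        grouped = data.neg2ll(*model.implied(th))
        assert grouped == pytest.approx(data.neg2ll_bruteforce(model, th), abs=1e-6)

    def test_gradient_matches_finite_differences(self, study_pairs, study_model):
        model, truth = study_model
        data = PairData(study_pairs, 6)
        fg = make_objective(model, data)
        th = model.theta_from(truth)
        f, g = fg(th)
        rng = np.random.default_rng(0)
        for j in rng.choice(len(th), 5, replace=False):
            h = 1e-5 * (1 + abs(th[j]))
            tp_, tm = th.copy(), th.copy()
            tp_[j] += h
            tm[j] -= h
            num = (fg(tp_)[0] - fg(tm)[0]) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-4)

    def test_rejects_all_missing_pair(self):
        df = random_pairs(10, 2, np.random.default_rng(0))
        df.loc[0, [c for c in df.columns if c.startswith("y")]] = np.nan
        with pytest.raises(ValueError, match="at least one observed"):
            PairData(df, 2)


class TestFit:
    def test_saturated_complete_data_matches_analytic_mle(self):
        """On complete balanced data the saturated FIML optimum equals the
        closed-form Gaussian MLE at the sample moments."""
        rng = np.random.default_rng(1)
        T = 1
        n = 400
        frames = []
        for zyg, r in (("MZ", 0.5), ("DZ", 0.25)):
            cov = np.array([[1.0, r], [r, 1.0]])
            Y = rng.multivariate_normal([1.0, 1.0], cov, size=n)
            df = pd.DataFrame(Y, columns=pair_columns(1))
            df.insert(0, "sex_2", 0.0)
            df.insert(0, "sex_1", 0.0)
            df.insert(0, "zygosity", zyg)
            frames.append(df)
        X = pd.concat(frames, ignore_index=True)
        data = PairData(X, 1)
        model = build_saturated(T=1)
        res = fit(model, data, n_restarts=1, seed=0)

        expected = 0.0
        for zyg in ("MZ", "DZ"):
            Y = X[X.zygosity == zyg][pair_columns(1)].to_numpy()
            mu = Y.mean(axis=0)
            S = (Y - mu).T @ (Y - mu) / len(Y)
            expected += len(Y) * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(S)) + 2)
        assert res.minus2ll == pytest.approx(expected, abs=1e-6)

    def test_complete_case_fiml_equals_complete_ml(self, interior_model):
        """With no missing data, the grouped FIML equals the dense evaluation."""
        model, truth = interior_model
        cfg = tp.SimulationConfig(model, truth, n_mz=300, n_dz=300, seed=3,
                                  missingness=None)
        pairs, _ = tp.simulate_pairs(cfg)
        data = PairData(pairs, 6)
        th = model.theta_from(truth)
        assert data.neg2ll(*model.implied(th)) == pytest.approx(
            data.neg2ll_bruteforce(model, th), abs=1e-8)

    def test_twin_order_invariance(self, study_pairs, study_model):
        """Swapping y1/y2 (and sexes) leaves the total -2LL unchanged under a
        structurally symmetric model."""
        model, truth = study_model
        th = model.theta_from(truth)
        swapped = study_pairs.copy()
        for t in range(6):
            swapped[[f"y1_t{t}", f"y2_t{t}"]] = study_pairs[[f"y2_t{t}", f"y1_t{t}"]].to_numpy()
        swapped[["sex_1", "sex_2"]] = study_pairs[["sex_2", "sex_1"]].to_numpy()
        f1 = PairData(study_pairs, 6).neg2ll(*model.implied(th))
        f2 = PairData(swapped, 6).neg2ll(*model.implied(th))
        assert f1 == pytest.approx(f2, abs=1e-8)

    def test_monotone_nesting(self, complete_pairs, interior_model):
        """Fixing a free parameter never decreases the minimized -2LL."""
        model, _ = interior_model
        data = PairData(complete_pairs, 6)
        full = fit(model, data, n_restarts=0, seed=0)
        sub = model.fixing({"c_innov_3": 0.0})
        warm = np.array([full.estimates[l] for l in sub.labels])
        res = fit(sub, data, n_restarts=0, seed=0, start=warm)
        assert res.minus2ll >= full.minus2ll - 1e-4

    def test_univariate_recovery_within_2se(self, complete_pairs):
        X = tp.estimators.subset_occasion(complete_pairs, 0, 6)
        m = tp.UnivariateACE(seed=0).fit(X)
        se = m.wald_se()
        # truth at occasion 1 of the interior model
        truth = {"a_var": 0.45**2, "c_var": 0.32**2, "e_var": 0.35**2 + 0.45**2}
        for lab, tv in truth.items():
            assert abs(m.estimates_[lab] - tv) < 2.5 * se[lab]


class TestWaldSE:
    def test_mean_se_matches_classical_formula(self):
        """E-only model on complete pairs: SE(mean) ~ sigma/sqrt(2n)."""
        rng = np.random.default_rng(5)
        n, sigma = 2000, 0.8
        Y = rng.normal(1.5, sigma, (n, 2))
        df = pd.DataFrame(Y, columns=pair_columns(1))
        df.insert(0, "sex_2", 0.0)
        df.insert(0, "sex_1", 0.0)
        df.insert(0, "zygosity", np.where(np.arange(n) % 2 == 0, "MZ", "DZ"))
        data = PairData(df, 1)
        model = build_univariate_ace(drop=("A", "C")).fixing({"beta_sex": 0.0})
        res = fit(model, data, n_restarts=1, seed=0)
        se = wald_se(model, data, res)
        assert se["mu_1"] == pytest.approx(sigma / np.sqrt(2 * n), rel=0.05)

    def test_se_scales_inverse_sqrt_n(self, interior_model):
        model, truth = interior_model
        ses = []
        for n in (400, 1600):
            cfg = tp.SimulationConfig(model, truth, n_mz=n, n_dz=n, seed=11,
                                      missingness=None)
            pairs, _ = tp.simulate_pairs(cfg)
            X = tp.estimators.subset_occasion(pairs, 0, 6)
            m = tp.UnivariateACE(seed=0).fit(X)
            ses.append(m.wald_se()["a_var"])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.35)

    def test_boundary_estimate_flagged(self):
        rng = np.random.default_rng(2)
        # pure-E data, AE model: a-variance estimate sits at/near its boundary
        Y = rng.normal(0.0, 1.0, (800, 2))
        df = pd.DataFrame(Y, columns=pair_columns(1))
        df.insert(0, "sex_2", 0.0)
        df.insert(0, "sex_1", 0.0)
        df.insert(0, "zygosity", np.where(np.arange(800) % 2 == 0, "MZ", "DZ"))
        data = PairData(df, 1)
        model = build_univariate_ace(drop=("C",))
        res = fit(model, data, n_restarts=1, seed=0)
        se = wald_se(model, data, res)  # must not raise; NaN allowed
        assert set(se) == set(model.labels)


class TestProfileCI:
    def test_quadratic_case_equals_wald(self):
        """For the mean of an E-only model the -2LL is exactly quadratic, so
        the profile interval equals the Wald interval."""
        rng = np.random.default_rng(8)
        Y = rng.normal(1.0, 1.0, (500, 2))
        df = pd.DataFrame(Y, columns=pair_columns(1))
        df.insert(0, "sex_2", 0.0)
        df.insert(0, "sex_1", 0.0)
        df.insert(0, "zygosity", np.where(np.arange(500) % 2 == 0, "MZ", "DZ"))
        data = PairData(df, 1)
        model = build_univariate_ace(drop=("A", "C")).fixing({"beta_sex": 0.0})
        res = fit(model, data, n_restarts=1, seed=0)
        se = wald_se(model, data, res)
        lo, hi = profile_ci(model, data, res, "mu_1")
        est = res.estimates["mu_1"]
        assert lo == pytest.approx(est - 1.96 * se["mu_1"], abs=2e-3)
        assert hi == pytest.approx(est + 1.96 * se["mu_1"], abs=2e-3)
        assert lo < est < hi

    def test_interval_covers_truth_in_easy_case(self, complete_pairs):
        X = tp.estimators.subset_occasion(complete_pairs, 0, 6)
        m = tp.UnivariateACE(seed=0).fit(X)
        m.wald_se()
        lo, hi = m.profile_ci("e_var")
        assert lo < m.estimates_["e_var"] < hi


class TestDeterminism:
    def test_fit_is_deterministic_given_seed(self, study_pairs):
        r1 = tp.AutoregressionACE(seed=3, n_restarts=1).fit(study_pairs).result_
        r2 = tp.AutoregressionACE(seed=3, n_restarts=1).fit(study_pairs).result_
        assert r1.minus2ll == r2.minus2ll
        assert np.array_equal(r1.theta, r2.theta)
        assert r1.to_json() == r2.to_json()
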
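"""Scikit-learn style estimators for the twin model families.

Each estimator wraps a model builder and the FIML engine: construct with the
family's structural options, call ``fit(X)`` on a wide twin-pair table
(``zygosity``, ``sex_1``, ``sex_2``, ``y1_t0..``, ``y2_t0..`` with NaN for
missing), and read the fitted attributes (``estimates_``, ``minus2ll_``,
``aic_``, ``converged_``, ...).  ``get_params``/``set_params`` follow the
scikit-learn contract, so the estimators compose with its model-selection
utilities; ``score(X)`` returns the mean log-likelihood per pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import fiml
from .fiml import PairData, pair_columns
from .pathmodel import PathModel
from . import zoo

__all__ = [
    "TwinPairModel",
    "SaturatedTwinModel",
    "TwinCorrelations",
    "UnivariateACE",
    "CorrelatedFactorsACE",
    "AutoregressionACE",
    "LatentGrowthACE",
    "DualChangeACE",
    "CommonPathwayACE",
    "IndependentPathwayACE",
    "subset_occasion",
    "ESTIMATOR_FAMILIES",
]


def _summary(X: pd.DataFrame, T: int):
    """Per-occasion pooled means/variances and within-twin covariance (pairwise)."""
    blocks = [X[[f"y{j}_t{t}" for t in range(T)]].to_numpy(float) for j in (1, 2)]
    stacked = pd.DataFrame(np.vstack(blocks))
    means = stacked.mean().to_numpy()
    means = np.where(np.isfinite(means), means, 0.0)
    S = stacked.cov(min_periods=3).to_numpy()
    d = np.diag(S).copy()
    d = np.where(np.isfinite(d) & (d > 1e-8), d, np.nanmean(d) if np.isfinite(np.nanmean(d)) else 1.0)
    S = np.where(np.isfinite(S), S, 0.0)
    np.fill_diagonal(S, d)
    # nudge to positive definiteness for use as a starting value
    w, V = np.linalg.eigh((S + S.T) / 2)
    S = (V * np.clip(w, 1e-4 * d.mean(), None)) @ V.T
    return means, np.diag(S).copy(), S


def subset_occasion(X: pd.DataFrame, occasion: int, T: int) -> pd.DataFrame:
    """Single-occasion (T=1) pair table; pairs with no data at it are dropped."""
    out = X[["family_id", "zygosity", "sex_1", "sex_2"]].copy() \
        if "family_id" in X.columns else X[["zygosity", "sex_1", "sex_2"]].copy()
    out["y1_t0"] = X[f"y1_t{occasion}"].to_numpy(float)
    out["y2_t0"] = X[f"y2_t{occasion}"].to_numpy(float)
    keep = out[["y1_t0", "y2_t0"]].notna().any(axis=1)
    return out[keep].reset_index(drop=True)


class TwinPairModel(BaseEstimator):
    """Base estimator: build a moment model, fit it by FIML, expose the result."""

    def __init__(self, T=6, n_restarts=2, seed=0, maxiter=1000):
        self.T = T
        self.n_restarts = n_restarts
        self.seed = seed
        self.maxiter = maxiter

    # subclasses override
    def _build(self, X: pd.DataFrame):
        raise NotImplementedError

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        self.data_ = PairData(X, self.T)
        self.model_ = self._build(X)
        self.result_ = fiml.fit(self.model_, self.data_, maxiter=self.maxiter,
                                n_restarts=self.n_restarts, seed=self.seed)
        self.estimates_ = self.result_.estimates
        self.minus2ll_ = self.result_.minus2ll
        self.n_parameters_ = self.result_.ep
        self.aic_ = self.result_.aic
        self.converged_ = self.result_.converged
        return self

    def _validate(self, X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a wide twin-pair DataFrame")
        missing = [c for c in ["zygosity", "sex_1", "sex_2"] + pair_columns(self.T)
                   if c not in X.columns]
        if missing:
            raise ValueError(f"pair table lacks columns {missing}")
        return X

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per pair (higher is better)."""
        self._check_fitted()
        data = PairData(self._validate(X), self.T)
        mu, Sigma, beta = self.model_.implied(self.result_.theta)
        return -0.5 * data.neg2ll(mu, Sigma, beta) / data.n_pairs

    def wald_se(self) -> dict:
        self._check_fitted()
        return fiml.wald_se(self.model_, self.data_, self.result_)

    def profile_ci(self, label: str, level: float = 0.95):
        self._check_fitted()
        return fiml.profile_ci(self.model_, self.data_, self.result_, label,
                               level=level)

    def implied_moments(self, zygosity: str, sex_1: float = 0.0, sex_2: float = 0.0):
        self._check_fitted()
        return self.model_.pair_moments(self.result_.theta, zygosity, sex_1, sex_2)

    def standardized_components(self):
        self._check_fitted()
        if not isinstance(self.model_, PathModel):
            raise TypeError("standardized components need a structural path model")
        return self.model_.standardized_components(self.result_.theta)


class SaturatedTwinModel(TwinPairModel):
    """Free means/(co)variances per twin order and zygosity; homogeneity variants
    equate means or variances across twin order ("twin") or zygosity ("zyg")."""

    def __init__(self, T=1, means="free", variances="free", include_sex=False,
                 n_restarts=2, seed=0, maxiter=1000):
        super().__init__(T=T, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.means = means
        self.variances = variances
        self.include_sex = include_sex

    def _build(self, X):
        model = zoo.build_saturated(self.T, means=self.means,
                                    variances=self.variances,
                                    include_sex=self.include_sex)
        means, var, S = _summary(X, self.T)
        start = {}
        for lab in model.labels:
            parts = lab.split("_")
            if lab.startswith("m_"):
                start[lab] = float(means[int(parts[-1]) - 1])
            elif lab.startswith("v_"):
                start[lab] = float(var[int(parts[-1]) - 1])
            elif lab.startswith("cv_"):
                a, b = int(parts[-2]) - 1, int(parts[-1]) - 1
                ta, tb = a % self.T, b % self.T
                same_twin = (a < self.T) == (b < self.T)
                start[lab] = float(S[ta, tb] * (1.0 if same_twin else 0.35))
            else:
                start[lab] = 0.0
        model.set_start(start)
        return model


class TwinCorrelations(TwinPairModel):
    """FIML twin-pair correlations by zygosity at one occasion."""

    def __init__(self, occasion=0, include_sex=True, n_restarts=2, seed=0,
                 maxiter=1000):
        super().__init__(T=1, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.occasion = occasion
        self.include_sex = include_sex

    def fit(self, X, y=None):
        Tsrc = sum(c.startswith("y1_t") for c in X.columns)
        if Tsrc > 1 or self.occasion != 0:
            X = subset_occasion(X, self.occasion, Tsrc)
        super().fit(X)
        self.r_mz_ = self.estimates_["r_mz"]
        self.r_dz_ = self.estimates_["r_dz"]
        return self

    def _build(self, X):
        model = zoo.TwinCorrelationModel(include_sex=self.include_sex)
        stacked = np.concatenate([X["y1_t0"].to_numpy(float),
                                  X["y2_t0"].to_numpy(float)])
        m = float(np.nanmean(stacked))
        v = float(np.nanvar(stacked))
        model.set_start({"mean_mz": m, "mean_dz": m,
                         "var_mz": max(v, 1e-3), "var_dz": max(v, 1e-3)})
        return model


class UnivariateACE(TwinPairModel):
    """Single-occasion A/C/E variance decomposition (negative-C convention).

    ``drop`` fixes kinds to zero: ("C",) -> AE, ("A",) -> CE, ("A","C") -> E.
    """

    def __init__(self, occasion=None, drop=(), n_restarts=2, seed=0,
                 maxiter=1000):
        super().__init__(T=1, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.occasion = occasion
        self.drop = drop

    def fit(self, X, y=None):
        if self.occasion is not None:
            Tsrc = sum(c.startswith("y1_t") for c in X.columns)
            X = subset_occasion(X, self.occasion, Tsrc)
        return super().fit(X)

    def _build(self, X):
        model = zoo.build_univariate_ace(drop=tuple(self.drop))
        means, var, _ = _summary(X, 1)
        v = float(var[0])
        model.set_start({"a_var": 0.3 * v, "c_var": 0.15 * v, "e_var": 0.45 * v,
                         "mu_1": float(means[0]), "beta_sex": 0.0})
        return model


def _scaled_start(model, labels_scale_sqrt, labels_scale_var, means, var):
    """Common start heuristic: path labels scale with the phenotypic SD."""
    start = {}
    vbar = float(np.mean(var))
    for lab in model.labels:
        if lab.startswith("mu_"):
            start[lab] = float(means[int(lab.split("_")[-1]) - 1])
    start.update({lab: np.sqrt(f * vbar) for lab, f in labels_scale_sqrt.items()})
    start.update({lab: f * vbar for lab, f in labels_scale_var.items()})
    start["beta_sex"] = 0.0
    return {k: v for k, v in start.items() if k in set(model.labels)}


class CorrelatedFactorsACE(TwinPairModel):
    """Reference model: free latent A/C/E covariance matrices."""

    def _build(self, X):
        model = zoo.build_correlated_factors(self.T)
        means, var, S = _summary(X, self.T)
        start = {}
        for frac, kl in (0.35, "a"), (0.15, "c"), (0.5, "e"):
            for i in range(self.T):
                for j in range(i + 1):
                    start[f"{kl}_cov_{i + 1}_{j + 1}"] = float(frac * S[i, j])
        for t in range(self.T):
            start[f"mu_{t + 1}"] = float(means[t])
        start["beta_sex"] = 0.0
        model.set_start(start)
        return model


class AutoregressionACE(TwinPairModel):
    """Genetic/environmental simplex with equated transmission and residual.

    ``kinds`` selects the included processes (("A","E") is the AE submodel);
    ``prune`` maps a kind to its last retained occasion, e.g. {"C": 2}.
    """

    def __init__(self, T=6, kinds=("A", "C", "E"), prune=None, n_restarts=2,
                 seed=0, maxiter=1000):
        super().__init__(T=T, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.kinds = kinds
        self.prune = prune

    def _build(self, X):
        model = zoo.build_autoregression(self.T, kinds=tuple(self.kinds),
                                         prune=self.prune)
        means, var, _ = _summary(X, self.T)
        sq = {}
        share = {"a": 0.3, "c": 0.1, "e": 0.1}
        for kl in ("a", "c", "e"):
            for t in range(self.T):
                sq[f"{kl}_innov_{t + 1}"] = share[kl]
        sq["res"] = 0.4
        start = _scaled_start(model, sq, {}, means, var)
        for kl, b in ("a", 0.6), ("c", 0.4), ("e", 0.3):
            if f"beta_{kl}" in model.labels:
                start[f"beta_{kl}"] = b
        model.set_start(start)
        return model


class LatentGrowthACE(TwinPairModel):
    """Biometric latent growth curve (intercept/linear[/quadratic])."""

    def __init__(self, T=6, degree=2, n_restarts=2, seed=0, maxiter=1000):
        super().__init__(T=T, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.degree = degree

    def _build(self, X):
        model = zoo.build_latent_growth(self.T, degree=self.degree)
        means, var, _ = _summary(X, self.T)
        vbar = float(np.mean(var))
        start = {}
        fnames = ("int", "lin", "quad")[: self.degree + 1]
        scale = {"int": 0.12, "lin": 0.004, "quad": 0.0002}
        for kl in ("a", "c", "e"):
            for i, fi in enumerate(fnames):
                for fj in fnames[: i + 1]:
                    start[f"{kl}_{fi}_{fj}"] = scale[fi] * vbar if fi == fj else 0.0
            for t in range(self.T):
                start[f"{kl}_res_{t + 1}"] = np.sqrt(0.2 * vbar)
        G = zoo.growth_design(self.T, self.degree)
        coef, *_ = np.linalg.lstsq(G, means, rcond=None)
        for f, c in zip(fnames, coef):
            start[f"mean_{f}"] = float(c)
        start["beta_sex"] = 0.0
        model.set_start(start)
        return model


class DualChangeACE(TwinPairModel):
    """Dual change score: latent growth plus proportional change, per kind."""

    def _build(self, X):
        model = zoo.build_dual_change(self.T)
        means, var, _ = _summary(X, self.T)
        vbar = float(np.mean(var))
        start = {}
        for kl in ("a", "c", "e"):
            start.update({f"{kl}_lvl_lvl": 0.12 * vbar, f"{kl}_lvl_slp": 0.0,
                          f"{kl}_slp_slp": 0.004 * vbar, f"{kl}_prop": 0.0})
            for t in range(self.T):
                start[f"{kl}_res_{t + 1}"] = np.sqrt(0.2 * vbar)
        G = zoo.growth_design(self.T, 1)
        coef, *_ = np.linalg.lstsq(G, means, rcond=None)
        start.update({"mean_level": float(coef[0]), "mean_slope": float(coef[1]),
                      "beta_sex": 0.0})
        model.set_start(start)
        return model


class CommonPathwayACE(TwinPairModel):
    """k common liabilities decomposed into A/C/E, per-kind occasion residuals."""

    def __init__(self, T=6, k=1, n_restarts=2, seed=0, maxiter=1000):
        super().__init__(T=T, n_restarts=n_restarts, seed=seed, maxiter=maxiter)
        self.k = k

    def _build(self, X):
        model = zoo.build_common_pathway(self.T, self.k)
        means, var, _ = _summary(X, self.T)
        vbar = float(np.mean(var))
        start = {}
        for lab in model.labels:
            if "_load_" in lab:
                start[lab] = 0.9
            elif lab.startswith("cp"):
                start[lab] = np.sqrt(0.12 * vbar)
            elif "_res_" in lab:
                start[lab] = np.sqrt(0.2 * vbar)
        for t in range(self.T):
            start[f"mu_{t + 1}"] = float(means[t])
        start["beta_sex"] = 0.0
        model.set_start(start)
        return model


class IndependentPathwayACE(TwinPairModel):
    """Separate common A, C and E factors plus per-kind occasion residuals."""

    def _build(self, X):
        model = zoo.build_independent_pathway(self.T)
        means, var, _ = _summary(X, self.T)
        vbar = float(np.mean(var))
        start = {}
        for kl in ("a", "c", "e"):
            for t in range(self.T):
                start[f"{kl}_common_{t + 1}"] = np.sqrt(0.15 * vbar)
                start[f"{kl}_res_{t + 1}"] = np.sqrt(0.2 * vbar)
        for t in range(self.T):
            start[f"mu_{t + 1}"] = float(means[t])
        start["beta_sex"] = 0.0
        model.set_start(start)
        return model


#: multivariate families in the comparison workflow, keyed by table name
ESTIMATOR_FAMILIES = {
    "autoregression": AutoregressionACE,
    "latent_growth": LatentGrowthACE,
    "dual_change": DualChangeACE,
    "common_pathway_1": lambda **kw: CommonPathwayACE(k=1, **kw),
    "common_pathway_2": lambda **kw: CommonPathwayACE(k=2, **kw),
    "common_pathway_3": lambda **kw: CommonPathwayACE(k=3, **kw),
    "independent_pathway": IndependentPathwayACE,
}
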
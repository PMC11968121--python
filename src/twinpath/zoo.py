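"""Builders for the competing longitudinal twin models.

Each builder returns a fully labelled :class:`~twinpath.pathmodel.PathModel`
(or a saturated-moments model) with the identification constraints of the
corresponding hypothesis baked in:

* ``build_saturated`` — free means/variances/covariances per twin order and
  zygosity, with optional equality classes for the homogeneity tests.
* ``build_univariate_ace`` — single-occasion A/C/E variance decomposition on
  the variance scale, so the shared component may go negative (sign indicates
  whether shared environment or genetic non-additivity predominates).
* ``build_correlated_factors`` — the atheoretical reference model: a full free
  latent covariance per kind.
* ``build_autoregression`` — genetic simplex: first-order transmission with a
  single beta per kind equated over time, free innovation paths, innovation
  variances fixed to 1, loadings fixed to 1, residual variance equated across
  occasions.
* ``build_latent_growth`` — intercept/linear(/quadratic) growth factors with a
  free factor covariance per kind and per-kind occasion residuals.
* ``build_dual_change`` — latent-difference hybrid of growth and
  autoregression.
* ``build_common_pathway`` — k common liabilities, each decomposed into
  A/C/E, echelon loadings with the first fixed to 1 per factor.
* ``build_independent_pathway`` — separate common A, C and E factors.
"""

from __future__ import annotations

import numpy as np

from .pathmodel import (
    KINDS,
    _fast_resolve,
    Cell,
    Diag,
    DualChange,
    Factor,
    FreeCov,
    MeanSpec,
    MomentModel,
    PathModel,
    Simplex,
    SpecificationError,
    _val,
    _cells_of,
)

__all__ = [
    "SaturatedModel",
    "TwinCorrelationModel",
    "build_saturated",
    "build_univariate_ace",
    "build_correlated_factors",
    "build_autoregression",
    "build_latent_growth",
    "build_dual_change",
    "build_common_pathway",
    "build_independent_pathway",
    "MODEL_BUILDERS",
]


# ---------------------------------------------------------------------------
# saturated moments
# ---------------------------------------------------------------------------


class SaturatedModel(MomentModel):
    """Free mean vector and covariance matrix per zygosity group.

    Cells are plain labels, so equality constraints (twin 1 = twin 2 within
    zygosity; MZ = DZ) are expressed by sharing labels; that is how the mean-
    and variance-homogeneity likelihood-ratio tests are formed.
    """

    def __init__(self, T, mean_cells, cov_cells, beta_sex: Cell = 0.0,
                 start=None, name="saturated"):
        self.T = int(T)
        self.mean_cells = mean_cells      # (2, 2T) nested lists of cells
        self.cov_cells = cov_cells        # (2, 2T, 2T) symmetric cells
        self.beta_sex = beta_sex
        self.name = name
        self._start = dict(start or {})
        seen: dict[str, None] = {}
        for l in _cells_of([self.mean_cells, self.cov_cells, [self.beta_sex]]):
            seen.setdefault(l)
        self._labels = list(seen)

    @property
    def labels(self):
        return self._labels

    @property
    def start(self):
        return np.array([self._start.get(l, _default_sat_start(l)) for l in self._labels])

    def set_start(self, values):
        self._start.update(values)
        return self

    def implied(self, theta):
        vals = self.values_from(theta)
        mu = _fast_resolve(self, "mean_cells", vals)
        S = _fast_resolve(self, "cov_cells", vals)
        Sigma = (S + np.transpose(S, (0, 2, 1))) / 2.0
        return mu, Sigma, _val(self.beta_sex, vals)


def _default_sat_start(label: str) -> float:
    if label.startswith("v_"):
        return 1.0
    if label.startswith("cv_"):
        return 0.1
    return 0.0


def build_saturated(T=1, means="free", variances="free", covariances="free",
                    include_sex=False) -> SaturatedModel:
    """Saturated twin-pair model with optional homogeneity equality classes.

    Parameters
    ----------
    means, variances : {"free", "twin", "zyg"}
        "twin" equates twin 1 and twin 2 within each zygosity group; "zyg"
        additionally equates MZ and DZ (the full homogeneity hypothesis).
    covariances : {"free", "zyg"}
        Cross-twin / cross-occasion covariances per zygosity; "zyg" equates
        them across zygosity (rarely wanted — it removes the twin design).
    """
    zyg_names = ("mz", "dz")

    def mean_label(z, j, t):
        zl, tw = zyg_names[z], j + 1
        if means == "zyg":
            return f"m_{t + 1}"
        if means == "twin":
            return f"m_{zl}_{t + 1}"
        return f"m_{zl}_tw{tw}_{t + 1}"

    def var_label(z, j, t):
        zl, tw = zyg_names[z], j + 1
        if variances == "zyg":
            return f"v_{t + 1}"
        if variances == "twin":
            return f"v_{zl}_{t + 1}"
        return f"v_{zl}_tw{tw}_{t + 1}"

    def cov_label(z, a, b):
        zl = zyg_names[z] if covariances != "zyg" else "all"
        return f"cv_{zl}_{a + 1}_{b + 1}"

    mean_cells = [[mean_label(z, j, t) for j in range(2) for t in range(T)]
                  for z in range(2)]
    cov_cells = []
    for z in range(2):
        M = [[0.0] * (2 * T) for _ in range(2 * T)]
        for a in range(2 * T):
            j, t = divmod(a, T)
            M[a][a] = var_label(z, j, t)
            for b in range(a):
                M[a][b] = M[b][a] = cov_label(z, a, b)
        cov_cells.append(M)
    return SaturatedModel(
        T, mean_cells, cov_cells,
        beta_sex="beta_sex" if include_sex else 0.0,
        name=f"saturated(means={means},variances={variances})",
    )


class TwinCorrelationModel(MomentModel):
    """Single-occasion saturated model parameterized by the twin correlation.

    Per zygosity: one mean (equated across twin order), one variance, and the
    within-pair correlation ``r`` as a free parameter, so FIML gives the twin
    correlation and its likelihood-based confidence interval directly.
    """

    T = 1

    def __init__(self, include_sex=True, start=None, name="twin_correlation"):
        self.beta_sex = "beta_sex" if include_sex else 0.0
        self.name = name
        self._labels = ["mean_mz", "mean_dz", "var_mz", "var_dz", "r_mz", "r_dz"]
        if include_sex:
            self._labels.append("beta_sex")
        self._start = {"mean_mz": 0.0, "mean_dz": 0.0, "var_mz": 1.0,
                       "var_dz": 1.0, "r_mz": 0.4, "r_dz": 0.2, "beta_sex": 0.0}
        self._start.update(start or {})

    @property
    def labels(self):
        return self._labels

    @property
    def start(self):
        return np.array([self._start[l] for l in self._labels])

    def set_start(self, values):
        self._start.update(values)
        return self

    def implied(self, theta):
        v = self.values_from(theta)
        mu = np.array([[v["mean_mz"]] * 2, [v["mean_dz"]] * 2])
        Sigma = np.empty((2, 2, 2))
        for z, zl in enumerate(("mz", "dz")):
            var, r = v[f"var_{zl}"], v[f"r_{zl}"]
            Sigma[z] = var * np.array([[1.0, r], [r, 1.0]])
        beta = v.get("beta_sex", 0.0) if isinstance(self.beta_sex, str) else 0.0
        return mu, Sigma, beta


# ---------------------------------------------------------------------------
# structural families
# ---------------------------------------------------------------------------


def _occ_means(T):
    return MeanSpec.occasion(T)


def _mean_start(T):
    return {f"mu_{t + 1}": 0.0 for t in range(T)}


def build_univariate_ace(drop=()) -> PathModel:
    """Single-occasion ACE decomposition on the variance scale.

    ``drop`` fixes components to zero: e.g. ``drop=("C",)`` gives the AE
    submodel, ``drop=("A", "C")`` the E-only model.  The C variance is
    unbounded below (negative-C convention).
    """
    comps = {}
    for kind in KINDS:
        label = f"{kind.lower()}_var"
        cell: Cell = 0.0 if kind in drop else label
        comps[kind] = [FreeCov([[cell]])]
    start = {"a_var": 0.3, "c_var": 0.1, "e_var": 0.4, "mu_1": 0.0, "beta_sex": 0.0}
    name = "univariate_" + "".join(k for k in KINDS if k not in drop)
    return PathModel(1, comps, [0.0], _occ_means(1), start=start, name=name)


def build_correlated_factors(T=6) -> PathModel:
    """Reference model: full free latent covariance per kind (variance scale)."""
    comps = {}
    start = {}
    for kind in KINDS:
        kl = kind.lower()
        cells = [[None] * T for _ in range(T)]
        for i in range(T):
            for j in range(i + 1):
                lab = f"{kl}_cov_{i + 1}_{j + 1}"
                cells[i][j] = cells[j][i] = lab
                start[lab] = 0.2 if i == j else 0.05
        comps[kind] = [FreeCov(cells)]
    start.update(_mean_start(T))
    start["beta_sex"] = 0.0
    return PathModel(T, comps, [0.0] * T, _occ_means(T), start=start,
                     name="correlated_factors")


def build_autoregression(T=6, kinds=("A", "C", "E"), prune=None,
                         equal_residual=True) -> PathModel:
    """Genetic/environmental simplex (first-order autoregression).

    Per included kind: T free innovation path coefficients and one shared
    transmission coefficient (beta equated across time); innovation variances
    and latent loadings fixed to 1.  The occasion residual is equated across
    occasions for identification and parsimony.

    ``prune`` maps a kind to its last retained occasion: ``{"C": 2}`` fixes
    the C innovations at occasions 3..T to zero and truncates the C
    transmission chain after occasion 2 (the post-hoc pruning structure).
    """
    prune = dict(prune or {})
    comps = {k: [] for k in KINDS}
    start = {}
    dropped = []
    for kind in KINDS:
        if kind not in kinds:
            continue
        kl = kind.lower()
        last = prune.get(kind, T)
        if last < 1:
            raise SpecificationError("pruning must retain at least occasion 1")
        innov = []
        for t in range(T):
            if t < last:
                lab = f"{kl}_innov_{t + 1}"
                innov.append(lab)
                start[lab] = 0.3
            else:
                innov.append(0.0)
                dropped.append(f"{kl}_innov_{t + 1}")
        if last > 1:
            trans = [f"beta_{kl}" if t + 1 < last else 0.0 for t in range(T - 1)]
            start[f"beta_{kl}"] = 0.4
        else:
            trans = [0.0] * (T - 1)
        comps[kind].append(Simplex(innov, trans))
    if not any(comps.values()) and not equal_residual:
        raise SpecificationError("autoregression spec with no kinds and no residual")
    res = ["res"] * T if equal_residual else [f"res_{t + 1}" for t in range(T)]
    start["res"] = 0.5
    if not equal_residual:
        start.update({f"res_{t + 1}": 0.5 for t in range(T)})
    start.update(_mean_start(T))
    start["beta_sex"] = 0.0
    name = "autoregression_" + "".join(kinds)
    if prune:
        name += "_pruned" + "".join(f"_{k}{v}" for k, v in sorted(prune.items()))
    bounds = {f"beta_{k.lower()}": (-0.99, 0.99) for k in kinds
              if f"beta_{k.lower()}" in start}
    return PathModel(T, comps, res, _occ_means(T), start=start, name=name,
                     bounds=bounds)


def growth_design(T, degree):
    """Growth loadings: intercept column of ones, linear 0..T-1, quadratic squares."""
    cols = [np.ones(T), np.arange(T, dtype=float)]
    if degree >= 2:
        cols.append(np.arange(T, dtype=float) ** 2)
    return np.column_stack(cols)


def build_latent_growth(T=6, degree=2) -> PathModel:
    """Latent growth curve with biometric decomposition of the growth factors.

    Linear loadings are 0, 1, ..., T-1 (0..5 at six occasions); quadratic
    loadings are their squares.  Each kind carries a free factor covariance
    and per-kind occasion residual paths.  Growth-factor means are free.
    """
    if degree not in (1, 2):
        raise SpecificationError("growth degree must be 1 or 2")
    G = growth_design(T, degree)
    fnames = ("int", "lin", "quad")[: degree + 1]
    comps = {}
    start = {}
    for kind in KINDS:
        kl = kind.lower()
        m = degree + 1
        cells = [[None] * m for _ in range(m)]
        for i in range(m):
            for j in range(i + 1):
                lab = f"{kl}_{fnames[i]}_{fnames[j]}"
                cells[i][j] = cells[j][i] = lab
                start[lab] = 0.1 if i == j else 0.0
        res = [f"{kl}_res_{t + 1}" for t in range(T)]
        start.update({r: 0.3 for r in res})
        comps[kind] = [FreeCov(cells, loadings=G), Diag(res)]
    mean = MeanSpec(G, [f"mean_{f}" for f in fnames])
    start.update({f"mean_{f}": 0.0 for f in fnames})
    start["beta_sex"] = 0.0
    return PathModel(T, comps, [0.0] * T, mean, start=start,
                     name=f"latent_growth_deg{degree}")


def build_dual_change(T=6) -> PathModel:
    """Dual change score: latent growth plus proportional (autoregressive) change.

    Per kind, a latent level/constant-change pair with free 2x2 covariance and
    one proportional coefficient; the phenotypic mean follows a linear
    trajectory so the zero-proportional limit is exactly the linear growth
    model.
    """
    comps = {}
    start = {}
    for kind in KINDS:
        kl = kind.lower()
        cells = [[f"{kl}_lvl_lvl", f"{kl}_lvl_slp"], [f"{kl}_lvl_slp", f"{kl}_slp_slp"]]
        start.update({f"{kl}_lvl_lvl": 0.15, f"{kl}_lvl_slp": 0.0,
                      f"{kl}_slp_slp": 0.02, f"{kl}_prop": 0.0})
        res = [f"{kl}_res_{t + 1}" for t in range(T)]
        start.update({r: 0.3 for r in res})
        comps[kind] = [DualChange(cells, f"{kl}_prop"), Diag(res)]
    mean = MeanSpec(growth_design(T, 1), ["mean_level", "mean_slope"])
    start.update({"mean_level": 0.0, "mean_slope": 0.0, "beta_sex": 0.0})
    bounds = {f"{k.lower()}_prop": (-0.99, 0.99) for k in KINDS}
    return PathModel(T, comps, [0.0] * T, mean, start=start, name="dual_change",
                     bounds=bounds)


def build_common_pathway(T=6, k=1) -> PathModel:
    """k common liabilities, each decomposed into A, C and E.

    Identification: echelon loadings — factor f loads 0 on occasions < f and
    1 on occasion f; factors are orthogonal.  The same loading labels appear
    in the A, C and E blocks (the liability is a single latent variable whose
    variance is split), while each factor's kind path scales are free.
    Occasion residuals are decomposed per kind.
    """
    if k >= T:
        raise SpecificationError(f"{k} common factors are not identified with T={T}")
    if k < 1:
        raise SpecificationError("need at least one common factor")
    load_cells = [[None] * k for _ in range(T)]
    start = {}
    for f in range(k):
        for t in range(T):
            if t < f:
                load_cells[t][f] = 0.0
            elif t == f:
                load_cells[t][f] = 1.0
            else:
                lab = f"cp{f + 1}_load_{t + 1}"
                load_cells[t][f] = lab
                start[lab] = 0.8
    comps = {}
    for kind in KINDS:
        kl = kind.lower()
        scales = [f"cp{f + 1}_{kl}" for f in range(k)]
        start.update({s: 0.3 for s in scales})
        res = [f"{kl}_res_{t + 1}" for t in range(T)]
        start.update({r: 0.3 for r in res})
        comps[kind] = [Factor(load_cells, scales), Diag(res)]
    start.update(_mean_start(T))
    start["beta_sex"] = 0.0
    return PathModel(T, comps, [0.0] * T, _occ_means(T), start=start,
                     name=f"common_pathway_{k}")


def build_independent_pathway(T=6) -> PathModel:
    """Separate common A, C and E factors with free loadings per occasion.

    Factor variances fixed to 1 (scale carried by the loadings; loading signs
    are resolved by a first-loading-positive reporting convention).  Occasion
    residuals are decomposed per kind.
    """
    comps = {}
    start = {}
    for kind in KINDS:
        kl = kind.lower()
        loads = [[f"{kl}_common_{t + 1}"] for t in range(T)]
        start.update({f"{kl}_common_{t + 1}": 0.3 for t in range(T)})
        res = [f"{kl}_res_{t + 1}" for t in range(T)]
        start.update({r: 0.3 for r in res})
        comps[kind] = [Factor(loads, [1.0]), Diag(res)]
    start.update(_mean_start(T))
    start["beta_sex"] = 0.0
    return PathModel(T, comps, [0.0] * T, _occ_means(T), start=start,
                     name="independent_pathway")


MODEL_BUILDERS = {
    "correlated_factors": build_correlated_factors,
    "autoregression": build_autoregression,
    "latent_growth": build_latent_growth,
    "dual_change": build_dual_change,
    "common_pathway_1": lambda T=6: build_common_pathway(T, 1),
    "common_pathway_2": lambda T=6: build_common_pathway(T, 2),
    "common_pathway_3": lambda T=6: build_common_pathway(T, 3),
    "independent_pathway": build_independent_pathway,
}
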
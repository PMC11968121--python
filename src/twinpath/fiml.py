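"""Raw-data full-information maximum likelihood (FIML) for twin pairs.

Each pair contributes the multivariate-normal −2 log-likelihood of its
*observed* subvector, so incomplete pairs (including singleton twins whose
co-twin is entirely missing) enter the likelihood without deletion.  The sex
covariate shifts the per-twin means (a definition variable).

Pairs are grouped by (zygosity, missing pattern); per group, sufficient
statistics (sums of outer products of scores and sex indicators) are
precomputed once per dataset, so one likelihood evaluation costs a handful of
batched small-matrix operations per distinct pattern size, independent of the
number of pairs.  The gradient with respect to the model-implied moments is
exact; it is chained to the free parameters through a finite-difference
Jacobian of the (cheap) moment-assembly map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pathmodel import ModelMoments, MomentModel

LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = ["PairData", "FitResult", "pair_loglik", "fit", "wald_se", "profile_ci"]


def pair_columns(T: int) -> list[str]:
    return [f"y{j}_t{t}" for j in (1, 2) for t in range(T)]


def pair_loglik(y: np.ndarray, moments: ModelMoments) -> float:
    """−2 log-likelihood contribution of one pair's stacked vector.

    ``y`` may contain NaN for missing elements; the density is evaluated on
    the observed subset.  Returns +inf (an optimizer barrier) when the
    selected covariance block is not positive definite.
    """
    y = np.asarray(y, float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("pair has no observed elements")
    r = y[obs] - moments.mean[obs]
    S = moments.cov[np.ix_(obs, obs)]
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return np.inf
    z = np.linalg.solve(L, r)
    k = int(obs.sum())
    return k * LOG_2PI + 2.0 * float(np.log(np.diag(L)).sum()) + float(z @ z)


@dataclass
class _Bucket:
    """Pattern groups sharing one observed-subset size k."""

    idx: np.ndarray   # (G, k) observed column indices
    zyg: np.ndarray   # (G,) 0 = MZ, 1 = DZ
    n: np.ndarray     # (G,) pairs per group
    Sy: np.ndarray    # (G, k) sum of y
    Syy: np.ndarray   # (G, k, k) sum of y y'
    Ss: np.ndarray    # (G, k) sum of sex vectors
    Sys: np.ndarray   # (G, k, k) sum of y s'
    Sss: np.ndarray   # (G, k, k) sum of s s'


class PairData:
    """Twin-pair dataset preprocessed for FIML evaluation.

    Built from a wide table with one row per family: ``zygosity`` (MZ/DZ),
    ``sex_1``, ``sex_2`` and score columns ``y1_t0..y1_t{T-1}``,
    ``y2_t0..y2_t{T-1}`` with NaN marking missing scores.
    """

    def __init__(self, pairs: pd.DataFrame, T: int):
        self.T = int(T)
        cols = pair_columns(T)
        missing = [c for c in cols if c not in pairs.columns]
        if missing:
            raise ValueError(f"pair table lacks score columns {missing}")
        Y = pairs[cols].to_numpy(float)
        zyg_raw = pairs["zygosity"].astype(str).str.upper().to_numpy()
        bad = ~np.isin(zyg_raw, ("MZ", "DZ"))
        if bad.any():
            raise ValueError(f"unknown zygosity codes: {set(zyg_raw[bad])}")
        zyg = (zyg_raw == "DZ").astype(np.int64)
        s1 = pairs["sex_1"].to_numpy(float)
        s2 = pairs["sex_2"].to_numpy(float)
        S = np.concatenate([np.repeat(s1[:, None], T, 1),
                            np.repeat(s2[:, None], T, 1)], axis=1)
        obs = ~np.isnan(Y)
        if not obs.any(axis=1).all():
            raise ValueError("every pair must have at least one observed score")
        # sex must be known wherever a twin contributes data
        if np.isnan(S[obs]).any():
            raise ValueError("sex covariate missing for an observed twin")

        self.n_pairs = len(Y)
        self.n_mz = int((zyg == 0).sum())
        self.n_dz = int((zyg == 1).sum())
        self.Y, self.zyg, self.S = Y, zyg, S

        # group pairs by (zygosity, observation pattern)
        pattern = obs @ (1 << np.arange(2 * T, dtype=np.int64))
        key = pattern * 2 + zyg
        uniq, inv = np.unique(key, return_inverse=True)
        by_k: dict[int, list] = {}
        for g, _ in enumerate(uniq):
            rows = np.where(inv == g)[0]
            cols_g = np.where(obs[rows[0]])[0]
            k = len(cols_g)
            Yo = Y[rows][:, cols_g]
            So = S[rows][:, cols_g]
            by_k.setdefault(k, []).append((
                cols_g, zyg[rows[0]], len(rows),
                Yo.sum(0), Yo.T @ Yo, So.sum(0), Yo.T @ So, So.T @ So,
            ))
        self.buckets: list[_Bucket] = []
        for k in sorted(by_k):
            groups = by_k[k]
            self.buckets.append(_Bucket(
                idx=np.array([g[0] for g in groups]),
                zyg=np.array([g[1] for g in groups]),
                n=np.array([g[2] for g in groups], float),
                Sy=np.array([g[3] for g in groups]),
                Syy=np.array([g[4] for g in groups]),
                Ss=np.array([g[5] for g in groups]),
                Sys=np.array([g[6] for g in groups]),
                Sss=np.array([g[7] for g in groups]),
            ))
        self.n_groups = int(sum(len(b.n) for b in self.buckets))

    # -- likelihood ---------------------------------------------------------

    def neg2ll(self, mu, Sigma, beta, grad=False):
        """Total −2 log-likelihood given per-zygosity moments.

        ``mu``: (2, 2T) base means (MZ row, DZ row), before the sex shift;
        ``Sigma``: (2, 2T, 2T); ``beta``: sex regression on the means.
        With ``grad=True`` also returns (d/dmu, d/dSigma, d/dbeta).
        """
        mu = np.asarray(mu, float)
        Sigma = np.asarray(Sigma, float)
        total = 0.0
        if grad:
            gmu = np.zeros_like(mu)
            gSig = np.zeros_like(Sigma)
            gbeta = 0.0
        for b in self.buckets:
            G, k = b.idx.shape
            Sig = Sigma[b.zyg[:, None, None], b.idx[:, :, None], b.idx[:, None, :]]
            a = mu[b.zyg[:, None], b.idx]
            try:
                L = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return (np.inf, None, None, None) if grad else np.inf
            logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            inv = np.linalg.inv(Sig)
            na = b.n[:, None] * a
            W = (b.Syy
                 - np.einsum("gi,gj->gij", b.Sy, a) - np.einsum("gi,gj->gij", a, b.Sy)
                 + np.einsum("gi,gj->gij", na, a)
                 - beta * (b.Sys + b.Sys.transpose(0, 2, 1))
                 + beta * (np.einsum("gi,gj->gij", a, b.Ss)
                           + np.einsum("gi,gj->gij", b.Ss, a))
                 + beta * beta * b.Sss)
            quad = np.einsum("gij,gij->g", inv, W)
            total += float((b.n * (k * LOG_2PI + logdet) + quad).sum())
            if grad:
                dSig = inv * b.n[:, None, None] - inv @ W @ inv
                rsum = b.Sy - na - beta * b.Ss
                da = -2.0 * np.einsum("gij,gj->gi", inv, rsum)
                dWdb = (-(b.Sys + b.Sys.transpose(0, 2, 1))
                        + np.einsum("gi,gj->gij", a, b.Ss)
                        + np.einsum("gi,gj->gij", b.Ss, a)
                        + 2.0 * beta * b.Sss)
                gbeta += float(np.einsum("gij,gij->", inv, dWdb))
                np.add.at(gSig, (b.zyg[:, None, None], b.idx[:, :, None],
                                 b.idx[:, None, :]), dSig)
                np.add.at(gmu, (b.zyg[:, None], b.idx), da)
        if grad:
            return total, gmu, gSig, gbeta
        return total

    def neg2ll_bruteforce(self, model: MomentModel, theta) -> float:
        """Naive per-pair evaluation (the contract check for the grouped path)."""
        zyg_names = np.array(["MZ", "DZ"])
        total = 0.0
        for i in range(self.n_pairs):
            m = model.pair_moments(theta, zyg_names[self.zyg[i]],
                                   self.S[i, 0], self.S[i, self.T])
            total += pair_loglik(self.Y[i], m)
        return total

    def missing_pattern_stats(self) -> dict:
        return {"n_pairs": self.n_pairs, "n_mz": self.n_mz, "n_dz": self.n_dz,
                "n_pattern_groups": self.n_groups}


# ---------------------------------------------------------------------------
# objective and optimizer
# ---------------------------------------------------------------------------


def _pack_moments(model, theta):
    mu, Sigma, beta = model.implied(theta)
    return np.concatenate([np.ravel(mu), np.ravel(Sigma), [beta]])


def _moment_jacobian(model, theta, rel_step=1e-6):
    theta = np.asarray(theta, float)
    p = theta.size
    cols = []
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        cols.append((_pack_moments(model, tp) - _pack_moments(model, tm)) / (2 * h))
    return np.array(cols)  # (p, n_out)


#: base of the positive-definiteness barrier (far above any realistic −2LL)
_PD_PENALTY = 1e10


def make_objective(model: MomentModel, data: PairData):
    """Return f(theta) -> (−2LL, gradient) for the optimizer.

    Outside the positive-definite region (possible under variance-scale
    parameterizations such as the correlated-factors and negative-C models)
    the objective becomes a smooth eigenvalue penalty whose gradient pushes
    the implied covariance back toward the cone, so quasi-Newton line
    searches recover instead of stalling on an infinite value.
    """

    def fg(theta):
        mu, Sigma, beta = model.implied(theta)
        floor = 1e-8 * (1.0 + np.trace(Sigma[0]) / Sigma.shape[-1])
        w = np.linalg.eigvalsh(Sigma)
        if w.min() < floor:
            gSig = np.zeros_like(Sigma)
            pen = 0.0
            for z in range(2):
                wz, V = np.linalg.eigh(Sigma[z])
                viol = np.clip(floor - wz, 0.0, None)
                pen += float((viol**2).sum())
                gSig[z] = (V * (-2.0 * viol)) @ V.T
            gpack = np.concatenate([np.zeros(mu.size), 1e6 * np.ravel(gSig), [0.0]])
            J = _moment_jacobian(model, theta)
            return _PD_PENALTY + 1e6 * pen, J @ gpack
        f, gmu, gSig, gbeta = data.neg2ll(mu, Sigma, beta, grad=True)
        if not np.isfinite(f):
            return _PD_PENALTY, np.zeros_like(theta)
        gpack = np.concatenate([np.ravel(gmu), np.ravel(gSig), [gbeta]])
        J = _moment_jacobian(model, theta)
        return f, J @ gpack

    return fg


@dataclass
class FitResult:
    """Converged (or flagged) FIML solution for one model on one dataset."""

    model_name: str
    labels: list[str]
    theta: np.ndarray
    minus2ll: float
    converged: bool
    grad_norm: float
    n_pairs: int
    n_restarts_used: int = 0
    message: str = ""
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.theta)))

    @property
    def ep(self) -> int:
        return len(self.labels)

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.ep

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "minus2ll": self.minus2ll,
            "ep": self.ep,
            "aic": self.aic,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_pairs": self.n_pairs,
            "estimates": self.estimates,
            "se": {k: (None if v is None or not np.isfinite(v) else float(v))
                   for k, v in self.se.items()},
            "ci": {k: [None if x is None else float(x) for x in v]
                   for k, v in self.ci.items()},
            "message": self.message,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def fit(model: MomentModel, data: PairData, *, n_restarts: int = 2,
        jitter: float = 0.15, seed: int = 0, maxiter: int = 1000,
        start=None, gtol: float = 1e-7, ftol: float = 1e-12) -> FitResult:
    """Minimize total −2LL by quasi-Newton iterations with jittered restarts.

    Deterministic given ``seed``.  Non-convergence after all restarts yields a
    flagged (``converged=False``) result rather than an exception.
    """
    if data.n_pairs == 0:
        raise ValueError("no pairs to fit")
    fg = make_objective(model, data)
    rng = np.random.default_rng(seed)
    theta0 = np.asarray(model.start if start is None else start, float)
    if theta0.size != len(model.labels):
        raise ValueError("start vector length does not match free labels")

    # precondition: balance parameters by the sensitivity of the implied
    # moments to each (growth-factor variances under quadratic loadings are
    # orders of magnitude more leveraged than means)
    J0 = _moment_jacobian(model, theta0)
    norms = np.sqrt((J0**2).sum(axis=1))
    scale = 1.0 / np.maximum(norms, 1e-3)
    scale /= np.median(scale)

    def fgs(x):
        f, g = fg(x * scale)
        return f, g * scale

    x0 = theta0 / scale
    lu = getattr(model, "bounds", {}) or {}
    sbounds = None
    if lu:
        sbounds = []
        for j, lab in enumerate(model.labels):
            lo, hi = lu.get(lab, (-np.inf, np.inf))
            sbounds.append((lo / scale[j], hi / scale[j]))
        x0 = np.clip(x0, [b[0] for b in sbounds], [b[1] for b in sbounds])
    starts = [x0]
    for _ in range(n_restarts):
        s = x0 + rng.normal(0.0, jitter * (np.abs(x0) + 0.05))
        if sbounds is not None:
            s = np.clip(s, [b[0] for b in sbounds], [b[1] for b in sbounds])
        starts.append(s)

    opts = {"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 25}
    best = None
    used = 0
    for i, s in enumerate(starts):
        res = optimize.minimize(fgs, s, jac=True, method="L-BFGS-B",
                                bounds=sbounds, options=opts)
        if best is None or res.fun < best.fun - 1e-9:
            best, used = res, i
        if i == 0 and res.success:
            break  # first start converged; restarts are a fallback
    # polish: restart the Hessian approximation at the candidate optimum
    pre_polish = best.fun
    res = optimize.minimize(fgs, best.x, jac=True, method="L-BFGS-B",
                            bounds=sbounds, options=opts)
    if res.fun <= best.fun:
        best = res
    gnorm = float(np.max(np.abs(best.jac))) if np.size(best.jac) else 0.0
    # stationarity: a fresh quasi-Newton run from the optimum finding nothing
    # further counts as converged even when the gradient-norm test is shy
    stationary = (pre_polish - best.fun) < 1e-5 * (1.0 + abs(best.fun))
    converged = bool(np.isfinite(best.fun)) and (best.success or gnorm < 1e-2
                                                 or stationary)
    return FitResult(
        model_name=model.name, labels=list(model.labels),
        theta=np.asarray(best.x) * scale,
        minus2ll=float(best.fun), converged=converged, grad_norm=gnorm,
        n_pairs=data.n_pairs, n_restarts_used=used,
        message=str(getattr(best, "message", "")),
    )


def wald_se(model: MomentModel, data: PairData, result: FitResult,
            rel_step: float = 1e-4) -> dict[str, float]:
    """Standard errors from the inverse observed information.

    The information is the Hessian of −2LL divided by two, obtained by
    symmetrized central differences of the analytic moment-chain gradient.
    Parameters whose curvature is not positive (typical at boundary
    estimates) get NaN, flagged rather than fatal.
    """
    fg = make_objective(model, data)
    theta = np.asarray(result.theta, float)
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (fg(tp)[1] - fg(tm)[1]) / (2 * h)
    H = (H + H.T) / 2.0
    se = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        d = np.diag(cov)
        for lab, v in zip(model.labels, d):
            se[lab] = float(np.sqrt(v)) if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        se = {lab: float("nan") for lab in model.labels}
    result.se.update(se)
    return se


def profile_m2ll(model: MomentModel, data: PairData, label: str, value: float,
                 warm: np.ndarray | None = None, seed: int = 0) -> tuple[float, np.ndarray]:
    """Minimized −2LL with ``label`` fixed at ``value`` (all others re-optimized)."""
    sub = model.fixing({label: value})
    start = None
    if warm is not None:
        full = dict(zip(model.labels, warm))
        start = np.array([full[l] for l in sub.labels])
    r = fit(sub, data, n_restarts=0, seed=seed, start=start)
    full = dict(zip(sub.labels, r.theta))
    full[label] = value
    return r.minus2ll, np.array([full[l] for l in model.labels])


def profile_ci(model: MomentModel, data: PairData, result: FitResult,
               label: str, level: float = 0.95, max_expand: int = 14) -> tuple:
    """Likelihood-based confidence interval for one free parameter.

    Bounds are the parameter values where the profile −2LL rises by the
    chi-square(1) quantile of ``level`` above the minimum, searched outward
    from the estimate with warm starts.  A bound that cannot be bracketed
    (parameter-space limit) is returned as None (one-sided interval).
    """
    crit = float(stats.chi2.ppf(level, 1))
    target = result.minus2ll + crit
    est = result.estimates[label]
    se = result.se.get(label)
    step = se if se is not None and np.isfinite(se) and se > 0 else 0.5 * abs(est) + 0.1

    bounds = []
    for direction in (-1.0, 1.0):
        warm = result.theta.copy()
        x_in, f_in = est, result.minus2ll
        x_out = None
        s = step
        for _ in range(max_expand):
            x_try = x_in + direction * s
            f_try, warm = profile_m2ll(model, data, label, x_try, warm=warm)
            if f_try >= target:
                x_out, f_out = x_try, f_try
                break
            x_in, f_in = x_try, f_try
            s *= 1.8
        if x_out is None:
            bounds.append(None)
            continue
        lo, flo, hi, fhi = x_in, f_in, x_out, f_out
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            fmid, warm = profile_m2ll(model, data, label, mid, warm=warm)
            if fmid >= target:
                hi, fhi = mid, fmid
            else:
                lo, flo = mid, fmid
            if abs(hi - lo) < 1e-4 * (1.0 + abs(est)):
                break
        bounds.append(0.5 * (lo + hi))
    lower, upper = bounds
    if lower is not None and upper is not None and lower > upper:
        lower, upper = upper, lower
    result.ci[label] = (lower, upper)
    return lower, upper
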
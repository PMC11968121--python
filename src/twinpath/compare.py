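"""Model selection: likelihood-ratio tests, AIC ranking, innovation pruning.

The workflow mirrors standard biometric practice: every theoretical model is
contrasted against the correlated-factors reference by the change in −2
log-likelihood (asymptotically chi-squared with df equal to the difference in
free-parameter counts), the best-fitting family is chosen by the lowest AIC,
and non-significant shared-environment innovations are pruned post hoc.

Variance-type parameters tested at their boundary have non-standard null
distributions; rows carry a ``boundary_caveat`` flag while the naive
chi-squared p-value is reported, matching the framework being reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fiml import FitResult, PairData, fit
from .pathmodel import KINDS, MomentModel
from .zoo import build_autoregression

__all__ = ["ComparisonRow", "NotNestedError", "lrt", "aic_rank",
           "comparison_table", "prune_innovations", "PruneReport"]

CHI2_95_DF1 = float(stats.chi2.ppf(0.95, 1))  # 3.841...


class NotNestedError(ValueError):
    """The models are not nested; compare them by AIC instead."""


@dataclass
class ComparisonRow:
    """One line of a model-fitting comparison table."""

    name: str
    ep: int
    minus2ll: float
    delta_m2ll: float | None = None
    delta_df: int | None = None
    p: float | None = None
    aic: float = float("nan")
    selected: bool = False
    converged: bool = True
    boundary_caveat: bool = False

    @classmethod
    def from_fit(cls, f: FitResult, **kw):
        return cls(name=f.model_name, ep=f.ep, minus2ll=f.minus2ll,
                   aic=f.aic, converged=f.converged, **kw)

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("name", "ep", "minus2ll", "delta_m2ll", "delta_df", "p",
                 "aic", "selected", "converged", "boundary_caveat")}


def lrt(reference: FitResult, nested: FitResult, *, assume_nested: bool = False,
        tol: float = 1e-4):
    """Likelihood-ratio test of a nested model against a reference.

    Structural nesting is checked via the free-label sets unless
    ``assume_nested`` asserts it (used when a theoretical model is nested in
    the correlated-factors reference in covariance structure but not in
    labels).  Returns ``(delta_m2ll, delta_df, p)``.  A negative Δ−2LL beyond
    tolerance means the nested fit beat the reference — an optimization
    failure the caller should resolve by refitting with restarts.
    """
    if not assume_nested and not set(nested.labels) <= set(reference.labels):
        raise NotNestedError(
            f"{nested.model_name} is not label-nested in {reference.model_name}; "
            "compare by AIC")
    ddf = reference.ep - nested.ep
    if ddf < 0:
        raise NotNestedError("nested model has more free parameters than reference")
    delta = nested.minus2ll - reference.minus2ll
    if delta < -tol:
        raise ArithmeticError(
            f"Δ−2LL = {delta:.6g} < 0: reference fit is not at its optimum; "
            "refit with more restarts")
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else float("nan")
    return delta, ddf, p


def aic_rank(rows: list[ComparisonRow]) -> list[ComparisonRow]:
    """Rank by AIC; lowest wins, ties broken by fewer parameters then name.

    Non-converged rows are excluded from selection but kept in the table.
    """
    if not rows:
        raise ValueError("no models to rank")
    ranked = sorted(rows, key=lambda r: (r.aic, r.ep, r.name))
    for r in ranked:
        r.selected = False
    eligible = [r for r in ranked if r.converged]
    if eligible:
        eligible[0].selected = True
    return ranked


def comparison_table(reference: FitResult, fits: list[FitResult],
                     assume_nested: bool = True) -> pd.DataFrame:
    """Reference-vs-competitors table (Δ−2LL, Δdf, p, AIC, selection)."""
    rows = [ComparisonRow.from_fit(reference)]
    for f in fits:
        delta, ddf, p = lrt(reference, f, assume_nested=assume_nested)
        rows.append(ComparisonRow.from_fit(f, delta_m2ll=delta, delta_df=ddf, p=p))
    ranked = aic_rank(rows)
    return pd.DataFrame([r.to_dict() for r in ranked])


# ---------------------------------------------------------------------------
# post-hoc pruning of innovations
# ---------------------------------------------------------------------------


@dataclass
class PruneReport:
    """Outcome of the shared-environment innovation pruning workflow."""

    kind: str
    tested: dict = field(default_factory=dict)      # label -> (delta_m2ll, spans_zero)
    pruned_occasions: list = field(default_factory=list)
    pruned_model: MomentModel | None = None
    pruned_fit: FitResult | None = None
    aic_improvement: float = 0.0
    warning: str | None = None

    def to_dict(self):
        return {
            "kind": self.kind,
            "tested": {k: {"delta_m2ll": float(v[0]), "spans_zero": bool(v[1])}
                       for k, v in self.tested.items()},
            "pruned_occasions": self.pruned_occasions,
            "aic_improvement": float(self.aic_improvement),
            "pruned_minus2ll": None if self.pruned_fit is None
            else self.pruned_fit.minus2ll,
            "pruned_ep": None if self.pruned_fit is None else self.pruned_fit.ep,
            "warning": self.warning,
        }


def _innovation_spans_zero(model, data, fitted, label, level, seed):
    """Profile-CI-spans-zero decision for an innovation path coefficient.

    The 95% profile interval of a path coefficient contains zero exactly when
    fixing the path to zero raises the minimized −2LL by less than the
    chi-squared(1) critical value, so the decision is made by one warm-started
    constrained refit rather than a two-sided bound search.
    """
    sub = model.fixing({label: 0.0})
    warm = np.array([fitted.estimates[l] for l in sub.labels])
    r0 = fit(sub, data, n_restarts=1, seed=seed, start=warm, maxiter=800,
             ftol=1e-11)
    delta = r0.minus2ll - fitted.minus2ll
    crit = float(stats.chi2.ppf(level, 1))
    return delta, delta < crit


def prune_innovations(model, fitted: FitResult, data: PairData, *,
                      kind: str = "C", earliest_kept: int = 2,
                      level: float = 0.95, seed: int = 0) -> PruneReport:
    """Drop a kind's non-significant innovations beyond the earliest kept occasion.

    Tests every free innovation of ``kind`` at occasions beyond
    ``earliest_kept``; those whose 95% interval spans zero are fixed to zero.
    When the surviving occasions form a leading block, the model is rebuilt
    structurally (the trailing transmission coefficients are removed too, as
    in the post-hoc workflow); otherwise the innovations alone are fixed.
    The pruned model is refitted and the AIC improvement reported; a pruned
    fit worse than chance allows warns and keeps both fits.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    T = model.T
    kl = kind.lower()
    report = PruneReport(kind=kind)
    free = set(model.labels)
    candidates = [(t, f"{kl}_innov_{t}") for t in range(earliest_kept + 1, T + 1)
                  if f"{kl}_innov_{t}" in free]
    for t, lab in candidates:
        delta, spans = _innovation_spans_zero(model, data, fitted, lab, level, seed)
        report.tested[lab] = (delta, spans)
        if spans:
            report.pruned_occasions.append(t)
    if not report.pruned_occasions:
        report.pruned_model = model
        report.pruned_fit = fitted
        return report

    last_kept = max(t for t in range(1, T + 1) if t not in report.pruned_occasions)
    trailing = set(report.pruned_occasions) == set(range(last_kept + 1, T + 1))
    if trailing and hasattr(model, "components"):
        kinds = tuple(k for k in KINDS
                      if any(l.startswith(f"{k.lower()}_innov") for l in model.labels))
        pruned = build_autoregression(T=T, kinds=kinds, prune={kind: last_kept})
        warm = {l: fitted.estimates[l] for l in pruned.labels
                if l in fitted.estimates}
        pruned.set_start(warm)
    else:
        pruned = model.fixing({f"{kl}_innov_{t}": 0.0
                               for t in report.pruned_occasions})
    rfit = fit(pruned, data, n_restarts=2, seed=seed, maxiter=1500, ftol=1e-11)
    report.pruned_model = pruned
    report.pruned_fit = rfit
    report.aic_improvement = fitted.aic - rfit.aic
    worsening = rfit.minus2ll - fitted.minus2ll
    allowance = float(stats.chi2.ppf(level, max(fitted.ep - rfit.ep, 1)))
    if worsening > allowance:
        report.warning = (
            f"pruned model fits worse by Δ−2LL={worsening:.3f} > {allowance:.3f}; "
            "keeping both fits")
    return report
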
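"""Synthetic twin-pair data with the statistical structure the models assume.

The generator is the stand-in for the restricted-access cohort: it draws twin
pairs from any bound :class:`~twinpath.pathmodel.PathModel` (additive-genetic
components correlated 1.0 within MZ and 0.5 within DZ pairs, shared
environment fully shared, non-shared environment independent), applies a sex
effect on the means, and masks occasions with the cohort-style missingness
profile (most subjects observed at 1-2 of the six 4-year age intervals, none
at more than four).

Two canonical truth configurations are provided.  ``default_truth`` mirrors
the structure reported for distress scores: a persistent genetic simplex with
innovations at every occasion, shared-environment innovations at the first two
occasions only, weakly persistent non-shared environment, and a dominant
transient residual.  ``interior_truth`` keeps every innovation away from zero;
parameter-recovery and likelihood-calibration checks use it so that boundary
effects do not confound the diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ITEM_COLUMNS, PanelConfig, bin_midpoint
from .fiml import pair_columns
from .pathmodel import KIND_CROSS_CORR, KINDS, PathModel
from .zoo import build_autoregression

__all__ = [
    "SimulationConfig",
    "MissingnessProfile",
    "default_truth",
    "interior_truth",
    "simulate_pairs",
    "simulate_panel",
    "apply_missingness",
    "emit_ordinal_items",
]

#: subjects observed at exactly 1, 2, 3 and 4 age intervals in the cohort the
#: generator emulates
COHORT_INTERVAL_COUNTS = (1639, 972, 931, 229)


@dataclass
class MissingnessProfile:
    """Distribution of the number of intervals a subject is observed at.

    ``probs[k-1]`` is the probability of exactly k observed intervals
    (contiguous window with a uniformly drawn start).  The default reproduces
    the cohort's 1/2/3/4-interval subject counts; no subject is observed at
    every interval and none is removed entirely.
    """

    probs: tuple = tuple(np.array(COHORT_INTERVAL_COUNTS, float)
                         / sum(COHORT_INTERVAL_COUNTS))

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("missingness profile must be a probability vector")

    def draw_mask(self, rng: np.random.Generator, n_subjects: int, T: int):
        """(n_subjects, T) boolean observation mask."""
        k_max = len(self.probs)
        if k_max > T:
            raise ValueError(f"profile allows up to {k_max} intervals but T={T}")
        ks = rng.choice(np.arange(1, k_max + 1), size=n_subjects, p=self.probs)
        starts = rng.integers(0, T - ks + 1)
        t = np.arange(T)
        return (t >= starts[:, None]) & (t < (starts + ks)[:, None])


def default_truth(T: int = 6):
    """Study-structure generating model: ACE simplex with shared-environment
    innovations at the first two occasions only.

    The structure is the full equated-transmission simplex with the later C
    innovation paths at zero, so the generating model is nested in the fitted
    ACE autoregression (the standard design for a pruning study); after
    occasion 2 the only shared-environment variance is the small residue the
    transmission chain carries forward.
    """
    model = build_autoregression(T=T)
    truth = {
        # the C transmission is weak: shared-environment influence is
        # confined to adolescence and barely carried forward
        "beta_a": 0.75, "beta_c": 0.30, "beta_e": 0.40,
        "res": 0.50, "beta_sex": -0.14,
    }
    a_innov = (0.45, 0.28, 0.25, 0.22, 0.20, 0.25)
    c_innov = (0.30, 0.15, 0.0, 0.0, 0.0, 0.0)
    mu = (1.50, 1.45, 1.40, 1.35, 1.30, 1.30)
    for t in range(T):
        truth[f"a_innov_{t + 1}"] = a_innov[t % len(a_innov)]
        truth[f"c_innov_{t + 1}"] = c_innov[t] if t < 6 else 0.0
        truth[f"e_innov_{t + 1}"] = 0.20
        truth[f"mu_{t + 1}"] = mu[t % len(mu)]
    model.set_start(truth)
    return model, truth


def interior_truth(T: int = 6):
    """Full ACE simplex with every parameter well inside the identified region.

    Recovery and likelihood-calibration studies need each process to leave a
    clear signature in the moments (an E process whose innovations nearly
    vanish trades off against the transient residual along a likelihood ridge
    and no estimator can recover the split at realistic n), so every
    innovation and transmission here is bounded away from zero.
    """
    model = build_autoregression(T=T)
    truth = {
        "beta_a": 0.70, "beta_c": 0.50, "beta_e": 0.50,
        "res": 0.45, "beta_sex": -0.14,
    }
    a_innov = (0.45, 0.30, 0.28, 0.25, 0.25, 0.28)
    c_innov = (0.32, 0.25, 0.22, 0.22, 0.20, 0.20)
    mu = (1.50, 1.45, 1.40, 1.35, 1.30, 1.30)
    for t in range(T):
        truth[f"a_innov_{t + 1}"] = a_innov[t % len(a_innov)]
        truth[f"c_innov_{t + 1}"] = c_innov[t % len(c_innov)]
        truth[f"e_innov_{t + 1}"] = 0.35
        truth[f"mu_{t + 1}"] = mu[t % len(mu)]
    model.set_start(truth)
    return model, truth


def demo_truth(family: str, T: int = 6):
    """Canonical generating configuration for one model family.

    Plausible parameter values on the transformed-score scale (total
    phenotypic variance around 0.5-0.7, heritability around a third), used by
    the generative/analytic agreement checks and demonstrations.  Returns
    ``(model, truth)``.
    """
    from . import zoo

    mu = {f"mu_{t + 1}": v for t, v in
          enumerate((1.50, 1.45, 1.40, 1.35, 1.30, 1.30)[:T])}

    def ar_corr(rho):
        t = np.arange(T)
        return rho ** np.abs(t[:, None] - t[None, :])

    if family == "univariate_ace":
        model = zoo.build_univariate_ace()
        truth = {"a_var": 0.5, "c_var": 0.2, "e_var": 0.3, "mu_1": 1.5,
                 "beta_sex": -0.14}
    elif family == "correlated_factors":
        model = zoo.build_correlated_factors(T)
        truth = dict(mu, beta_sex=-0.14)
        for kl, scale, rho in (("a", 0.25, 0.7), ("c", 0.10, 0.9), ("e", 0.30, 0.4)):
            S = scale * ar_corr(rho)
            for i in range(T):
                for j in range(i + 1):
                    truth[f"{kl}_cov_{i + 1}_{j + 1}"] = float(S[i, j])
    elif family == "autoregression":
        return interior_truth(T)
    elif family == "latent_growth":
        model = zoo.build_latent_growth(T, degree=2)
        truth = {"beta_sex": -0.14, "mean_int": 1.5, "mean_lin": -0.05,
                 "mean_quad": 0.003}
        phi = {"int_int": 0.10, "lin_int": 0.008, "lin_lin": 0.006,
               "quad_int": 0.0, "quad_lin": 0.0, "quad_quad": 0.0004}
        for kl, f in (("a", 1.0), ("c", 0.4), ("e", 0.7)):
            for cell, v in phi.items():
                truth[f"{kl}_{cell}"] = f * v
            for t in range(T):
                truth[f"{kl}_res_{t + 1}"] = 0.30
    elif family == "dual_change":
        model = zoo.build_dual_change(T)
        truth = {"beta_sex": -0.14, "mean_level": 1.5, "mean_slope": -0.04}
        for kl, f, prop in (("a", 1.0, -0.06), ("c", 0.35, -0.02), ("e", 0.6, -0.10)):
            truth.update({f"{kl}_lvl_lvl": 0.12 * f, f"{kl}_lvl_slp": 0.008 * f,
                          f"{kl}_slp_slp": 0.006 * f, f"{kl}_prop": prop})
            for t in range(T):
                truth[f"{kl}_res_{t + 1}"] = 0.30
    elif family in ("common_pathway_1", "common_pathway_2"):
        k = int(family[-1])
        model = zoo.build_common_pathway(T, k)
        truth = dict(mu, beta_sex=-0.14)
        lam = {1: (1.0, 0.9, 0.8, 0.75, 0.7, 0.7),
               2: (0.0, 1.0, 0.6, 0.55, 0.5, 0.45)}
        for f in range(1, k + 1):
            for t in range(f, T):
                truth[f"cp{f}_load_{t + 1}"] = lam[f][t]
            truth[f"cp{f}_a"] = 0.35
            truth[f"cp{f}_c"] = 0.20
            truth[f"cp{f}_e"] = 0.30
        for kl in ("a", "c", "e"):
            for t in range(T):
                truth[f"{kl}_res_{t + 1}"] = {"a": 0.30, "c": 0.15, "e": 0.40}[kl]
    elif family == "independent_pathway":
        model = zoo.build_independent_pathway(T)
        truth = dict(mu, beta_sex=-0.14)
        for kl, common in (("a", 0.40), ("c", 0.20), ("e", 0.30)):
            for t in range(T):
                truth[f"{kl}_common_{t + 1}"] = common * (1.0 - 0.05 * t)
                truth[f"{kl}_res_{t + 1}"] = {"a": 0.25, "c": 0.12, "e": 0.40}[kl]
    else:
        raise KeyError(f"unknown family {family!r}")
    truth = {l: truth[l] for l in model.labels}
    model.set_start(truth)
    return model, truth


MOMENT_ORACLE_FAMILIES = (
    "univariate_ace", "correlated_factors", "autoregression", "latent_growth",
    "dual_change", "common_pathway_1", "common_pathway_2", "independent_pathway",
)


@dataclass
class SimulationConfig:
    """Generating model, sample composition and missingness for one dataset."""

    model: PathModel
    truth: dict
    n_mz: int = 1000
    n_dz: int = 1000
    p_male: float = 0.5
    missingness: MissingnessProfile | None = field(default_factory=MissingnessProfile)
    seed: int = 0

    def __post_init__(self):
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any persisted dataset")

    def replace(self, **kw):
        return replace(self, **kw)


def draw_pair_scores(model: PathModel, vals: dict, rng: np.random.Generator,
                     n: int, zygosity: str):
    """(y1, y2) transformed-scale scores for ``n`` pairs, before the sex shift."""
    T = model.T
    z = 0 if zygosity == "MZ" else 1
    y1 = np.zeros((n, T))
    y2 = np.zeros((n, T))
    for kind in KINDS:
        r = KIND_CROSS_CORR[kind][z]
        for comp in model.components[kind]:
            c1, c2 = comp.draw(vals, rng, n, T, r)
            y1 += c1
            y2 += c2
    sd = np.sqrt(model.residual_var(vals))
    y1 += rng.standard_normal((n, T)) * sd
    y2 += rng.standard_normal((n, T)) * sd
    m = model.mean.mean(vals)
    return y1 + m, y2 + m


def apply_missingness(pairs: pd.DataFrame, profile: MissingnessProfile,
                      seed: int, T: int):
    """Mask each twin's occasions by the profile; returns (masked, audit).

    Each subject keeps at least one interval, so no pair is emptied.
    """
    rng = np.random.default_rng(seed)
    out = pairs.copy()
    n = len(out)
    audit_counts = np.zeros(T + 1, int)
    for j in (1, 2):
        mask = profile.draw_mask(rng, n, T)
        cols = [f"y{j}_t{t}" for t in range(T)]
        vals = out[cols].to_numpy(float)
        vals[~mask] = np.nan
        out[cols] = vals
        ks, cnt = np.unique(mask.sum(axis=1), return_counts=True)
        audit_counts[ks] += cnt
    audit = {"subjects_at_k_intervals": {int(k): int(audit_counts[k])
                                         for k in range(1, T + 1) if audit_counts[k]}}
    return out, audit


def simulate_pairs(config: SimulationConfig):
    """Generate a wide twin-pair table (and audit) from the configuration.

    Columns match the FIML input contract: family_id, zygosity, sex_1, sex_2,
    ``y1_t0..``, ``y2_t0..``; scores are on the transformed (analysis) scale.
    Deterministic: the same config and seed give a byte-identical table.
    """
    model, truth = config.model, config.truth
    missing = set(model.labels) - set(truth)
    if missing:
        raise ValueError(f"truth does not bind labels: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    T = model.T
    beta = truth.get("beta_sex", 0.0) if "beta_sex" in model.labels else (
        model.beta_sex if isinstance(model.beta_sex, float) else 0.0)

    frames = []
    fam0 = 0
    for zygosity, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        if n == 0:
            continue
        y1, y2 = draw_pair_scores(model, truth, rng, n, zygosity)
        if zygosity == "MZ":
            sex1 = rng.binomial(1, config.p_male, n).astype(float)
            sex2 = sex1.copy()
        else:
            sex1 = rng.binomial(1, config.p_male, n).astype(float)
            sex2 = rng.binomial(1, config.p_male, n).astype(float)
        y1 = y1 + beta * sex1[:, None]
        y2 = y2 + beta * sex2[:, None]
        df = pd.DataFrame(np.hstack([y1, y2]), columns=pair_columns(T))
        df.insert(0, "sex_2", sex2)
        df.insert(0, "sex_1", sex1)
        df.insert(0, "zygosity", zygosity)
        df.insert(0, "family_id", [f"F{fam0 + i:06d}" for i in range(n)])
        fam0 += n
        frames.append(df)
    pairs = pd.concat(frames, ignore_index=True)
    audit = {"n_mz": config.n_mz, "n_dz": config.n_dz, "seed": config.seed}
    if config.missingness is not None and T > 1:
        pairs, miss_audit = apply_missingness(
            pairs, config.missingness, seed=int(rng.integers(2**31)), T=T)
        audit.update(miss_audit)
    return pairs, audit


# ---------------------------------------------------------------------------
# ordinal item emission
# ---------------------------------------------------------------------------

#: default item thresholds on the item-latent scale, chosen so roughly 70% of
#: responses fall in category 0 (right-skewed sums, as self-report distress
#: screeners show)
DEFAULT_THRESHOLDS = (0.9, 2.0)
ITEM_NOISE_SD = 0.8


def emit_ordinal_items(latent: np.ndarray, thresholds=DEFAULT_THRESHOLDS,
                       rng: np.random.Generator | None = None,
                       n_items: int = 6, noise_sd: float = ITEM_NOISE_SD):
    """Map standardized latent scores to ordinal item responses.

    Each item's latent value is the common score plus independent noise; the
    response is the count of thresholds exceeded.  ``latent`` has shape (n,);
    the result is (n, n_items) with values in {0, 1, 2}.
    """
    lo, hi = thresholds
    if not hi > lo:
        raise ValueError("thresholds must be strictly increasing")
    rng = rng or np.random.default_rng(0)
    x = latent[:, None] + rng.standard_normal((latent.size, n_items)) * noise_sd
    return (x > lo).astype(int) + (x > hi).astype(int)


def simulate_panel(config: SimulationConfig, *, ordinal: bool = True,
                   domain: str = "psychological", age_jitter_sd: float = 1.0,
                   panel_config: PanelConfig | None = None):
    """Long-format subject-by-wave panel for the data-preparation pipeline.

    Draws pair scores, masks occasions, and emits one row per observed
    subject-occasion with an age near the interval midpoint.  With
    ``ordinal=True`` the latent score is re-expressed as 12 three-point items
    (the named domain carries the signal; the other six items are independent
    noise); otherwise a ``score_transformed`` column carries the continuous
    score for exact pipeline closure.
    """
    panel_config = panel_config or PanelConfig()
    pairs, _ = simulate_pairs(config)
    T = config.model.T
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for _, rec in pairs.iterrows():
        for j in (1, 2):
            scores = np.array([rec[f"y{j}_t{t}"] for t in range(T)])
            for t in np.where(~np.isnan(scores))[0]:
                age = bin_midpoint(int(t), panel_config) + np.clip(
                    rng.normal(0, age_jitter_sd), -1.9, 1.9)
                rows.append({
                    "subject_id": f"{rec['family_id']}_{j}",
                    "family_id": rec["family_id"], "twin_order": j,
                    "zygosity": rec["zygosity"], "sex": rec[f"sex_{j}"],
                    "age": round(float(age), 2), "score": scores[t],
                })
    panel = pd.DataFrame(rows)
    if not ordinal:
        panel = panel.rename(columns={"score": "score_transformed"})
        return panel

    z = (panel["score"] - panel["score"].mean()) / panel["score"].std()
    items = emit_ordinal_items(z.to_numpy(), rng=rng)
    other = emit_ordinal_items(rng.standard_normal(len(panel)), rng=rng)
    signal_first = panel_config.domain_items[domain][0] == 0
    blocks = (items, other) if signal_first else (other, items)
    item_df = pd.DataFrame(np.hstack(blocks), columns=ITEM_COLUMNS,
                           index=panel.index)
    return pd.concat([panel.drop(columns="score"), item_df], axis=1)
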
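"""Scoring and reshaping of SPHERE-style twin questionnaire data.

The pipeline mirrors how a longitudinal twin cohort's wave-based self-report
data are prepared for biometric modelling:

1. twelve 3-point ordinal items (0/1/2) are summed into two 6-item domain
   scores (psychological and somatic distress, each 0-12);
2. each assessment is recoded from its wave to a 4-year age interval
   (12-15, 16-19, ..., 32-35 by default; ages of 36 and over are excluded);
3. domain scores are square-root transformed;
4. subjects are reshaped into twin-pair records (one row per family, both
   twins' scores at every interval, NaN marking missing), the unit the FIML
   engine consumes.  Singleton twins are retained with an all-missing co-twin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiml import pair_columns

__all__ = [
    "InvalidDataError",
    "InvalidStructureError",
    "PanelConfig",
    "score_domain",
    "assign_age_interval",
    "transform_score",
    "score_panel",
    "build_pairs",
    "read_long_csv",
    "write_pairs_csv",
    "read_pairs_csv",
]


class InvalidDataError(ValueError):
    """A value violates the instrument's coding (item outside {0,1,2}, negative age...)."""


class InvalidStructureError(ValueError):
    """Family structure violates the twin design (3+ subjects, zygosity conflict)."""


ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, 13)]


@dataclass
class PanelConfig:
    """How waves are scored and binned into age intervals.

    ``T`` 4-year bins starting at ``age_start``; ages below ``age_start`` are
    excluded unless within ``lower_tol`` years of it; ages at or above the last
    bin's upper edge are excluded (the sparse oldest interval is dropped from
    analysis).  ``domain_items`` maps each domain to its 6 item indices
    (0-based within the 12-item battery).
    """

    T: int = 6
    age_start: float = 12.0
    bin_width: float = 4.0
    lower_tol: float = 0.0
    domain_items: dict = field(default_factory=lambda: {
        "psychological": tuple(range(0, 6)),
        "somatic": tuple(range(6, 12)),
    })


def score_domain(responses, domain: str, config: PanelConfig | None = None) -> float:
    """Sum a domain's six item scores; missing if any constituent item is missing.

    ``responses``: the 12 ordinal item values (NaN/None = missing).  Raises
    :class:`InvalidDataError` for responses outside {0, 1, 2}.
    """
    config = config or PanelConfig()
    if domain not in config.domain_items:
        raise KeyError(f"unknown domain {domain!r}")
    vals = [np.nan if r is None else float(r) for r in responses]
    if len(vals) != 12:
        raise InvalidDataError(f"expected 12 item responses, got {len(vals)}")
    total = 0.0
    for i in config.domain_items[domain]:
        v = vals[i]
        if np.isnan(v):
            return float("nan")
        if v not in (0.0, 1.0, 2.0):
            raise InvalidDataError(f"item_{i + 1:02d} response {v!r} not in {{0,1,2}}")
        total += v
    return total


def assign_age_interval(age: float, config: PanelConfig | None = None):
    """Age in years -> half-open 4-year bin index, or None if excluded.

    Bins are [12,16), [16,20), ..., [32,36); every real age maps uniquely.
    Ages in the excluded oldest range (36+) and ages more than ``lower_tol``
    below 12 return None.
    """
    config = config or PanelConfig()
    age = float(age)
    if age < 0:
        raise InvalidDataError(f"negative age {age}")
    if np.isnan(age):
        return None
    if age < config.age_start:
        return 0 if age >= config.age_start - config.lower_tol else None
    idx = int((age - config.age_start) // config.bin_width)
    return idx if idx < config.T else None


def transform_score(raw: float) -> float:
    """Square-root transform of a raw domain score; missing propagates."""
    raw = float(raw)
    if np.isnan(raw):
        return raw
    if raw < 0:
        raise InvalidDataError(f"negative domain score {raw}")
    return float(np.sqrt(raw))


def bin_midpoint(index: int, config: PanelConfig | None = None) -> float:
    config = config or PanelConfig()
    return config.age_start + config.bin_width * (index + 0.5)


# ---------------------------------------------------------------------------
# panel scoring
# ---------------------------------------------------------------------------

_SUBJECT_COLS = ["subject_id", "family_id", "twin_order", "zygosity", "sex"]


def read_long_csv(path) -> pd.DataFrame:
    """One row per subject per wave; items or precomputed scores; NA = missing."""
    df = pd.read_csv(path)
    need = [c for c in ("family_id", "twin_order", "zygosity", "sex", "age")
            if c not in df.columns]
    if need:
        raise InvalidDataError(f"long-format file lacks columns {need}")
    if "subject_id" not in df.columns:
        df = df.copy()
        df["subject_id"] = (df["family_id"].astype(str) + "_"
                            + df["twin_order"].astype(int).astype(str))
    return df


def score_panel(long_df: pd.DataFrame, domain: str,
                config: PanelConfig | None = None):
    """Long wave-based rows -> per-(subject, age interval) transformed scores.

    Accepts either the 12 item columns or a precomputed score column
    (``{psych|somatic}_score`` on the raw 0-12 scale, or
    ``score_transformed`` already on the analysis scale).  When two waves of
    one subject land in the same interval, the assessment closest to the bin
    midpoint is kept and the discard logged in the audit.

    Returns ``(panel, audit)``; panel columns: the subject descriptors,
    ``interval`` and ``score`` (transformed scale).
    """
    config = config or PanelConfig()
    df = long_df.reset_index(drop=True)
    score_col = {"psychological": "psych_score", "somatic": "somatic_score"}[domain]
    audit = {"excluded_age": 0, "missing_score": 0, "collisions": [], "n_rows": len(df)}

    rows = []
    for i, row in df.iterrows():
        try:
            interval = assign_age_interval(row["age"], config)
        except InvalidDataError as exc:
            raise InvalidDataError(f"subject {row['subject_id']}: {exc}") from exc
        if interval is None:
            audit["excluded_age"] += 1
            continue
        if "score_transformed" in df.columns:
            score = float(row["score_transformed"])
        else:
            if score_col in df.columns:
                raw = float(row[score_col])
            else:
                try:
                    raw = score_domain([row[c] for c in ITEM_COLUMNS], domain, config)
                except InvalidDataError as exc:
                    raise InvalidDataError(
                        f"subject {row['subject_id']}: {exc}") from exc
            score = transform_score(raw)
        if np.isnan(score):
            audit["missing_score"] += 1
            continue
        rows.append({**{c: row[c] for c in _SUBJECT_COLS},
                     "age": float(row["age"]), "interval": int(interval),
                     "score": score})
    panel = pd.DataFrame(rows, columns=_SUBJECT_COLS + ["age", "interval", "score"])

    # interval collisions: keep the assessment closest to the bin midpoint
    if len(panel):
        panel["_dist"] = (panel["age"]
                          - panel["interval"].map(lambda t: bin_midpoint(t, config))).abs()
        panel = panel.sort_values(["subject_id", "interval", "_dist"],
                                  kind="mergesort")
        dup = panel.duplicated(["subject_id", "interval"], keep="first")
        for _, r in panel[dup].iterrows():
            audit["collisions"].append(
                {"subject_id": str(r["subject_id"]), "interval": int(r["interval"]),
                 "discarded_age": float(r["age"])})
        panel = panel[~dup].drop(columns="_dist").reset_index(drop=True)
    return panel, audit


def build_pairs(panel: pd.DataFrame, T: int = 6):
    """Per-(subject, interval) panel -> one twin-pair record per family + audit.

    Singleton twins are retained with the co-twin fully missing (FIML uses
    them).  Raises :class:`InvalidStructureError` for families with more than
    two subjects or conflicting zygosity.
    """
    audit = {"intervals_observed_hist": {}, "pairs": {}, "excluded_subjects": []}
    hist = panel.groupby("subject_id")["interval"].nunique().value_counts()
    audit["intervals_observed_hist"] = {int(k): int(v) for k, v in hist.items()}

    records = []
    for fam, g in panel.groupby("family_id", sort=True):
        zygs = set(g["zygosity"].astype(str).str.upper())
        if len(zygs) > 1:
            raise InvalidStructureError(f"family {fam}: conflicting zygosity {zygs}")
        orders = sorted(set(g["twin_order"].astype(int)))
        if len(orders) > 2 or any(o not in (1, 2) for o in orders):
            raise InvalidStructureError(
                f"family {fam}: twin_order values {orders} (need subset of {{1,2}})")
        rec = {"family_id": fam, "zygosity": zygs.pop(),
               "sex_1": np.nan, "sex_2": np.nan}
        for c in pair_columns(T):
            rec[c] = np.nan
        for j in (1, 2):
            gj = g[g["twin_order"].astype(int) == j]
            if not len(gj):
                continue
            rec[f"sex_{j}"] = float(gj["sex"].iloc[0])
            for _, r in gj.iterrows():
                if r["interval"] >= T:
                    raise InvalidStructureError(
                        f"interval {r['interval']} outside configured T={T}")
                rec[f"y{j}_t{int(r['interval'])}"] = float(r["score"])
        records.append(rec)
    pairs = pd.DataFrame(records,
                         columns=["family_id", "zygosity", "sex_1", "sex_2"]
                         + pair_columns(T))

    y1 = pairs[[f"y1_t{t}" for t in range(T)]].notna().any(axis=1)
    y2 = pairs[[f"y2_t{t}" for t in range(T)]].notna().any(axis=1)
    for z in ("MZ", "DZ"):
        m = pairs["zygosity"] == z
        audit["pairs"][z] = {"complete": int((m & y1 & y2).sum()),
                             "incomplete": int((m & ~(y1 & y2)).sum())}
    audit["n_families"] = len(pairs)
    audit["n_subjects"] = int(panel["subject_id"].nunique())
    return pairs, audit


def write_pairs_csv(pairs: pd.DataFrame, path, audit: dict | None = None,
                    audit_path=None) -> None:
    pairs.to_csv(path, index=False, float_format="%.10g")
    if audit is not None and audit_path is not None:
        with open(audit_path, "w") as fh:
            json.dump(audit, fh, indent=1, sort_keys=True)


def read_pairs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "zygosity" not in df.columns:
        raise InvalidDataError("pair file lacks a zygosity column")
    for c in df.columns:
        if c.startswith(("y1_t", "y2_t", "sex_")):
            df[c] = df[c].astype(float)
    return df
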
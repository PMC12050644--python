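"""Clinical endpoint statistics for the contralateral design.

Observer dryness scores (0-4 in 0.5 steps) and skin conductance are
compared with the paired Wilcoxon signed-rank test — between arms at each
day and within arm against day 0 — with Benjamini-Hochberg adjustment
within each endpoint's comparison family. Immunofluorescence intensities
from the biopsy substudy (n as small as 3) use the classical paired
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import wilcoxon_signed_rank
from .quantify import ARMS, ValidationError

logger = logging.getLogger("scproteome")

ENDPOINTS = ("observer_score", "conductance", "if_intensity")
CLINICAL_COLUMNS = ("subject_id", "arm", "day", "endpoint", "value")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Schema and invariant checks for a clinical endpoint table."""
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    out = table.copy()
    out["day"] = pd.to_numeric(out["day"], errors="raise").astype(int)
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    if (out["day"] < 0).any():
        raise ValidationError("day must be >= 0")
    bad_arm = ~out["arm"].isin(ARMS)
    if bad_arm.any():
        raise ValidationError(
            f"unknown arm {out.loc[bad_arm, 'arm'].iloc[0]!r}")
    dup = out.duplicated(subset=["subject_id", "arm", "day", "endpoint"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValidationError(
            "duplicate clinical record for subject "
            f"{row['subject_id']!r}, arm {row['arm']!r}, day {row['day']}, "
            f"endpoint {row['endpoint']!r}")
    scores = out.loc[out["endpoint"] == "observer_score", "value"].dropna()
    ok = (scores >= 0) & (scores <= 4) & ((scores * 2) % 1 == 0)
    if not ok.all():
        raise ValidationError(
            f"observer_score must be in [0, 4] in 0.5 steps; got "
            f"{scores[~ok].iloc[0]}")
    return out


def endpoint_changes(table: pd.DataFrame, endpoint: str,
                     reference_day: int = 0) -> pd.DataFrame:
    """Per subject x arm change from the reference day at every later day.

    Subjects missing the reference-day record in an arm are excluded from
    that arm with a warning.
    """
    sub = table[table["endpoint"] == endpoint]
    wide = sub.pivot_table(index=["subject_id", "arm"], columns="day",
                           values="value")
    if reference_day not in wide.columns:
        raise ValidationError(
            f"reference day {reference_day} absent for endpoint {endpoint!r}")
    has_ref = wide[reference_day].notna()
    excluded = wide.index[~has_ref].tolist()
    if excluded:
        logger.warning("endpoint_changes(%s): excluding subject/arm pairs "
                       "missing day %d: %s", endpoint, reference_day, excluded)
    wide = wide[has_ref]
    changes = wide.drop(columns=[reference_day]).subtract(
        wide[reference_day], axis=0)
    long = changes.reset_index().melt(id_vars=["subject_id", "arm"],
                                      var_name="day", value_name="change")
    return long.dropna(subset=["change"]).reset_index(drop=True)


def paired_endpoint_tests(table: pd.DataFrame, endpoint: str,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Between-arm and within-arm paired Wilcoxon tests for one endpoint.

    Comparisons: (a) lotion_ff vs lotion at each observed day; (b) within
    each arm, change at each later day vs day 0. All comparisons of the
    endpoint form one Benjamini-Hochberg family; significance is adjusted
    p < alpha. Comparisons with fewer than 2 complete pairs are flagged
    untestable (p missing, not adjusted).
    """
    sub = table[table["endpoint"] == endpoint]
    if sub.empty:
        raise ValidationError(f"no records for endpoint {endpoint!r}")
    wide = sub.pivot_table(index="subject_id", columns=["arm", "day"],
                           values="value")
    rows = []
    days = sorted(sub["day"].unique())
    for day in days:
        cols = [(arm, day) for arm in ARMS]
        if not all(c in wide.columns for c in cols):
            continue
        pair = wide[cols].dropna()
        diffs = (pair[("lotion_ff", day)] - pair[("lotion", day)]).to_numpy()
        rows.append(("between_arm", day, diffs))
    ref = days[0] if days else 0
    for arm in ARMS:
        for day in days:
            if day == ref:
                continue
            cols = [(arm, ref), (arm, day)]
            if not all(c in wide.columns for c in cols):
                continue
            pair = wide[cols].dropna()
            diffs = (pair[(arm, day)] - pair[(arm, ref)]).to_numpy()
            rows.append((f"within_{arm}", day, diffs))

    records = []
    for comparison, day, diffs in rows:
        n = diffs.size
        if n < 2:
            records.append((endpoint, comparison, day, n, np.nan, True))
            continue
        res = wilcoxon_signed_rank(diffs)
        records.append((endpoint, comparison, day, n, res.p_value,
                        res.degenerate))
    out = pd.DataFrame(records, columns=["endpoint", "comparison", "day",
                                         "n", "p_value", "degenerate"])
    out["p_adj"] = np.nan
    testable = out["p_value"].notna()
    if testable.any():
        out.loc[testable, "p_adj"] = multipletests(
            out.loc[testable, "p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test result."""

    statistic: float
    p_value: float
    df: int
    degenerate: bool = False


def paired_ttest(values_a, values_b) -> TTestResult:
    """Classical paired t-test (two-sided), robust to tiny n.

    Zero-variance differences are flagged degenerate rather than yielding a
    spurious p: identical vectors give t = 0, p = 1; a constant nonzero
    difference leaves p undefined (NaN).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired_ttest needs two equal-length vectors")
    if a.size < 2:
        raise ValidationError("paired_ttest needs n >= 2 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return TTestResult(statistic=0.0, p_value=1.0, df=a.size - 1,
                               degenerate=True)
        return TTestResult(statistic=np.nan, p_value=np.nan, df=a.size - 1,
                           degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(res.statistic),
                       p_value=float(res.pvalue), df=a.size - 1)
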
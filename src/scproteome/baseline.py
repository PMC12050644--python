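"""Baseline between-arm concordance filter.

In a contralateral two-arm design, both legs of each subject should present
the same stratum corneum proteome before treatment. Proteins whose arm-mean
PAI differs substantially between arms at baseline (e.g. blood or
inflammation markers picked up on one leg only) are not interpretable for
treatment contrasts and are removed before differential analysis.

The retention rule is count-based: with retention fraction f (default 0.95),
the floor(f * P) proteins with the smallest absolute baseline difference are
kept and the remainder excluded, reported with their fold magnitude
10^|diff|. A percentile-threshold variant is available behind
``method="percentile"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ValidationError

logger = logging.getLogger("scproteome")


def baseline_differences(pai: pd.DataFrame, design: pd.DataFrame,
                         min_subjects: int = 2) -> pd.DataFrame:
    """Arm-mean baseline PAI differences per protein.

    diff_pai = mean over subjects of PAI in the lotion_ff arm at baseline
    minus the same mean in the lotion arm, using all subjects with an
    observed value (pairwise-complete). Proteins observed at baseline in
    fewer than ``min_subjects`` subjects in either arm are flagged
    ``insufficient`` with a missing diff.

    Returns a frame indexed by protein with columns
    ``n_lotion, n_ff, diff_pai, abs_diff, fold, insufficient``.
    """
    base = design[design["timepoint"] == "baseline"]
    cols = {}
    for arm in ("lotion", "lotion_ff"):
        samples = base.loc[base["arm"] == arm, "sample_id"]
        missing = [s for s in samples if s not in pai.columns]
        if missing:
            raise ValidationError(f"baseline samples absent from PAI matrix: {missing}")
        cols[arm] = pai[list(samples)]
    if cols["lotion"].shape[1] == 0 or cols["lotion_ff"].shape[1] == 0:
        raise ValidationError("both arms must have baseline samples")

    n_lot = cols["lotion"].notna().sum(axis=1)
    n_ff = cols["lotion_ff"].notna().sum(axis=1)
    diff = cols["lotion_ff"].mean(axis=1) - cols["lotion"].mean(axis=1)
    insufficient = (n_lot < min_subjects) | (n_ff < min_subjects)
    diff = diff.where(~insufficient)
    out = pd.DataFrame({
        "n_lotion": n_lot,
        "n_ff": n_ff,
        "diff_pai": diff,
        "abs_diff": diff.abs(),
        "fold": np.power(10.0, diff.abs()),
        "insufficient": insufficient,
    })
    out.index.name = "protein_id"
    n_insuff = int(insufficient.sum())
    if n_insuff:
        logger.warning("baseline_differences: %d proteins with insufficient "
                       "baseline coverage", n_insuff)
    return out.sort_index()


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the concordance filter."""

    retained: list[str]
    excluded: pd.DataFrame  # protein-indexed, sorted by descending fold
    insufficient: list[str]


def apply_concordance_filter(diffs: pd.DataFrame, retention: float = 0.95,
                             method: str = "count") -> FilterResult:
    """Split proteins into baseline-concordant (retained) and discordant.

    ``method="count"`` (default) retains exactly floor(retention * P)
    proteins with the smallest ``abs_diff`` among the P proteins with a
    defined difference; ties break on (abs_diff, accession) for determinism.
    ``method="percentile"`` instead thresholds at the empirical
    retention-quantile of abs_diff.
    """
    if not (0.0 < retention <= 1.0):
        raise ValidationError(f"retention fraction must be in (0, 1], got {retention}")
    defined = diffs[diffs["diff_pai"].notna()]
    insufficient = sorted(diffs.index[diffs["diff_pai"].isna()])
    p = len(defined)
    # mergesort is stable; pre-sorting the index makes the tie-break lexicographic
    order = defined.loc[sorted(defined.index)].sort_values(
        by=["abs_diff"], kind="mergesort")
    if method == "count":
        n_keep = math.floor(retention * p)
        retained = order.index[:n_keep].tolist()
        excluded = order.iloc[n_keep:]
    elif method == "percentile":
        if p == 0:
            retained, excluded = [], order
        else:
            threshold = order["abs_diff"].quantile(retention)
            keep = order["abs_diff"] <= threshold
            retained = order.index[keep].tolist()
            excluded = order[~keep]
    else:
        raise ValidationError(f"unknown filter method {method!r}")
    excluded = excluded.sort_values(
        by=["fold"], ascending=False, kind="mergesort")
    logger.info("concordance filter: %d retained, %d excluded, %d insufficient",
                len(retained), len(excluded), len(insufficient))
    return FilterResult(retained=retained, excluded=excluded,
                        insufficient=insufficient)
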
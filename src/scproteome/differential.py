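"""Paired differential analysis of PAI profiles.

Per arm, the baseline -> day 14 change of each protein is the mean over
subjects of ΔPAI = PAI(day14) − PAI(baseline); because PAI is log10-scale,
the arm fold change is 10^(mean ΔPAI) (a geometric-mean-style fold). The
treatment contrast compares the two arms within subject: for each protein
the paired differences d_s = ΔPAI_ff(s) − ΔPAI_lotion(s) feed an exact
paired Wilcoxon signed-rank test, and the resulting p-values are converted
to Storey q-values (FDR) across the retained proteins. Proteins are further
classified by the signs of their per-arm log fold changes into the four
scatter-plot quadrants, and the between-arm fold-change ratio
fc_ff / fc_lotion summarizes the film's added effect.

The Wilcoxon p-value is exact — the null distribution of the positive rank
sum W+ over all 2^n sign assignments, computed by dynamic programming — for
n <= ``exact_n_max`` untied differences; otherwise a normal approximation
with tie-corrected variance and continuity correction is used. Zero
differences are dropped before ranking; an all-zero vector is flagged
degenerate with p = 1 so that noise-free null fixtures run end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ARMS, ValidationError

logger = logging.getLogger("scproteome")

LOG10_2 = np.log10(2.0)

QUADRANTS = ("up_up", "down_down", "up_ff_down_lotion", "up_lotion_down_ff",
             "boundary")


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def signed_rank_null_counts(n: int) -> np.ndarray:
    """Null distribution of the positive rank sum W+ for n untied pairs.

    Entry [w] counts the sign assignments of ranks 1..n whose positive-rank
    sum equals w; entries sum to 2^n. Computed by the subset-sum dynamic
    program (polynomial product of (1 + x^r) for r = 1..n).
    """
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        nxt = counts.copy()
        nxt[r:] += counts[: counts.size - r]
        counts = nxt
    return counts


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test result."""

    p_value: float
    statistic: float  # W+ (sum of ranks of positive differences)
    n: int            # pairs used after zero removal
    method: str       # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def wilcoxon_signed_rank(diffs, exact_n_max: int = 25,
                         zero_tol: float = 1e-10) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zeros are dropped before ranking (standard signed-rank convention);
    differences with |d| <= ``zero_tol`` count as zeros, so log-scale
    round-trip residue in noise-free fixtures does not masquerade as
    signal (real ΔPAI values are orders of magnitude above the tolerance).
    The p-value is exact by full enumeration of sign assignments when the
    remaining n <= ``exact_n_max`` and the |differences| are untied, and a
    tie-corrected, continuity-corrected normal approximation otherwise. An
    all-zero vector yields the degenerate result p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[np.abs(d) > zero_tol]
    n = d.size
    if n == 0:
        return WilcoxonResult(p_value=1.0, statistic=np.nan, n=0,
                              method="degenerate")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)  # average ranks under ties
    w_pos = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= exact_n_max and not has_ties:
        counts = signed_rank_null_counts(n)
        total = counts.sum()
        cdf = counts.cumsum()
        w = int(round(w_pos))
        p_low = cdf[w] / total
        p_high = (total - (cdf[w - 1] if w >= 1 else 0.0)) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return WilcoxonResult(p_value=p, statistic=w_pos, n=n, method="exact")
    # normal approximation with tie-corrected variance + continuity correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(p_value=1.0, statistic=w_pos, n=n,
                              method="degenerate")
    dev = w_pos - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    p = max(p, np.finfo(float).tiny)
    return WilcoxonResult(p_value=p, statistic=w_pos, n=n, method="normal")


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(p_values, lambdas=None,
                   pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Convert p-values to Storey q-values.

    The null proportion π₀ is estimated on the λ-grid 0.05, 0.10, ..., 0.95
    from π₀(λ) = #{p > λ} / (m (1 − λ)), smoothed with a least-squares cubic
    over the grid and evaluated at the largest λ, then clamped to
    [1/m, 1] (the lower clamp keeps q-values strictly positive). Passing
    ``pi0`` explicitly (e.g. 1.0) skips estimation; with π₀ = 1 the q-values
    are exactly Benjamini–Hochberg adjusted p-values.

    Returns (q, pi0_hat); q is monotone non-decreasing in p and lies in
    (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be a 1-d vector")
    if p.size == 0:
        return np.array([]), 1.0
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam))
                            for lam in lambdas])
        coeffs = np.polyfit(lambdas, pi0_lam, 3)
        pi0_hat = float(np.polyval(coeffs, lambdas.max()))
    else:
        pi0_hat = float(pi0)
    pi0_hat = min(1.0, max(pi0_hat, 1.0 / m))

    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1) * pi0_hat
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0_hat


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def subject_log_fold_changes(pai: pd.DataFrame, design: pd.DataFrame,
                             arm: str) -> pd.DataFrame:
    """Per-subject ΔPAI = PAI(day14) − PAI(baseline) for one arm.

    Returns a proteins x subjects matrix; a cell is missing when either
    endpoint is missing for that subject.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; expected one of {ARMS}")
    sub = design[design["arm"] == arm]
    cols = {}
    for tp in ("baseline", "day14"):
        rows = sub[sub["timepoint"] == tp]
        mapping = dict(zip(rows["sample_id"], rows["subject_id"]))
        present = [s for s in mapping if s in pai.columns]
        frame = pai[present].copy()
        frame.columns = [mapping[s] for s in present]
        cols[tp] = frame
    shared = sorted(set(cols["baseline"].columns) & set(cols["day14"].columns))
    delta = cols["day14"][shared] - cols["baseline"][shared]
    delta.columns.name = "subject_id"
    return delta


def arm_fold_change(delta: pd.DataFrame) -> pd.DataFrame:
    """Per-protein arm log fold change: lfc = mean over subjects of ΔPAI.

    Also reports fc = 10^lfc and the number of subjects used. Proteins with
    no usable subject are dropped (with a warning).
    """
    n = delta.notna().sum(axis=1)
    lfc = delta.mean(axis=1)
    out = pd.DataFrame({"lfc": lfc, "fc": np.power(10.0, lfc), "n": n})
    dropped = out.index[n == 0].tolist()
    if dropped:
        logger.warning("arm_fold_change: dropping %d proteins with no "
                       "usable subject: %s", len(dropped), dropped[:5])
    return out[n > 0]


def test_between_arm_changes(delta_lotion: pd.DataFrame,
                             delta_ff: pd.DataFrame,
                             exact_n_max: int = 25) -> pd.DataFrame:
    """Paired between-arm test per protein.

    For each protein, the within-subject contrast d_s = ΔPAI_ff(s) −
    ΔPAI_lotion(s) over shared subjects feeds the paired Wilcoxon
    signed-rank test. Proteins with fewer than 2 complete pairs are flagged
    ``untestable`` (p missing). q-values are not computed here — callers
    apply :func:`storey_qvalues` to the family they define.
    """
    shared = sorted(set(delta_lotion.columns) & set(delta_ff.columns))
    if not shared:
        raise ValidationError("no shared subjects between arm matrices")
    proteins = delta_lotion.index.intersection(delta_ff.index)
    d = delta_ff.loc[proteins, shared] - delta_lotion.loc[proteins, shared]
    records = []
    for prot, row in d.iterrows():
        vals = row.to_numpy(dtype=float)
        n_pairs = int(np.sum(~np.isnan(vals)))
        if n_pairs < 2:
            records.append((prot, np.nan, n_pairs, True, "untestable"))
            continue
        res = wilcoxon_signed_rank(vals, exact_n_max=exact_n_max)
        records.append((prot, res.p_value, n_pairs, res.degenerate, res.method))
    out = pd.DataFrame(records, columns=["protein_id", "p_value", "n",
                                         "degenerate", "method"])
    return out.set_index("protein_id")


def within_arm_tests(delta: pd.DataFrame,
                     exact_n_max: int = 25) -> pd.DataFrame:
    """Paired Wilcoxon of ΔPAI against zero within one arm, per protein."""
    records = []
    for prot, row in delta.iterrows():
        vals = row.to_numpy(dtype=float)
        n_pairs = int(np.sum(~np.isnan(vals)))
        if n_pairs < 2:
            records.append((prot, np.nan, n_pairs, True, "untestable"))
            continue
        res = wilcoxon_signed_rank(vals, exact_n_max=exact_n_max)
        records.append((prot, res.p_value, n_pairs, res.degenerate, res.method))
    out = pd.DataFrame(records, columns=["protein_id", "p_value", "n",
                                         "degenerate", "method"])
    return out.set_index("protein_id")


# ---------------------------------------------------------------------------
# quadrants, ratios, scatter
# ---------------------------------------------------------------------------

def classify_quadrant(lfc_lotion: float, lfc_ff: float) -> str:
    """Sign-based scatter-plot quadrant of a protein's per-arm log fold changes."""
    if np.isnan(lfc_lotion) or np.isnan(lfc_ff):
        raise ValidationError("quadrant classification needs both lfc values")
    if lfc_lotion == 0.0 or lfc_ff == 0.0:
        return "boundary"
    if lfc_lotion > 0 and lfc_ff > 0:
        return "up_up"
    if lfc_lotion < 0 and lfc_ff < 0:
        return "down_down"
    if lfc_lotion < 0 < lfc_ff:
        return "up_ff_down_lotion"
    return "up_lotion_down_ff"


def fold_change_ratio(fc_ff: float, fc_lotion: float) -> float:
    """Between-arm ratio of baseline->day14 fold changes (film vs lotion)."""
    if fc_lotion <= 0:
        raise ValidationError(f"fc_lotion must be > 0, got {fc_lotion}")
    return fc_ff / fc_lotion


@dataclass(frozen=True)
class ScatterSummary:
    """Pearson correlation and marginal histograms of per-arm log2 fold changes."""

    pearson_r: float
    n: int
    bin_edges: np.ndarray
    counts_lotion: np.ndarray
    counts_ff: np.ndarray
    degenerate: bool = False


def scatter_summary(records: pd.DataFrame, n_bins: int = 20) -> ScatterSummary:
    """Summarize the two-arm fold-change scatter.

    ``records`` must carry ``lfc_lotion`` and ``lfc_ff`` columns (log10
    scale). Pearson r is computed over the per-protein pairs of log2 fold
    changes; marginal histograms share one set of bin edges spanning both
    arms. Zero variance on either axis flags the correlation degenerate.
    """
    sub = records[["lfc_lotion", "lfc_ff"]].dropna()
    if len(sub) < 2:
        raise ValidationError("scatter summary needs >= 2 complete records")
    l2_lot = sub["lfc_lotion"].to_numpy() / LOG10_2
    l2_ff = sub["lfc_ff"].to_numpy() / LOG10_2
    degenerate = bool(np.std(l2_lot) == 0 or np.std(l2_ff) == 0)
    r = np.nan if degenerate else float(stats.pearsonr(l2_lot, l2_ff).statistic)
    lo = min(l2_lot.min(), l2_ff.min())
    hi = max(l2_lot.max(), l2_ff.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_lot, _ = np.histogram(l2_lot, bins=edges)
    counts_ff, _ = np.histogram(l2_ff, bins=edges)
    return ScatterSummary(pearson_r=r, n=len(sub), bin_edges=edges,
                          counts_lotion=counts_lot, counts_ff=counts_ff,
                          degenerate=degenerate)


# ---------------------------------------------------------------------------
# assembled differential table
# ---------------------------------------------------------------------------

def differential_table(pai: pd.DataFrame, design: pd.DataFrame,
                       proteins, q_threshold: float = 0.05,
                       exact_n_max: int = 25) -> pd.DataFrame:
    """One differential record per protein for the given (retained) set.

    Columns: per-arm log10 fold changes and folds, between-arm fold ratio,
    quadrant, between-arm Wilcoxon p and Storey q (the significance family,
    mirroring the scatter plot's highlighted proteins), and within-arm
    p/q as separate q-value families.
    """
    proteins = [p for p in proteins if p in pai.index]
    sub = pai.loc[proteins]
    delta_lot = subject_log_fold_changes(sub, design, "lotion")
    delta_ff = subject_log_fold_changes(sub, design, "lotion_ff")
    fc_lot = arm_fold_change(delta_lot)
    fc_ff = arm_fold_change(delta_ff)
    between = test_between_arm_changes(delta_lot, delta_ff,
                                       exact_n_max=exact_n_max)
    within_lot = within_arm_tests(delta_lot, exact_n_max=exact_n_max)
    within_ff = within_arm_tests(delta_ff, exact_n_max=exact_n_max)

    idx = fc_lot.index.intersection(fc_ff.index)
    out = pd.DataFrame(index=idx)
    out.index.name = "protein_id"
    out["lfc_lotion"] = fc_lot.loc[idx, "lfc"]
    out["lfc_ff"] = fc_ff.loc[idx, "lfc"]
    out["fc_lotion"] = fc_lot.loc[idx, "fc"]
    out["fc_ff"] = fc_ff.loc[idx, "fc"]
    out["fc_ratio"] = out["fc_ff"] / out["fc_lotion"]
    out["n_lotion"] = fc_lot.loc[idx, "n"]
    out["n_ff"] = fc_ff.loc[idx, "n"]
    out["quadrant"] = [classify_quadrant(a, b)
                       for a, b in zip(out["lfc_lotion"], out["lfc_ff"])]
    out["p_value"] = between["p_value"].reindex(idx)

    testable = out.index[out["p_value"].notna()]
    q = pd.Series(np.nan, index=out.index)
    pi0_hat = np.nan
    if len(testable) > 0:
        qv, pi0_hat = storey_qvalues(out.loc[testable, "p_value"].to_numpy())
        q.loc[testable] = qv
    out["q_value"] = q
    out["significant"] = out["q_value"] < q_threshold
    out.attrs["pi0_between"] = pi0_hat

    for label, table in (("lotion", within_lot), ("ff", within_ff)):
        pcol = table["p_value"].reindex(idx)
        out[f"p_{label}"] = pcol
        ok = out.index[pcol.notna()]
        qcol = pd.Series(np.nan, index=out.index)
        if len(ok) > 0:
            qv, pi0_arm = storey_qvalues(pcol.loc[ok].to_numpy())
            qcol.loc[ok] = qv
            out.attrs[f"pi0_{label}"] = pi0_arm
        out[f"q_{label}"] = qcol
        out[f"significant_{label}"] = qcol < q_threshold
    return out


def quadrant_counts(records: pd.DataFrame,
                    significant_col: str = "significant") -> pd.DataFrame:
    """Protein counts (total and significant) per scatter quadrant."""
    rows = []
    for quad in QUADRANTS:
        sub = records[records["quadrant"] == quad]
        rows.append((quad, len(sub), int(sub[significant_col].sum())))
    return pd.DataFrame(rows, columns=["quadrant", "n", "n_significant"]
                        ).set_index("quadrant")
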
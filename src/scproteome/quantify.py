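"""Reference-protein quantification for tape-strip proteomics.

Peptide-level intensity tables are rolled up to protein level and normalized
against the single most abundant protein (in stratum corneum tape strips this
is typically keratin 10), yielding the protein amount index (PAI):

* **PPI** — per protein and sample, the sum of the peak intensities of all
  peptides identifying that protein.
* **wt** — per sample, the ratio of the standard protein's PPI to its maximum
  PPI across all samples; lies in (0, 1] and absorbs global loading
  differences between tape strips.
* **PAI** — ``log10(PPI / wt)``, the normalized log-scale protein abundance.

Missing is distinct from zero throughout: a protein with no observed peptide
in a sample has missing PPI (and missing PAI), never ``-inf``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("scproteome")

ARMS = ("lotion", "lotion_ff")
TIMEPOINTS = ("baseline", "day14")

PEPTIDE_COLUMNS = ("peptide_id", "protein_id", "sample_id", "intensity")
DESIGN_COLUMNS = ("sample_id", "subject_id", "arm", "timepoint", "leg")


class ValidationError(ValueError):
    """Raised when an input table violates its schema or invariants."""


def validate_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form peptide intensity table.

    Requires columns ``peptide_id, protein_id, sample_id, intensity``; each
    (peptide_id, sample_id) pair must be unique and every intensity finite
    and >= 0. Rows with missing intensity (``NA``) are allowed and treated as
    unobserved. Returns the table with ``intensity`` coerced to float.
    """
    missing_cols = [c for c in PEPTIDE_COLUMNS if c not in peptides.columns]
    if missing_cols:
        raise ValidationError(f"peptide table missing columns: {missing_cols}")
    out = peptides.copy()
    out["intensity"] = pd.to_numeric(out["intensity"], errors="coerce")
    observed = out["intensity"].notna()
    bad = observed & (~np.isfinite(out["intensity"].to_numpy(dtype=float))
                      | (out["intensity"] < 0))
    if bad.any():
        row = out[bad].iloc[0]
        raise ValidationError(
            "negative or non-finite intensity for peptide "
            f"{row['peptide_id']!r} in sample {row['sample_id']!r}"
        )
    dup = out.duplicated(subset=["peptide_id", "sample_id"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for peptide {row['peptide_id']!r} in sample "
            f"{row['sample_id']!r}"
        )
    return out


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a study design table (one row per sample)."""
    missing_cols = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing_cols:
        raise ValidationError(f"design table missing columns: {missing_cols}")
    bad_arm = ~design["arm"].isin(ARMS)
    if bad_arm.any():
        raise ValidationError(
            f"unknown arm label {design.loc[bad_arm, 'arm'].iloc[0]!r}; "
            f"expected one of {ARMS}"
        )
    bad_tp = ~design["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        raise ValidationError(
            f"unknown timepoint {design.loc[bad_tp, 'timepoint'].iloc[0]!r}; "
            f"expected one of {TIMEPOINTS}"
        )
    if design["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in design table")
    dup = design.duplicated(subset=["subject_id", "arm", "timepoint"])
    if dup.any():
        row = design[dup].iloc[0]
        raise ValidationError(
            "more than one sample for subject "
            f"{row['subject_id']!r}, arm {row['arm']!r}, "
            f"timepoint {row['timepoint']!r}"
        )
    # warn about subjects that cannot enter paired analyses
    cells = design.groupby("subject_id").size()
    unpaired = cells[cells < 4].index.tolist()
    if unpaired:
        logger.warning("subjects without all 4 arm/timepoint samples: %s",
                       unpaired)
    return design


def compute_ppi(peptides: pd.DataFrame) -> pd.DataFrame:
    """Roll peptide intensities up to protein peak intensity (PPI).

    Returns a proteins x samples matrix where each cell is the sum of the
    observed peptide intensities of that protein in that sample; cells with
    no observed peptide are NaN (missing), not zero.
    """
    peptides = validate_peptides(peptides)
    observed = peptides.dropna(subset=["intensity"])
    n_dropped = len(peptides) - len(observed)
    if n_dropped:
        logger.info("compute_ppi: %d unobserved peptide records ignored",
                    n_dropped)
    ppi = observed.pivot_table(
        index="protein_id", columns="sample_id", values="intensity",
        aggfunc="sum",
    )
    # keep every sample that appears anywhere in the input
    all_samples = pd.Index(sorted(peptides["sample_id"].unique()),
                           name="sample_id")
    ppi = ppi.reindex(columns=all_samples).sort_index()
    return ppi


@dataclass(frozen=True)
class Weights:
    """Per-sample normalization weights derived from the standard protein.

    ``wt`` maps sample_id -> PPI_i(standard) / PPI_k(standard) where k is the
    sample with the maximum standard-protein PPI (``reference_sample``); the
    maximum weight is exactly 1.
    """

    wt: pd.Series
    reference_sample: str
    standard_protein: str


def select_standard_protein(ppi: pd.DataFrame, force: str | None = None) -> str:
    """Pick the normalization standard: the protein with the highest PPI.

    Among proteins observed (PPI > 0) in every sample, the one with the
    largest total PPI across samples wins; exact ties break to the
    lexicographically smallest accession. ``force`` overrides the selection
    with a named accession (it must still be observed everywhere).
    """
    if force is not None:
        if force not in ppi.index:
            raise ValidationError(f"standard protein {force!r} not in PPI matrix")
        row = ppi.loc[force]
        if row.isna().any() or (row <= 0).any():
            raise ValidationError(
                f"standard protein {force!r} is missing or zero in some sample"
            )
        return force
    complete = ppi.dropna(axis=0)
    complete = complete[(complete > 0).all(axis=1)]
    if complete.empty:
        raise ValidationError(
            "no protein observed with PPI > 0 in every sample; "
            "cannot select a standard protein"
        )
    totals = complete.sum(axis=1)
    best = totals.max()
    candidates = sorted(totals.index[totals == best])
    return candidates[0]


def compute_weights(ppi: pd.DataFrame, standard: str,
                    reference_sample: str | None = None) -> Weights:
    """Compute per-sample weights wt_i = PPI_i(standard) / PPI_k(standard).

    By default the reference sample k is the one attaining the maximum
    standard-protein PPI, so all weights lie in (0, 1] with the maximum
    exactly 1. Pinning ``reference_sample`` keeps the weight denominator
    tied to the same physical sample across re-analyses (e.g. when samples
    are re-scaled or a batch is extended), which is what makes PAI exactly
    invariant to per-sample loading.
    """
    if standard not in ppi.index:
        raise ValidationError(f"standard protein {standard!r} not in PPI matrix")
    row = ppi.loc[standard]
    if row.isna().any() or (row <= 0).any():
        bad = row.index[row.isna() | (row <= 0)][0]
        raise ValidationError(
            f"standard protein {standard!r} missing or zero in sample {bad!r}"
        )
    if reference_sample is None:
        reference_sample = row.idxmax()
    elif reference_sample not in row.index:
        raise ValidationError(
            f"reference sample {reference_sample!r} not in PPI matrix")
    wt = row / row.loc[reference_sample]
    wt.name = "wt"
    return Weights(wt=wt, reference_sample=str(reference_sample),
                   standard_protein=standard)


def compute_pai(ppi: pd.DataFrame, weights: Weights) -> pd.DataFrame:
    """Protein amount index: PAI = log10(PPI / wt), missing where PPI is.

    Cells with PPI == 0 are treated as missing (a protein observed at zero
    intensity carries no quantitative signal on the log scale).
    """
    wt = weights.wt.reindex(ppi.columns)
    if wt.isna().any():
        missing = wt.index[wt.isna()][0]
        raise ValidationError(f"no weight for sample {missing!r}")
    norm = ppi.divide(wt, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pai = np.log10(norm.where(norm > 0))
    return pai


def quantify(peptides: pd.DataFrame, standard: str | None = None,
             reference_sample: str | None = None
             ) -> tuple[pd.DataFrame, Weights, pd.DataFrame]:
    """Full quantification chain: peptides -> (PPI, weights, PAI)."""
    ppi = compute_ppi(peptides)
    std = select_standard_protein(ppi, force=standard)
    weights = compute_weights(ppi, std, reference_sample=reference_sample)
    pai = compute_pai(ppi, weights)
    return ppi, weights, pai
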
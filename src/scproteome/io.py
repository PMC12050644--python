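"""File formats, configuration and pipeline orchestration.

All tables are UTF-8 TSV with a header row, ``.`` decimal separator, ``NA``
missing token and LF line endings. The full pipeline is quantify ->
baseline filter -> differential -> annotate -> clinical; a run manifest
records parameters and SHA-256 checksums of inputs and outputs, and every
output is reproducible bit-for-bit from (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .annotate import load_function_map, render_report, group_fold_change_table
from .baseline import apply_concordance_filter, baseline_differences
from .clinical import paired_endpoint_tests, validate_clinical
from .differential import (differential_table, quadrant_counts,
                           scatter_summary)
from .quantify import (ValidationError, quantify, validate_design,
                       validate_peptides)

logger = logging.getLogger("scproteome")

NA_TOKEN = "NA"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | os.PathLike, required: tuple[str, ...],
              numeric: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN],
                         keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValidationError(
                f"{path}: non-numeric {col!r} value {df.loc[bad.idxmax(), col]!r} "
                f"at line {line}")
        n_missing = int(converted.isna().sum())
        if n_missing:
            logger.info("%s: %d missing %r values", path, n_missing, col)
        df[col] = converted
    return df


def read_peptides(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a peptides.tsv (peptide_id, protein_id, sample_id, intensity)."""
    df = _read_tsv(path, ("peptide_id", "protein_id", "sample_id", "intensity"),
                   numeric=("intensity",))
    return validate_peptides(df)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a design.tsv (sample_id, subject_id, arm, timepoint, leg)."""
    df = _read_tsv(path, ("sample_id", "subject_id", "arm", "timepoint", "leg"))
    return validate_design(df)


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a clinical.tsv (subject_id, arm, day, endpoint, value)."""
    df = _read_tsv(path, ("subject_id", "arm", "day", "endpoint", "value"),
                   numeric=("day", "value"))
    return validate_clinical(df)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a proteins x samples matrix TSV (first column = protein_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    df.index.name = "protein_id"
    return df


def write_table(table: pd.DataFrame, path: str | os.PathLike,
                index: bool = True) -> str:
    """Write a TSV with the package's fixed conventions."""
    path = os.fspath(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    table.to_csv(path, sep="\t", na_rep=NA_TOKEN, lineterminator="\n",
                 index=index)
    return path


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run."""

    peptides: str
    design: str
    out_dir: str
    clinical: str | None = None
    function_map: str | None = None
    retention_fraction: float = 0.95
    q_threshold: float = 0.05
    standard_protein: str | None = None
    exact_n_max: int = 25
    filter_method: str = "count"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.retention_fraction <= 1.0):
            raise ValidationError("retention_fraction must be in (0, 1]")
        if not (0.0 < self.q_threshold < 1.0):
            raise ValidationError("q_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------

def analyze_study(peptides: pd.DataFrame, design: pd.DataFrame,
                  retention_fraction: float = 0.95,
                  q_threshold: float = 0.05,
                  standard_protein: str | None = None,
                  exact_n_max: int = 25,
                  filter_method: str = "count") -> dict[str, Any]:
    """Run quantification, baseline filter and differential analysis in memory.

    Returns a dict with ``ppi, weights, pai, baseline, filter, differential,
    quadrants, scatter`` — the complete proteomics arm of the pipeline
    without touching disk. This is also the engine behind
    :func:`run_pipeline` and the simulation studies.
    """
    design = validate_design(design)
    ppi, weights, pai = quantify(peptides, standard=standard_protein)
    diffs = baseline_differences(pai, design)
    filt = apply_concordance_filter(diffs, retention=retention_fraction,
                                    method=filter_method)
    records = differential_table(pai, design, filt.retained,
                                 q_threshold=q_threshold,
                                 exact_n_max=exact_n_max)
    quads = quadrant_counts(records)
    scatter = scatter_summary(records) if len(records) >= 2 else None
    return {"ppi": ppi, "weights": weights, "pai": pai, "baseline": diffs,
            "filter": filt, "differential": records, "quadrants": quads,
            "scatter": scatter}


# ---------------------------------------------------------------------------
# full pipeline with artifacts
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all artifacts.

    Stages: quantify -> filter -> differential -> annotate -> clinical ->
    report. Any stage error aborts with a stage-named message. Returns the
    manifest (also written as manifest.json).
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    peptides = stage("read", lambda: read_peptides(config.peptides))
    design = stage("read", lambda: read_design(config.design))
    logger.info("loaded %d peptide records, %d samples",
                len(peptides), len(design))

    results = stage("analyze", lambda: analyze_study(
        peptides, design,
        retention_fraction=config.retention_fraction,
        q_threshold=config.q_threshold,
        standard_protein=config.standard_protein,
        exact_n_max=config.exact_n_max,
        filter_method=config.filter_method))

    outputs: dict[str, str] = {}
    outputs["ppi.tsv"] = write_table(results["ppi"], os.path.join(out, "ppi.tsv"))
    wt = results["weights"]
    wt_frame = wt.wt.to_frame()
    wt_frame["is_reference"] = wt_frame.index == wt.reference_sample
    outputs["weights.tsv"] = write_table(wt_frame, os.path.join(out, "weights.tsv"))
    outputs["pai.tsv"] = write_table(results["pai"], os.path.join(out, "pai.tsv"))

    base = results["baseline"].copy()
    base["excluded"] = base.index.isin(results["filter"].excluded.index)
    outputs["baseline_diffs.tsv"] = write_table(
        base, os.path.join(out, "baseline_diffs.tsv"))
    retained_path = os.path.join(out, "retained.txt")
    with open(retained_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(results["filter"].retained) + "\n")
    outputs["retained.txt"] = retained_path

    records = results["differential"]
    outputs["differential.tsv"] = write_table(
        records, os.path.join(out, "differential.tsv"))

    scatter = results["scatter"]
    if scatter is not None:
        scatter_frame = pd.DataFrame({
            "bin_left": scatter.bin_edges[:-1],
            "bin_right": scatter.bin_edges[1:],
            "count_lotion": scatter.counts_lotion,
            "count_ff": scatter.counts_ff,
        })
        outputs["scatter.tsv"] = write_table(
            scatter_frame, os.path.join(out, "scatter.tsv"), index=False)

    qc_rows = [("n_proteins", float(len(results["baseline"]))),
               ("n_retained", float(len(results["filter"].retained))),
               ("n_excluded", float(len(results["filter"].excluded))),
               ("pi0_between", float(records.attrs.get("pi0_between", np.nan))),
               ("pearson_r",
                float(scatter.pearson_r) if scatter is not None else np.nan)]
    for quad, row in results["quadrants"].iterrows():
        qc_rows.append((f"n_{quad}", float(row["n"])))
        qc_rows.append((f"n_significant_{quad}", float(row["n_significant"])))
    qc = pd.DataFrame(qc_rows, columns=["metric", "value"])
    outputs["qc_summary.tsv"] = write_table(
        qc, os.path.join(out, "qc_summary.tsv"), index=False)

    fmap = stage("annotate", lambda: load_function_map(config.function_map))
    report_paths = stage("report", lambda: render_report(records, fmap, out))
    outputs.update(report_paths)

    if config.clinical is not None:
        clinical = stage("clinical", lambda: read_clinical(config.clinical))
        tests = []
        for endpoint in sorted(clinical["endpoint"].unique()):
            tests.append(stage("clinical", lambda e=endpoint: paired_endpoint_tests(
                clinical, e, alpha=config.q_threshold)))
        clin = pd.concat(tests, ignore_index=True)
        outputs["clinical_tests.tsv"] = write_table(
            clin, os.path.join(out, "clinical_tests.tsv"), index=False)

    manifest: dict[str, Any] = {
        "package": "scproteome",
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {os.path.basename(p): sha256_file(p)
                   for p in (config.peptides, config.design, config.clinical)
                   if p is not None},
        "outputs": {name: sha256_file(path)
                    for name, path in sorted(outputs.items())},
    }
    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = manifest_path
    return manifest
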
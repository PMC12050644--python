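"""Functional grouping of differential results.

Proteins are assigned to functional groups (keratins, proteasome,
filaggrin processing, cornified-envelope processing, cytoskeleton, redox,
...) from a local two-column mapping table; unmapped proteins fall into
``unassigned``. Per group, the report carries the members' between-arm
log2 fold-change ratios (dot-plot values) and per-arm log2 fold-change
five-number summaries (box-plot values), plus the count of significant
members. A curated default map covering the stratum corneum marker
proteins discussed in the differential analysis ships with the package.
"""

from __future__ import annotations

import logging
import os
from importlib import resources

import numpy as np
import pandas as pd

from .differential import LOG10_2
from .quantify import ValidationError

logger = logging.getLogger("scproteome")

UNASSIGNED = "unassigned"


def default_function_map_path() -> str:
    """Path to the packaged curated protein -> group table."""
    return str(resources.files("scproteome").joinpath("data/function_map.tsv"))


def load_function_map(path: str | os.PathLike | None = None) -> pd.Series:
    """Load a protein -> group mapping from a two-column TSV.

    Duplicate accessions or malformed rows raise an error naming the line.
    With ``path=None`` the packaged default map is used.
    """
    if path is None:
        path = default_function_map_path()
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip().split("\t")[:2] != ["protein_id", "group_label"]:
            raise ValidationError(
                f"{path}: expected header 'protein_id\\tgroup_label'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValidationError(f"{path}: malformed row at line {lineno}")
            prot, group = parts
            if prot in mapping:
                raise ValidationError(
                    f"{path}: duplicate accession {prot!r} at line {lineno}")
            mapping[prot] = group
    return pd.Series(mapping, name="group_label")


def assign_groups(proteins, function_map: pd.Series) -> pd.Series:
    """Group label per protein; proteins absent from the map -> 'unassigned'."""
    idx = pd.Index(proteins, name="protein_id")
    return function_map.reindex(idx).fillna(UNASSIGNED)


def _five_number(values: np.ndarray) -> tuple[float, float, float, float, float]:
    return (float(np.min(values)), float(np.percentile(values, 25)),
            float(np.median(values)), float(np.percentile(values, 75)),
            float(np.max(values)))


def group_fold_change_table(records: pd.DataFrame,
                            function_map: pd.Series
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein group assignments and per-group fold-change summaries.

    ``records`` is a differential table with ``lfc_lotion``, ``lfc_ff``,
    ``fc_ratio`` and ``significant`` columns. Returns ``(members, summary)``:
    members carries one row per protein with its group and log2 fold-change
    ratio; summary has, per group, the member count, significant count,
    median log2 ratio, and per-arm log2 fold-change five-number summaries.
    Groups sort lexicographically. Membership is a partition — every record
    lands in exactly one group.
    """
    if records.empty:
        members = pd.DataFrame(columns=["group_label", "log2_fc_ratio",
                                        "significant"])
        members.index.name = "protein_id"
        summary = pd.DataFrame(columns=["n", "n_significant",
                                        "median_log2_fc_ratio"])
        summary.index.name = "group_label"
        return members, summary
    groups = assign_groups(records.index, function_map)
    members = pd.DataFrame({
        "group_label": groups,
        "log2_fc_ratio": np.log2(records["fc_ratio"]),
        "log2_fc_lotion": records["lfc_lotion"] / LOG10_2,
        "log2_fc_ff": records["lfc_ff"] / LOG10_2,
        "significant": records["significant"].astype(bool),
    })
    members = members.sort_values(["group_label"], kind="mergesort")

    rows = []
    for group, sub in members.groupby("group_label", sort=True):
        row = {"group_label": group, "n": len(sub),
               "n_significant": int(sub["significant"].sum()),
               "median_log2_fc_ratio": float(sub["log2_fc_ratio"].median())}
        for arm in ("lotion", "ff"):
            vals = sub[f"log2_fc_{arm}"].to_numpy(dtype=float)
            for stat, val in zip(("min", "q1", "median", "q3", "max"),
                                 _five_number(vals)):
                row[f"{arm}_{stat}"] = val
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group_label").sort_index()
    return members, summary


def render_report(records: pd.DataFrame, function_map: pd.Series,
                  out_dir: str | os.PathLike) -> dict[str, str]:
    """Write groups.tsv and group_summary.tsv; idempotent."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    members, summary = group_fold_change_table(records, function_map)
    paths = {}
    for name, table in (("groups.tsv", members),
                        ("group_summary.tsv", summary)):
        path = os.path.join(out_dir, name)
        table.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")
        paths[name] = path
    return paths
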
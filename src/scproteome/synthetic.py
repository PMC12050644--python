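"""Synthetic contralateral tape-strip studies with known ground truth.

The generator emulates the design of a two-arm, two-timepoint stratum
corneum study: each subject treats one lower leg with lotion alone and the
other with lotion plus the fine-fiber film, sampled at baseline and after
14 days. Protein log10 abundances are drawn once per protein, a designated
standard protein (keratin-10-like) receives a large abundance boost so it
dominates every sample, and each sample gets a global multiplicative
loading factor — the quantity the PAI normalization must remove. Planted
treatment effects (per-protein, per-arm ΔPAI between baseline and day 14)
and baseline between-arm offsets (discordant proteins the concordance
filter should catch) are recorded in a ground-truth table.

A protein's per-sample signal is split across its peptides by fixed
per-peptide proportions drawn once per protein (ionization propensity), so
the peptide-sum rollup reconstructs the protein signal exactly; peptide
intensities then drop out independently at ``missing_rate``. Peptide
intensities are modeled log-normal — a modeling assumption, not an
empirical fact about any instrument.

Clinical endpoints come from a simple linear improvement model (observer
dryness score decreasing, conductance increasing, both steeper in the film
arm) with subject-level random intercepts; this is deliberately minimal —
just enough structure to exercise the endpoint statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import ARMS, TIMEPOINTS


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class Effect:
    """A planted treatment effect: ΔPAI added at day 14 in one arm."""

    protein_id: str
    arm: str
    delta_pai: float


@dataclass(frozen=True)
class BaselineOutlier:
    """A planted baseline-discordant protein: PAI offset in the film arm."""

    protein_id: str
    delta_pai: float


# Fold changes the study narrative reports for named marker proteins
# (lotion-alone fold, film fold); None means no change in that arm.
_MARKER_EFFECTS: dict[str, tuple[float | None, float | None]] = {
    "SBSN": (0.5, 1.9), "VIM": (1.2, 2.3), "ASPRV1": (1.3, 2.0),
    "BLMH": (None, 1.6), "ANXA2": (None, 0.6), "PRDX2": (None, 0.7),
    "SERPINB8": (None, 1.5), "GSDMA": (None, 1.4), "ASAH1": (None, 1.5),
    "ALOX12B": (None, 1.5), "ALOXE3": (None, 0.95), "DSG1": (None, 1.4),
    "FLNA": (None, 1.5), "FLNB": (None, 1.4), "TTN": (None, 1.4),
    "ARHGEF17": (None, 0.7), "GGH": (None, 1.4), "GAPDH": (None, 1.4),
    "CAPNS1": (None, 0.7), "HSPA5": (None, 1.4), "NPEPPS": (None, 1.4),
    "SRP68": (None, 1.4), "ACVR2A": (None, 1.4), "LAMA2": (None, 1.4),
    "SBNO1": (None, 1.3), "EN2": (None, 1.3), "NCCRP1": (None, 1.3),
    "MUC16": (None, 1.3), "NAV1": (None, 1.3), "GFAP": (None, 0.7),
    "GGCT": (None, 1.3), "HAL": (None, 1.2), "ARG1": (None, 1.1),
    "CASP14": (None, 1.05), "DSC1": (None, 1.3),
    "KRT1": (1.2, 1.8), "KRT2": (None, 1.6), "KRT3": (None, 1.4),
    "KRT5": (None, 1.5), "KRT7": (None, 1.5), "KRT19": (None, 1.5),
    "KRT23": (None, 1.4), "KRT26": (None, 1.4), "KRT27": (None, 1.4),
    "KRT28": (None, 1.4), "KRT75": (None, 1.4), "KRT80": (None, 1.4),
    "KRT8": (None, 0.7), "KRT15": (None, 0.7), "KRT73": (None, 0.7),
}

# Baseline-discordant proteins and their between-arm fold magnitudes; signs
# alternate so discordance occurs in both directions.
_BASELINE_OUTLIER_FOLDS: dict[str, float] = {
    "HBB": 3.8, "S100A7": -3.2, "S100A9": 3.1, "HSPA8": -2.8,
    "TUFT1": 2.5, "CALML5": -2.4, "IL37": 2.1, "SERPINB2": -1.9,
    "PGK1": 1.9,
}


def default_effects() -> list[Effect]:
    """Planted effects emulating the study's fold-change structure.

    Named marker proteins get the narrative's film-arm folds; where only a
    film fold is known, the lotion arm receives a damped response (half the
    log fold), reflecting that the stratum corneum proteome largely follows
    the lotion with the film amplifying it. A deterministic block of
    generic response proteins (RSP001...) with correlated per-arm changes
    fills in the broad two-arm scatter — mostly concordant, mostly boosted
    by the film — that the real study showed.
    """
    effects = []
    for prot, (fc_lotion, fc_ff) in _MARKER_EFFECTS.items():
        d_ff = None if fc_ff is None else float(np.log10(fc_ff))
        if fc_lotion is not None:
            d_lot = float(np.log10(fc_lotion))
        else:
            d_lot = 0.5 * d_ff
        effects.append(Effect(prot, "lotion", d_lot))
        if d_ff is not None:
            effects.append(Effect(prot, "lotion_ff", d_ff))
    # generic correlated response block: alternating up/down lotion ramps
    # with a mostly positive film boost
    boosts = (0.15, 0.10, 0.05, -0.05)
    for j in range(72):
        prot = f"RSP{j + 1:03d}"
        step = j // 2
        if j % 2 == 0:
            d_lot = 0.05 + 0.40 * step / 35.0
        else:
            d_lot = -0.05 - 0.30 * step / 35.0
        d_ff = d_lot + boosts[j % 4]
        effects.append(Effect(prot, "lotion", round(d_lot, 6)))
        effects.append(Effect(prot, "lotion_ff", round(d_ff, 6)))
    return effects


def default_baseline_outliers() -> list[BaselineOutlier]:
    """Nine planted baseline-discordant proteins (fold magnitudes 1.9-3.8x)."""
    return [BaselineOutlier(prot, float(np.sign(f) * np.log10(abs(f))))
            for prot, f in _BASELINE_OUTLIER_FOLDS.items()]


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete statistical description of a synthetic study.

    Defaults describe a study of 8 subjects and 172 proteins with a
    dominant keratin-10-like standard protein, per-sample loading variation,
    ~30% of proteins carrying planted treatment effects, and nine planted
    baseline-discordant proteins.
    """

    n_subjects: int = 8
    n_proteins: int = 172
    peptides_min: int = 2
    peptides_max: int = 8
    base_abundance_mean: float = 6.0   # log10 MS intensity units
    base_abundance_sd: float = 0.8
    standard_protein_boost: float = 3.0  # log10 offset of the standard
    standard_protein_id: str = "K1C10"
    sample_scale_sd: float = 0.15      # per-sample log10 loading factor sd
    noise_sd: float = 0.05             # per-protein per-sample log10 noise sd
    effects: tuple[Effect, ...] = field(
        default_factory=lambda: tuple(default_effects()))
    baseline_outliers: tuple[BaselineOutlier, ...] = field(
        default_factory=lambda: tuple(default_baseline_outliers()))
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_proteins < 2:
            raise ConfigError("n_proteins must be >= 2")
        if not (1 <= self.peptides_min <= self.peptides_max):
            raise ConfigError("peptides_min/peptides_max must satisfy "
                              "1 <= min <= max")
        for name in ("base_abundance_sd", "sample_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.standard_protein_boost <= 0:
            raise ConfigError("standard_protein_boost must be > 0")
        named = len(self._named_proteins())
        if self.n_proteins < named:
            raise ConfigError(
                f"n_proteins={self.n_proteins} is smaller than the "
                f"{named} named proteins in effects/baseline_outliers")
        for eff in self.effects:
            if eff.arm not in ARMS:
                raise ConfigError(f"effects: unknown arm {eff.arm!r}")
        keys = [(e.protein_id, e.arm) for e in self.effects]
        if len(keys) != len(set(keys)):
            raise ConfigError("effects: duplicate (protein, arm) entry")
        out_keys = [o.protein_id for o in self.baseline_outliers]
        if len(out_keys) != len(set(out_keys)):
            raise ConfigError("baseline_outliers: duplicate protein entry")

    def _named_proteins(self) -> list[str]:
        names = [self.standard_protein_id]
        for eff in self.effects:
            if eff.protein_id not in names:
                names.append(eff.protein_id)
        for out in self.baseline_outliers:
            if out.protein_id not in names:
                names.append(out.protein_id)
        return names

    def protein_ids(self) -> list[str]:
        """Accessions: standard first, then named proteins, then filler."""
        names = self._named_proteins()
        filler = [f"P{i:04d}" for i in range(1, self.n_proteins - len(names) + 1)]
        return names + filler


def config_for_scale(n_proteins: int, **kwargs) -> GeneratorConfig:
    """Default-flavoured config scaled down to a smaller protein panel.

    Keeps the default planted-effect and baseline-outlier structure but
    trims both lists so the named proteins fit within ``n_proteins``
    (roughly preserving the default proportions: ~30% effect proteins,
    ~5% outliers). Extra keyword arguments override config fields.
    """
    if n_proteins >= 172:
        return GeneratorConfig(n_proteins=n_proteins, **kwargs)
    n_out = min(9, n_proteins // 20)
    outliers = tuple(default_baseline_outliers()[:n_out])
    budget = n_proteins - 1 - n_out  # minus standard protein
    effects, seen = [], set()
    for eff in default_effects():
        if eff.protein_id not in seen and len(seen) >= max(0, min(
                budget, int(0.3 * n_proteins))):
            continue
        seen.add(eff.protein_id)
        effects.append(eff)
    return GeneratorConfig(n_proteins=n_proteins, effects=tuple(effects),
                           baseline_outliers=outliers, **kwargs)


@dataclass(frozen=True)
class Study:
    """A generated study: peptide table, design, clinical endpoints, truth."""

    peptides: pd.DataFrame
    design: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _build_design(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for s in range(1, config.n_subjects + 1):
        subject = f"S{s:02d}"
        ff_leg = "left" if s % 2 else "right"
        for arm in ARMS:
            leg = ff_leg if arm == "lotion_ff" else ("right" if ff_leg == "left" else "left")
            for tp in TIMEPOINTS:
                rows.append((f"{subject}_{arm}_{tp}", subject, arm, tp, leg))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "arm",
                                       "timepoint", "leg"])


def _generate_clinical(config: GeneratorConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Linear improvement model with subject random intercepts."""
    days = (0, 7, 14)
    score_slope = {"lotion": 0.05, "lotion_ff": 0.09}       # score units/day
    cond_slope = {"lotion": 1.5, "lotion_ff": 3.0}          # instrument units/day
    rows = []
    for s in range(1, config.n_subjects + 1):
        subject = f"S{s:02d}"
        score0 = 3.2 + rng.normal(0, 0.15)
        cond0 = 80.0 + rng.normal(0, 10.0)
        for arm in ARMS:
            for day in days:
                raw = score0 - score_slope[arm] * day + rng.normal(0, 0.1)
                score = float(np.clip(np.round(raw * 2) / 2, 0.0, 4.0))
                rows.append((subject, arm, day, "observer_score", score))
                cond = cond0 + cond_slope[arm] * day + rng.normal(0, 2.0)
                rows.append((subject, arm, day, "conductance", float(cond)))
    # immunofluorescence: a small biopsy subset at day 5, film arm brighter
    for s in range(1, min(3, config.n_subjects) + 1):
        subject = f"S{s:02d}"
        base = rng.normal(0, 10.0)
        rows.append((subject, "lotion", 5, "if_intensity",
                     float(100.0 + base + rng.normal(0, 15.0))))
        rows.append((subject, "lotion_ff", 5, "if_intensity",
                     float(160.0 + base + rng.normal(0, 15.0))))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "day",
                                       "endpoint", "value"])


def generate_study(config: GeneratorConfig) -> Study:
    """Generate a complete synthetic study, deterministic given the seed.

    Peptide intensity of peptide j of protein p in sample i is
    ``proportion_pj * 10^(abundance_p + scale_i + effect + offset + noise)``
    where the planted effect applies in its arm at day 14 and the baseline
    outlier offset applies in the film arm at both timepoints (a persistent
    leg difference). Sub-streams of the seeded RNG are drawn in a fixed
    order, so identical configs give byte-identical outputs.
    """
    config.validate()
    proteins = config.protein_ids()
    ss = np.random.SeedSequence(config.seed)
    rng_abund, rng_pep, rng_scale, rng_noise, rng_miss, rng_clin = (
        np.random.default_rng(child) for child in ss.spawn(6))

    n_prot = config.n_proteins
    design = _build_design(config)
    samples = design["sample_id"].tolist()
    n_samp = len(samples)

    abund = rng_abund.normal(config.base_abundance_mean,
                             config.base_abundance_sd, n_prot)
    abund[0] = config.base_abundance_mean + config.standard_protein_boost

    pep_counts = rng_pep.integers(config.peptides_min,
                                  config.peptides_max + 1, n_prot)
    proportions = [rng_pep.dirichlet(np.ones(k)) for k in pep_counts]

    scale = rng_scale.normal(0.0, config.sample_scale_sd, n_samp)
    noise = rng_noise.normal(0.0, config.noise_sd, (n_prot, n_samp))

    prot_pos = {p: i for i, p in enumerate(proteins)}
    log_sig = abund[:, None] + scale[None, :] + noise
    arm_of = design["arm"].to_numpy()
    tp_of = design["timepoint"].to_numpy()
    for eff in config.effects:
        cols = (arm_of == eff.arm) & (tp_of == "day14")
        log_sig[prot_pos[eff.protein_id], cols] += eff.delta_pai
    for out in config.baseline_outliers:
        cols = arm_of == "lotion_ff"
        log_sig[prot_pos[out.protein_id], cols] += out.delta_pai

    prot_sig = np.power(10.0, log_sig)

    # expand to peptide level
    prot_idx = np.repeat(np.arange(n_prot), pep_counts)
    props = np.concatenate(proportions)
    pep_ids = np.concatenate(
        [[f"{proteins[p]}_pep{j + 1}" for j in range(pep_counts[p])]
         for p in range(n_prot)])
    pep_matrix = props[:, None] * prot_sig[prot_idx, :]

    n_pep = pep_matrix.shape[0]
    if config.missing_rate > 0:
        keep = rng_miss.random((n_pep, n_samp)) >= config.missing_rate
    else:
        keep = np.ones((n_pep, n_samp), dtype=bool)

    rows_keep = keep.ravel()
    peptides = pd.DataFrame({
        "peptide_id": np.repeat(pep_ids, n_samp)[rows_keep],
        "protein_id": np.repeat(np.asarray(proteins)[prot_idx], n_samp)[rows_keep],
        "sample_id": np.tile(np.asarray(samples), n_pep)[rows_keep],
        "intensity": pep_matrix.ravel()[rows_keep],
    })

    truth_rows = [("effect", e.protein_id, e.arm, e.delta_pai)
                  for e in config.effects]
    truth_rows += [("baseline_outlier", o.protein_id, "lotion_ff", o.delta_pai)
                   for o in config.baseline_outliers]
    truth = pd.DataFrame(truth_rows, columns=["kind", "protein_id", "arm",
                                              "delta_pai"])
    clinical = _generate_clinical(config, rng_clin)
    return Study(peptides=peptides, design=design, clinical=clinical,
                 truth=truth, config=config)


def generate_null_study(config: GeneratorConfig) -> Study:
    """Generate a study with no planted effects or baseline outliers."""
    null_config = replace(config, effects=(), baseline_outliers=())
    return generate_study(null_config)


def load_generator_config(path: str | os.PathLike) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML file mirroring its field names.

    ``effects`` entries are mappings with ``protein_id, arm, delta_pai``;
    ``baseline_outliers`` entries have ``protein_id, delta_pai``. Omitted
    fields keep their defaults; unknown fields are rejected.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of config fields")
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    if "effects" in raw:
        raw["effects"] = tuple(
            Effect(e["protein_id"], e["arm"], float(e["delta_pai"]))
            for e in raw["effects"])
    if "baseline_outliers" in raw:
        raw["baseline_outliers"] = tuple(
            BaselineOutlier(o["protein_id"], float(o["delta_pai"]))
            for o in raw["baseline_outliers"])
    config = GeneratorConfig(**raw)
    config.validate()
    return config


FIXTURE_FILES = ("peptides.tsv", "design.tsv", "clinical.tsv", "truth.tsv")


def write_fixture(study: Study, directory: str | os.PathLike) -> list[str]:
    """Write a study as the TSV file set the pipeline readers consume."""
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"fixture directory does not exist: {directory}")
    tables = {"peptides.tsv": study.peptides, "design.tsv": study.design,
              "clinical.tsv": study.clinical, "truth.tsv": study.truth}
    paths = []
    for name, table in tables.items():
        path = os.path.join(directory, name)
        table.to_csv(path, sep="\t", index=False, na_rep="NA",
                     lineterminator="\n")
        paths.append(path)
    return paths
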
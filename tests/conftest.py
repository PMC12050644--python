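"""Shared fixtures: small ground-truthed synthetic studies."""

import numpy as np
import pandas as pd
import pytest

from scproteome import GeneratorConfig, generate_study
from scproteome.synthetic import Effect, BaselineOutlier


@pytest.fixture
def make_config():
    """Factory for small generator configs with quiet defaults."""

    def _make(**kwargs):
        defaults = dict(n_subjects=4, n_proteins=12, noise_sd=0.0,
                        sample_scale_sd=0.0, missing_rate=0.0,
                        effects=(), baseline_outliers=(), seed=11)
        defaults.update(kwargs)
        return GeneratorConfig(**defaults)

    return _make


@pytest.fixture
def noiseless_effect_study(make_config):
    """Zero-noise study with one planted film-arm effect and one outlier."""
    config = make_config(
        effects=(Effect("SBSN", "lotion_ff", float(np.log10(1.9))),),
        baseline_outliers=(BaselineOutlier("HBB", float(np.log10(3.8))),),
    )
    return generate_study(config)


@pytest.fixture
def small_peptides():
    """Hand-written peptide table with known sums."""
    return pd.DataFrame({
        "peptide_id": ["p1", "p2", "p3", "p1", "p2"],
        "protein_id": ["P1", "P1", "P2", "P1", "P1"],
        "sample_id": ["S", "S", "S", "T", "T"],
        "intensity": [100.0, 50.0, 30.0, 40.0, 60.0],
    })
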
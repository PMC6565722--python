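"""End-to-end study runners: simulate a cohort, validate, calibrate, test.

These wrap the full pipeline the way the command-line workflow composes it —
synthetic cohort → QC → leave-one-subject-out validation → stratified
statistics — behind a single seed, and provide the parametric power
calculations used to size the study arms.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import model as mdl
from . import pipeline as pl
from . import synth
from .config import PipelineConfig


def run_main_study(seed: int, generator: synth.GeneratorConfig | None = None,
                   config: PipelineConfig | None = None) -> dict:
    """Default 60-subject × 2-measurement cohort through simulate → LOSO."""
    gcfg = generator or synth.GeneratorConfig(seed=seed)
    gcfg = replace(gcfg, seed=seed)
    cfg = config or PipelineConfig(seed=seed)
    cfg = replace(cfg, seed=seed)
    ds = synth.generate_cohort(gcfg)
    accepted, rejected = pl.process_dataset(ds.records, ds.biometrics(), ds.references(), cfg)
    loso = mdl.loso_validate(accepted, cfg)
    return {
        "dataset": ds,
        "accepted": accepted,
        "rejected": rejected,
        "loso": loso,
        "config": cfg,
        "generator": gcfg,
    }


def run_calibration_study(seed: int, n_prior: int = 3,
                          config: PipelineConfig | None = None) -> dict:
    """Repeated-measurement arm: LOSO, then per-subject median-error calibration.

    The first ``n_prior`` measurements of each subject form the calibration
    factor; the remaining ones are the held-out comparisons.
    """
    out = run_main_study(seed, generator=synth.calibration_study_config(seed), config=config)
    out["calib"] = mdl.calibrate_loso_errors(out["loso"], n_prior=n_prior)
    return out


def two_sample_power(mean1: float, sd1: float, n1: int,
                     mean2: float, sd2: float, n2: int,
                     alpha: float = 0.05, n_rep: int = 400, seed: int = 0) -> float:
    """Simulated power of the two-sample t-test at the observed group statistics."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        a = rng.normal(mean1, sd1, n1)
        b = rng.normal(mean2, sd2, n2)
        if stats.ttest_ind(a, b).pvalue < alpha:
            hits += 1
    return hits / n_rep


def paired_power(mean_d: float, sd_d: float, n: int,
                 alpha: float = 0.05, n_rep: int = 400, seed: int = 0) -> float:
    """Simulated power of the one-sided paired t-test at the observed difference."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        d = rng.normal(mean_d, sd_d, n)
        if stats.ttest_1samp(d, 0.0, alternative="greater").pvalue < alpha:
            hits += 1
    return hits / n_rep


def prediction_table_bytes(loso: pd.DataFrame) -> bytes:
    """Canonical byte representation of a prediction table (for hashing)."""
    cols = ["measurement_id", "subject_id", "test_sbp", "test_dbp", "ref_sbp", "ref_dbp"]
    return loso[cols].to_csv(index=False, float_format="%.10g").encode()
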
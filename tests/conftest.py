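import numpy as np
import pytest

from ppgbp import synth
from ppgbp.config import PipelineConfig
from ppgbp.signal import PPGRecord


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects × 2 measurements — enough for LOSO and QC exercises."""
    gcfg = synth.GeneratorConfig(n_subjects=8, measurements_per_subject=2, seed=7)
    return synth.generate_cohort(gcfg)


@pytest.fixture(scope="session")
def clean_measurement():
    """One noise-free, drift-free measurement with ground truth."""
    gcfg = synth.GeneratorConfig(
        n_subjects=1, measurements_per_subject=1, seed=11,
        noise_rel=0.0, noise_abs=0.0, drift_rel=0.0,
        notch_damping_prob=0.0,
    )
    subject = synth.sample_cohort(gcfg)[0]
    record, truth = synth.generate_measurement(subject, gcfg, 0)
    return subject, record, truth, gcfg


def pulse_train(period_s=0.8, fs=50.0, duration_s=60.0, drift_per_beat=0.0):
    """Asymmetric sawtooth-like pulse train with a known period (foot oracle)."""
    t = np.arange(int(duration_s * fs)) / fs
    phase = (t % period_s) / period_s
    # fast rise over 15 % of the cycle, slow decay after
    wave = np.where(phase < 0.15, phase / 0.15, np.exp(-(phase - 0.15) / 0.3))
    x = 100.0 + 10.0 * wave
    if drift_per_beat:
        x = x + drift_per_beat * 10.0 * t / period_s
    return PPGRecord(samples=x, fs=fs, measurement_id="train", subject_id="T")


@pytest.fixture
def train_record():
    return pulse_train()
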
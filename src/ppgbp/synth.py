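"""Synthetic 50 Hz PPG cohort with a known latent blood pressure.

The generator emulates what the estimation pipeline consumes, nothing more:
pulsatile finger-PPG in raw device counts with a foot, a systolic peak, a
dicrotic notch, plausible SDPTG a–e waves, baseline drift, additive device
noise, beat-to-beat period variability, and a monotone latent mapping from
(blood pressure, age) to waveform morphology.

Waveform family — per beat of period T (seconds, t = 0 at the nominal onset):

    w(t) = G2(t; mu1, s_up, s_dn)                      systolic lobe (skewed)
         + A2 * exp(-(t - mu2)^2 / (2 s2^2))           diastolic lobe
         + D * sigmoid((t - mu1)/w_g) * exp(-(t - mu1)/tau)   diastolic runoff

where G2 is a two-sided Gaussian (width s_up before the peak, s_dn after).
The valley between the lobes is the dicrotic notch.

Morphology coupling (the signal the model must learn), with SBP*/DBP* the
per-measurement effective pressures (true BP plus a per-subject bias and a
per-measurement perturbation — together the irreducible error floor):

    peak-to-notch gap  : mu2 - mu1 = 0.34 - 0.0013 (SBP* - 90)   [s]
    downstroke skew    : s_dn/s_up = 1.65 - 0.0055 (SBP* - 120) - 0.002 (age - 50)
    diastolic amplitude: A2 = 0.33 + 0.004 (DBP* - 70)
    diastolic width    : s2/T = 0.13 - 0.00035 (SBP* - 90)

(the peak-to-notch gap additionally scales with the square root of the
cycle length, Bazett-like systolic timing), so the stiff index rises and
b/a grows more negative as pressure rises.  Low-perfusion subjects
(PI < 0.01, block-randomized across the SBP-sorted cohort so the perfusion
arms carry comparable BP distributions) read low: their morphology SBP is
shifted down (default 22 mmHg, floored at 88 mmHg), and the absolute
component of the device noise weighs relatively more in their weaker
pulses — both degrade low-PI accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import PPGRecord


@dataclass
class MorphologyCoupling:
    """Linear-in-parameters morphology shifts; defaults give monotone, detectable
    couplings across the 90–200 mmHg SBP range at 50 Hz."""

    sig_up_frac: float = 0.06  # systolic upstroke width / T
    mu1_frac: float = 0.20  # systolic peak position / T
    gap_base_s: float = 0.34
    gap_slope_s_per_mmhg: float = 0.0013
    gap_bounds_s: tuple[float, float] = (0.19, 0.40)
    skew_base: float = 1.65
    skew_slope_sbp: float = 0.0055
    skew_slope_age: float = 0.002
    skew_bounds: tuple[float, float] = (1.10, 1.80)
    a2_base: float = 0.33
    a2_slope_dbp: float = 0.004
    a2_bounds: tuple[float, float] = (0.22, 0.50)
    sig2_base_frac: float = 0.13
    sig2_slope: float = 0.00035
    sig2_bounds: tuple[float, float] = (0.085, 0.135)
    decay_amp: float = 0.15
    decay_tau_frac: float = 0.35


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort."""

    n_subjects: int = 60
    measurements_per_subject: int = 2
    duration_s: float = 60.0
    fs: float = 50.0
    seed: int = 0

    dc_level: float = 2000.0  # device counts
    noise_rel: float = 0.005  # white-noise sd as a fraction of AC amplitude
    noise_abs: float = 0.15  # absolute white-noise floor, counts
    drift_rel: float = 0.05  # baseline drift amplitude as a fraction of AC
    drift_freq_hz: float = 0.04
    hr_jitter: float = 0.02  # beat-period jitter sd (fractional)

    # irreducible error floor: subject bias + per-measurement perturbation
    sigma_subject_sbp: float = 4.0
    sigma_meas_sbp: float = 3.0
    sigma_subject_dbp: float = 3.0
    sigma_meas_dbp: float = 2.0

    # perfusion: low-PI status is block-randomized across the SBP-sorted
    # cohort so the two perfusion arms have comparable BP distributions
    # (the between-arm comparison is then not confounded with BP level)
    low_pi_fraction: float = 0.2
    pi_low_median: float = 0.007
    pi_high_median: float = 0.022
    pi_log_sd: float = 0.5
    pi_meas_jitter: float = 0.05  # lognormal sd of per-measurement PI wobble
    low_pi_morph_bias_mmhg: float = 22.0

    # older-arm dicrotic-notch damping (exercises the notchless path)
    notch_damping_prob: float = 0.1
    notch_damping_a2: float = 0.7
    notch_damping_sig2: float = 1.3

    young_fraction: float = 0.5
    coupling: MorphologyCoupling = field(default_factory=MorphologyCoupling)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for name in ("n_subjects", "measurements_per_subject", "duration_s", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    height_cm: float
    weight_kg: float
    bmi: float
    true_sbp: float
    true_dbp: float
    pi_level: float
    hr_mean: float
    sbp_bias: float = 0.0  # per-subject irreducible bias (calibration target)
    dbp_bias: float = 0.0
    notch_damped: bool = False


def _trunc_normal(rng, mean, sd, lo, hi):
    """Truncated-normal draw by rejection (no probability mass piles on the bounds)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def sample_cohort(cfg: GeneratorConfig) -> list[SubjectProfile]:
    """Draw subject biometrics and latent BP.

    Marginals emulate a community + in-hospital adult cohort: young arm age
    36.0 ± 8.4 y with SBP 118.7 ± 17.0 mmHg, older arm 69.3 ± 11.6 y with
    130.5 ± 18.6 mmHg; height ≈ 163 ± 8 cm, BMI ≈ 24 ± 4 kg/m².
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC00]))
    subjects = []
    n_young = int(round(cfg.young_fraction * cfg.n_subjects))
    for i in range(cfg.n_subjects):
        young = i < n_young
        if young:
            age = float(_trunc_normal(rng, 36.0, 8.4, 18.0, 50.0))
            height = float(_trunc_normal(rng, 166.8, 8.2, 145.0, 200.0))
            bmi = float(_trunc_normal(rng, 24.7, 4.2, 16.0, 40.0))
            sbp = float(_trunc_normal(rng, 118.7, 17.0, 90.0, 200.0))
            pp = float(_trunc_normal(rng, 42.5, 9.0, 20.0, 90.0))
        else:
            age = float(_trunc_normal(rng, 69.3, 11.6, 50.5, 95.0))
            height = float(_trunc_normal(rng, 161.0, 7.8, 140.0, 195.0))
            bmi = float(_trunc_normal(rng, 24.1, 3.4, 16.0, 40.0))
            sbp = float(_trunc_normal(rng, 130.5, 18.6, 90.0, 200.0))
            pp = float(_trunc_normal(rng, 58.9, 11.0, 25.0, 100.0))
        dbp = float(np.clip(sbp - pp, 40.0, sbp - 15.0))
        weight = bmi * (height / 100.0) ** 2
        damped = (not young) and (rng.random() < cfg.notch_damping_prob)
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i:04d}",
                age=age,
                height_cm=height,
                weight_kg=weight,
                bmi=bmi,
                true_sbp=sbp,
                true_dbp=dbp,
                pi_level=float("nan"),
                hr_mean=float(_trunc_normal(rng, 72.0, 8.0, 50.0, 100.0)),
                sbp_bias=float(rng.normal(0.0, cfg.sigma_subject_sbp)),
                dbp_bias=float(rng.normal(0.0, cfg.sigma_subject_dbp)),
                notch_damped=damped,
            )
        )
    _assign_perfusion(subjects, cfg, rng)
    return subjects


def _assign_perfusion(subjects: list[SubjectProfile], cfg: GeneratorConfig, rng) -> None:
    """Block-randomized perfusion arms, balanced over the SBP distribution.

    Subjects are SBP-rank-ordered and partitioned into blocks; within each
    block the prescribed fraction is assigned to the low-perfusion arm, so
    the low- and high-PI groups carry comparable BP distributions.  PI levels
    are drawn per arm with a margin around the 0.01 threshold (the arms are
    distinct perfusion states, not a knife-edge split).
    """
    order = np.argsort([s.true_sbp for s in subjects], kind="stable")
    block = max(1, int(round(1.0 / max(cfg.low_pi_fraction, 1e-9))))
    low_idx = set()
    for start in range(0, len(order), block):
        members = order[start : start + block]
        if len(members) == block:
            low_idx.add(int(rng.choice(members)))
    for i, s in enumerate(subjects):
        if i in low_idx:
            pi = np.exp(rng.normal(np.log(cfg.pi_low_median), 0.25))
            s.pi_level = float(np.clip(pi, 0.003, 0.0095))
        else:
            pi = np.exp(rng.normal(np.log(cfg.pi_high_median), cfg.pi_log_sd))
            s.pi_level = float(np.clip(pi, 0.0105, 0.08))


def _morph_params(
    morph_sbp: float,
    morph_dbp: float,
    age: float,
    cfg: GeneratorConfig,
    damped: bool,
    period_s: float = 0.83,
) -> dict:
    c = cfg.coupling
    skew = np.clip(
        c.skew_base - c.skew_slope_sbp * (morph_sbp - 120.0) - c.skew_slope_age * (age - 50.0),
        *c.skew_bounds,
    )
    gap = np.clip(c.gap_base_s - c.gap_slope_s_per_mmhg * (morph_sbp - 90.0), *c.gap_bounds_s)
    # systolic timing scales with cycle length (~sqrt(T), Bazett-like), which
    # also keeps the two-lobe valley resolvable at slow heart rates
    gap = float(np.clip(gap * np.sqrt(period_s / 0.83), 0.16, 0.45))
    a2 = np.clip(c.a2_base + c.a2_slope_dbp * (morph_dbp - 70.0), *c.a2_bounds)
    sig2 = np.clip(c.sig2_base_frac - c.sig2_slope * (morph_sbp - 90.0), *c.sig2_bounds)
    if damped:
        a2 *= cfg.notch_damping_a2
        sig2 *= cfg.notch_damping_sig2
    return dict(skew=float(skew), gap_s=gap, a2=float(a2), sig2_frac=float(sig2))


def _notch_depth(T: float, morph: dict, cfg: GeneratorConfig) -> float:
    """Rebound height of the dicrotic wave above the valley (unit-peak scale)."""
    dense_fs = 1000.0
    t = np.arange(int(T * dense_fs)) / dense_fs
    w = beat_waveform(t, T, morph, cfg)
    pk = int(np.argmax(w))
    d = np.diff(w)
    notch = None
    for i in range(pk + 1, len(w) - 1):
        if d[i - 1] < 0 <= d[i]:
            notch = i
            break
    if notch is None:
        return 0.0
    rebound = float(np.max(w[notch:]) - w[notch])
    return rebound


def _ensure_notch(T: float, morph: dict, cfg: GeneratorConfig, min_depth: float = 0.04) -> dict:
    """Guarantee a resolvable two-lobe valley at this period.

    The valley between the lobes disappears (or becomes too shallow to detect
    at 50 Hz under noise) when the systolic downstroke is too wide relative
    to the lobe gap — slow heart rates at low pressure; the downstroke skew
    is reduced until the dicrotic rebound reaches ``min_depth`` of the
    systolic peak.
    """
    morph = dict(morph)
    while morph["skew"] > cfg.coupling.skew_bounds[0]:
        if _notch_depth(T, morph, cfg) >= min_depth:
            break
        morph["skew"] = max(cfg.coupling.skew_bounds[0], morph["skew"] - 0.05)
    return morph


def beat_waveform(t: np.ndarray, T: float, morph: dict, cfg: GeneratorConfig) -> np.ndarray:
    """Evaluate the (unit-scale) beat waveform at times ``t`` since beat onset."""
    c = cfg.coupling
    mu1 = c.mu1_frac * T
    s_up = c.sig_up_frac * T
    s_dn = morph["skew"] * s_up
    mu2 = mu1 + morph["gap_s"]
    s2 = morph["sig2_frac"] * T
    w = np.where(
        t < mu1,
        np.exp(-0.5 * ((t - mu1) / s_up) ** 2),
        np.exp(-0.5 * ((t - mu1) / s_dn) ** 2),
    )
    w = w + morph["a2"] * np.exp(-0.5 * ((t - mu2) / s2) ** 2)
    gate = 1.0 / (1.0 + np.exp(-(t - mu1) / (0.02 * T)))
    w = w + c.decay_amp * gate * np.exp(-(t - mu1) / (c.decay_tau_frac * T))
    return w


def generate_beat_waveform(
    profile: SubjectProfile, cfg: GeneratorConfig, *, morph_sbp=None, morph_dbp=None
) -> tuple[np.ndarray, dict]:
    """One clean cycle sampled at ``cfg.fs`` plus its ground-truth fiducials.

    Fiducial truth (peak, notch, SDPTG a–e) is read off a dense (1 kHz)
    evaluation of the analytic waveform and reported in fs-sample units.
    """
    msbp = profile.true_sbp if morph_sbp is None else morph_sbp
    mdbp = profile.true_dbp if morph_dbp is None else morph_dbp
    T = 60.0 / profile.hr_mean
    morph = _morph_params(msbp, mdbp, profile.age, cfg, profile.notch_damped, period_s=T)
    if not profile.notch_damped:
        morph = _ensure_notch(T, morph, cfg)
    n = int(round(T * cfg.fs))
    samples = beat_waveform(np.arange(n) / cfg.fs, T, morph, cfg)
    truth = _beat_truth(T, morph, cfg)
    return samples, truth


def _beat_truth(T: float, morph: dict, cfg: GeneratorConfig) -> dict:
    """Dense-grid fiducials of one isolated beat, in units of fs samples."""
    dense_fs = 1000.0
    t = np.arange(int(T * dense_fs)) / dense_fs
    w = beat_waveform(t, T, morph, cfg)
    pk = int(np.argmax(w))
    # notch: first local minimum after the peak
    d = np.diff(w)
    notch = None
    for i in range(pk + 1, len(w) - 1):
        if d[i - 1] < 0 <= d[i]:
            notch = i
            break
    d2 = np.gradient(np.gradient(w)) * dense_fs**2
    half = len(w) // 2
    a = int(np.argmax(d2[:half]))
    idx = [a]
    cur, want_min = a, True
    while len(idx) < 5:
        found = -1
        for i in range(cur + 1, len(d2) - 1):
            if want_min and d2[i] <= d2[i - 1] and d2[i] < d2[i + 1]:
                found = i
                break
            if not want_min and d2[i] >= d2[i - 1] and d2[i] > d2[i + 1]:
                found = i
                break
        if found < 0:
            break
        idx.append(found)
        cur, want_min = found, not want_min
    scale = cfg.fs / dense_fs
    out = {
        "period_s": T,
        "peak": pk * scale,
        "notch": None if notch is None else notch * scale,
        "morph": morph,
    }
    for name, j in zip("abcde", idx):
        out[f"sdptg_{name}"] = j * scale
    return out


def generate_measurement(
    profile: SubjectProfile,
    cfg: GeneratorConfig,
    measurement_index: int = 0,
) -> tuple[PPGRecord, dict]:
    """A full noisy measurement plus its ground truth.

    Ground truth carries: onset sample indices, per-beat fiducial truth
    (foot/peak/notch from the rendered clean signal), the effective morphology
    pressures, the reference BP, and the clean signal itself.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1, _stable_id(profile.subject_id), measurement_index])
    )
    msbp = profile.true_sbp + profile.sbp_bias + rng.normal(0, cfg.sigma_meas_sbp)
    mdbp = profile.true_dbp + profile.dbp_bias + rng.normal(0, cfg.sigma_meas_dbp)
    pi = profile.pi_level * float(np.exp(rng.normal(0, cfg.pi_meas_jitter)))
    # poor-perfusion distortion is a property of the subject's vasculature:
    # every measurement of a low-PI subject carries the same morphology shift
    # toward apparent lower pressure, floored at the physiological low edge
    # (a waveform cannot read below a perfused minimum)
    if profile.pi_level < 0.01:
        msbp = max(msbp - cfg.low_pi_morph_bias_mmhg, 88.0)
    T = 60.0 / profile.hr_mean
    morph = _morph_params(msbp, mdbp, profile.age, cfg, profile.notch_damped, period_s=T)
    if not profile.notch_damped:
        morph = _ensure_notch(T, morph, cfg)
    n_beats = int(np.ceil(cfg.duration_s / T)) + 2
    periods = T * (1.0 + rng.normal(0, cfg.hr_jitter, n_beats))
    onsets_t = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    n = int(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    clean = np.zeros(n)
    for t0, Tk in zip(onsets_t, periods):
        lo = max(0, int((t0 - 0.3 * Tk) * cfg.fs))
        hi = min(n, int(np.ceil((t0 + 3.0 * Tk) * cfg.fs)))
        if lo >= hi:
            continue
        tt = t[lo:hi] - t0
        m = tt >= 0
        clean[lo:hi][m] += beat_waveform(tt[m], Tk, morph, cfg)

    # scale so the measured PI (peak-to-trough over mean) matches the target
    dc = cfg.dc_level
    denom = np.ptp(clean) - pi * clean.mean()
    amp = pi * dc / denom
    ac = amp * np.ptp(clean)
    sig = dc + amp * clean
    sig = sig + cfg.drift_rel * ac * np.sin(
        2 * np.pi * cfg.drift_freq_hz * t + rng.uniform(0, 2 * np.pi)
    )
    noise_sd = cfg.noise_rel * ac + cfg.noise_abs
    sig = sig + rng.normal(0, noise_sd, n)

    onsets = np.round(onsets_t * cfg.fs).astype(int)
    onsets = onsets[onsets < n]
    fiducials = _measurement_fiducials(dc + amp * clean, onsets)
    record = PPGRecord(
        samples=sig,
        fs=cfg.fs,
        measurement_id=f"{profile.subject_id}-M{measurement_index:02d}",
        subject_id=profile.subject_id,
    )
    truth = {
        "onsets": onsets,
        "fiducials": fiducials,
        "morph_sbp": float(msbp),
        "morph_dbp": float(mdbp),
        "ref_sbp": profile.true_sbp,
        "ref_dbp": profile.true_dbp,
        "pi": float(pi),
        "noise_sd": float(noise_sd),
        "ac": float(ac),
        "clean": dc + amp * clean,
        "morph": morph,
    }
    return record, truth


def _measurement_fiducials(clean: np.ndarray, onsets: np.ndarray) -> list[dict]:
    """Foot/peak/notch truth per beat, from the rendered noise-free signal."""
    out = []
    for i in range(len(onsets) - 1):
        t0, t1 = onsets[i], onsets[i + 1]
        span = t1 - t0
        lo = max(0, t0 - span // 4)
        foot = lo + int(np.argmin(clean[lo : t0 + span // 4 + 1]))
        nxt_lo = max(0, t1 - span // 4)
        next_foot = nxt_lo + int(np.argmin(clean[nxt_lo : min(len(clean), t1 + span // 4 + 1)]))
        if next_foot <= foot + 2:
            continue
        seg = clean[foot : next_foot + 1]
        pk = int(np.argmax(seg[: max(2, int(0.6 * len(seg)))]))
        d = np.diff(seg)
        notch = None
        for j in range(pk + 1, len(seg) - 1):
            if d[j - 1] < 0 <= d[j]:
                notch = j
                break
        out.append({"foot": foot, "next_foot": next_foot, "peak": pk, "notch": notch})
    return out


def _stable_id(s: str) -> int:
    import zlib

    return zlib.crc32(s.encode()) % (2**31 - 1)


@dataclass
class SyntheticDataset:
    """Cohort + measurements + ground truth, ready for the pipeline."""

    subjects: list[SubjectProfile]
    records: list[PPGRecord]
    truths: dict  # measurement_id -> truth dict
    config: GeneratorConfig

    def biometrics(self) -> dict[str, dict]:
        return {
            s.subject_id: {
                "age": s.age,
                "height_cm": s.height_cm,
                "weight_kg": s.weight_kg,
                "bmi": s.bmi,
            }
            for s in self.subjects
        }

    def references(self) -> dict[str, dict]:
        return {
            mid: {
                "subject_id": t["subject_id"],
                "ref_sbp": t["ref_sbp"],
                "ref_dbp": t["ref_dbp"],
                "cuff_discrepancy_flag": 0,
            }
            for mid, t in self.truths.items()
        }

    def biometrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": k, **v} for k, v in sorted(self.biometrics().items())]
        )

    def references_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"measurement_id": k, **v} for k, v in sorted(self.references().items())]
        )


def generate_cohort(cfg: GeneratorConfig) -> SyntheticDataset:
    """Sample a cohort and render every measurement (deterministic per seed)."""
    subjects = sample_cohort(cfg)
    records, truths = [], {}
    for s in subjects:
        for m in range(cfg.measurements_per_subject):
            rec, truth = generate_measurement(s, cfg, m)
            truth["subject_id"] = s.subject_id
            records.append(rec)
            truths[rec.measurement_id] = truth
    return SyntheticDataset(subjects=subjects, records=records, truths=truths, config=cfg)


def calibration_study_config(seed: int = 0) -> GeneratorConfig:
    """Cohort preset for the personal-calibration study arm.

    Mirrors a month-long repeated-measurement follow-up: fewer subjects, five
    measurements each, and a dominant per-subject bias (sd 8 mmHg) of the kind
    personal calibration is designed to remove.
    """
    return GeneratorConfig(
        n_subjects=30,
        measurements_per_subject=5,
        sigma_subject_sbp=8.0,
        sigma_subject_dbp=5.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

CORRUPT_MODES = ("spike", "dropout", "drift")


def corrupt(
    record: PPGRecord,
    truth: dict,
    mode: str,
    *,
    fraction: float = 0.1,
    seed: int = 0,
    rel_amp: float = 0.8,
    width_s: float = 0.04,
) -> tuple[PPGRecord, dict]:
    """Inject seeded artifacts into a fraction of beats; returns a manifest.

    Modes: ``spike`` adds a Gaussian transient (rel_amp × AC) at the systolic
    peak of the chosen beats; ``dropout`` flattens the chosen beats to the
    local baseline; ``drift`` adds a linear baseline ramp over the whole
    record (rel_amp × AC per beat period; manifest lists no beats).
    """
    if mode not in CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {CORRUPT_MODES}")
    rng = np.random.default_rng(seed)
    x = record.samples.copy()
    fid = truth["fiducials"]
    ac = truth["ac"]
    n = len(x)
    t = np.arange(n) / record.fs

    if mode == "drift":
        # rel_amp × AC of drift per beat period, linear over the record
        x = record.samples + rel_amp * ac * (t / t[-1]) * len(fid)
        manifest = {"mode": mode, "beats": []}
        return PPGRecord(x, record.fs, record.measurement_id, record.subject_id), manifest

    k = max(1, int(round(fraction * len(fid))))
    chosen = sorted(rng.choice(len(fid), size=k, replace=False).tolist())
    for bi in chosen:
        f = fid[bi]
        if mode == "spike":
            center = (f["foot"] + f["peak"]) / record.fs
            x += rel_amp * ac * np.exp(-0.5 * ((t - center) / width_s) ** 2)
        else:  # dropout
            lo, hi = f["foot"], f["next_foot"]
            x[lo:hi] = np.median(record.samples[lo:hi])
    manifest = {"mode": mode, "beats": chosen}
    return PPGRecord(x, record.fs, record.measurement_id, record.subject_id), manifest
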
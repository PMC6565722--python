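"""Beat-level hemodynamic features and measurement accept/reject rules.

Per beat: perfusion index (AC/DC), stiff index (height / systolic-peak-to-
dicrotic-notch lapse), heart rate, and the two areas under the waveform split
at the dicrotic notch.  A beat is abnormal when any of these five features is
a robust outlier (median ± 3 × scaled MAD within the measurement) or when a
fiducial flag is set.  A separate SDPTG noise test fails a beat when the
standard deviation of its second derivative between the dicrotic notch and
the next foot exceeds 15 % of the b-wave magnitude.

Measurement-level rules: reject when the abnormal fraction exceeds 20 %
(strict), or when fewer than 30 good-quality cycles survive all filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .exceptions import BaselineInvalidError
from .signal import SDPTG, Beat, FLAG_NOTCHLESS

REASON_ABNORMAL = "abnormal>20%"
REASON_FEW_CYCLES = "fewer than 30 cycles"

_OUTLIER_FEATURES = ("pi", "si", "hr", "area1", "area2")


@dataclass
class BeatQuality:
    """Per-beat hemodynamic features plus quality flags."""

    beat_index: int
    pi: float
    si: float | None  # m/s; None for notchless beats
    hr: float
    area1: float
    area2: float
    abnormal: bool = False
    noise_fail: bool = False
    flags: set = field(default_factory=set)


@dataclass
class MeasurementQC:
    """Measurement-level quality verdict."""

    n_beats: int
    n_abnormal: int
    abnormal_fraction: float
    accepted: bool
    reject_reasons: list = field(default_factory=list)
    mean_pi: float = float("nan")
    n_good: int = 0


def perfusion_index(beat: Beat) -> float:
    """AC/DC of the beat: peak-to-trough amplitude over the mean level.

    The mean (DC) must be positive — raw device counts are assumed.
    """
    dc = float(np.mean(beat.samples))
    if dc <= 0:
        raise BaselineInvalidError(f"baseline invalid: non-positive DC {dc}")
    return float(np.ptp(beat.samples)) / dc


def stiff_index(beat: Beat, height_cm: float) -> float | None:
    """Subject height (m) over the systolic-peak-to-dicrotic-notch lapse (s).

    Returns None for notchless beats (the lapse is undefined).
    """
    if not 100 <= height_cm <= 220:
        raise ValueError(f"height {height_cm} cm outside plausible range [100, 220]")
    if FLAG_NOTCHLESS in beat.flags or beat.notch_idx <= beat.peak_idx:
        beat.flags.add(FLAG_NOTCHLESS)
        return None
    lapse = (beat.notch_idx - beat.peak_idx) / beat.fs
    return (height_cm / 100.0) / lapse


def beat_heart_rate(beat: Beat) -> float:
    """Instantaneous heart rate in bpm from the beat duration."""
    if beat.duration_s <= 0:
        raise ValueError("beat duration must be positive")
    return 60.0 / beat.duration_s


def beat_areas(beat: Beat) -> tuple[float, float] | None:
    """Trapezoidal areas of (samples − beat minimum), split at the dicrotic notch.

    Units: sample-unit·s.  Returns None for notchless beats.
    """
    if FLAG_NOTCHLESS in beat.flags or beat.notch_idx <= 0:
        return None
    y = beat.samples - beat.samples.min()
    dx = 1.0 / beat.fs
    a1 = float(np.trapezoid(y[: beat.notch_idx + 1], dx=dx))
    a2 = float(np.trapezoid(y[beat.notch_idx :], dx=dx))
    return a1, a2


def flag_abnormal_beats(
    qualities: list[BeatQuality], config: PipelineConfig | None = None
) -> list[BeatQuality]:
    """Mark outlier beats: any feature outside median ± k × scaled MAD.

    The scaled MAD (scale 1.4826) is computed per feature across the
    measurement, ignoring undefined values.  Fiducial flags force abnormal.
    Mutates and returns the list.
    """
    cfg = config or PipelineConfig()
    if len(qualities) < 5:
        raise ValueError("at least 5 beats are required for outlier flagging")
    for name in _OUTLIER_FEATURES:
        vals = np.array(
            [getattr(q, name) if getattr(q, name) is not None else np.nan for q in qualities]
        )
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        med = float(np.median(vals[ok]))
        mad = cfg.mad_scale * float(np.median(np.abs(vals[ok] - med)))
        # scale floor: at 50 Hz several features are quantized (a handful of
        # discrete values per measurement), which can drive the MAD to zero
        # and flag every minority beat; deviations under the floor are
        # physiologically meaningless rather than artifactual
        scale = max(mad, cfg.outlier_rel_floor * abs(med))
        for q, v, is_ok in zip(qualities, vals, ok):
            if not is_ok:
                continue
            if abs(v - med) > cfg.outlier_mad_k * scale:
                q.abnormal = True
                q.flags.add(f"outlier-{name}")
    for q in qualities:
        if q.flags & {"peak-boundary", "notchless", "sdptg-incomplete", "sdptg-abnormal", "too-short"}:
            q.abnormal = True
    return qualities


def sdptg_noise_test(
    sdptg: SDPTG,
    notch_idx: int,
    next_foot_idx: int,
    config: PipelineConfig | None = None,
) -> bool | None:
    """Noise test on the SDPTG segment from the dicrotic notch to the next foot.

    Returns True when the beat PASSES (segment sd ≤ 15 % of |b|, strict
    "exceeds" semantics), False when it fails, None when not applicable
    (incomplete SDPTG or too-short segment).
    """
    cfg = config or PipelineConfig()
    if not sdptg.complete:
        return None
    seg = sdptg.samples[notch_idx : next_foot_idx + 1]
    if len(seg) < 3:
        return None
    sd = float(np.std(seg))  # population sd: the boundary case is exact
    thr = cfg.noise_fraction_of_b * abs(sdptg.b_amp)
    # strict "exceeds": equality passes; tolerance guards float round-off at
    # the exact boundary
    return not sd > thr + 1e-12 * max(sd, thr)


def qc_measurement(
    qualities: list[BeatQuality],
    n_selected_good: int,
    config: PipelineConfig | None = None,
) -> MeasurementQC:
    """Apply the measurement-level accept/reject rules."""
    cfg = config or PipelineConfig()
    if not qualities:
        raise ValueError("qualities must be nonempty")
    n = len(qualities)
    n_abn = sum(q.abnormal for q in qualities)
    frac = n_abn / n
    reasons = []
    if frac > cfg.max_abnormal_fraction:
        reasons.append(REASON_ABNORMAL)
    if n_selected_good < cfg.min_good_cycles:
        reasons.append(REASON_FEW_CYCLES)
    good_pi = [q.pi for q in qualities if not q.abnormal and not q.noise_fail]
    mean_pi = float(np.mean(good_pi)) if good_pi else float("nan")
    return MeasurementQC(
        n_beats=n,
        n_abnormal=n_abn,
        abnormal_fraction=frac,
        accepted=not reasons,
        reject_reasons=reasons,
        mean_pi=mean_pi,
        n_good=n_selected_good,
    )


def qc_report(rows: list[tuple[str, MeasurementQC]]) -> pd.DataFrame:
    """One row per measurement: id, beat counts, abnormal fraction, mean PI, verdict."""
    return pd.DataFrame(
        [
            {
                "measurement_id": mid,
                "n_beats": qc.n_beats,
                "n_abnormal": qc.n_abnormal,
                "abnormal_fraction": qc.abnormal_fraction,
                "n_good": qc.n_good,
                "mean_pi": qc.mean_pi,
                "accepted": qc.accepted,
                "reasons": ";".join(qc.reject_reasons),
            }
            for mid, qc in rows
        ]
    )
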
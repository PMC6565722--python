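"""Beat detection, fiducial points and the second-derivative waveform (SDPTG).

A raw finger-PPG record sampled at 50 Hz is segmented into foot-to-foot beats.
Within each beat the systolic peak and the dicrotic notch are located, and the
second time-derivative of a smoothed copy of the beat (the SDPTG) is computed.
The five early systolic waves of the SDPTG — a (initial positive), b (early
negative), c, d, e — are located as the alternating local extrema that follow
the global early-systolic maximum.

The pulse-detection strategy: band-pass the record (0.5–10 Hz, zero phase),
find the steepest upstrokes as first-derivative maxima, and take the local
minimum preceding each upstroke as the pulse foot.  Inter-foot intervals
outside the physiological range 0.3–2.0 s (30–200 bpm) invalidate both
bounding feet.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .exceptions import NoPulsatileActivityError

# beat-level flag codes
FLAG_PEAK_BOUNDARY = "peak-boundary"
FLAG_NOTCHLESS = "notchless"
FLAG_SDPTG_INCOMPLETE = "sdptg-incomplete"
FLAG_SDPTG_ABNORMAL = "sdptg-abnormal"
FLAG_TOO_SHORT = "too-short"


@dataclass
class PPGRecord:
    """A single raw PPG measurement (device counts at a fixed sampling rate)."""

    samples: np.ndarray
    fs: float = 50.0
    measurement_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def validate_for_processing(self) -> None:
        if len(self.samples) < self.fs * 10:
            raise ValueError(
                f"record too short: {len(self.samples)} samples < 10 s at {self.fs} Hz"
            )


@dataclass
class Beat:
    """One cardiac cycle, foot-to-foot, closed on both ends."""

    samples: np.ndarray
    fs: float
    start: int = 0  # index of the beat's first sample in the parent record
    foot_idx: int = 0
    peak_idx: int = -1
    notch_idx: int = -1
    flags: set = field(default_factory=set)

    @property
    def duration_s(self) -> float:
        # closed-boundary convention: n samples span (n-1)/fs seconds
        return (len(self.samples) - 1) / self.fs


@dataclass
class SDPTG:
    """Second derivative of a beat with its a–e wave locations."""

    samples: np.ndarray
    a_idx: int = -1
    b_idx: int = -1
    c_idx: int = -1
    d_idx: int = -1
    e_idx: int = -1
    flags: set = field(default_factory=set)

    @property
    def complete(self) -> bool:
        return FLAG_SDPTG_INCOMPLETE not in self.flags

    @property
    def a_amp(self) -> float:
        return float(self.samples[self.a_idx])

    @property
    def b_amp(self) -> float:
        return float(self.samples[self.b_idx])

    @property
    def c_amp(self) -> float:
        return float(self.samples[self.c_idx])

    @property
    def d_amp(self) -> float:
        return float(self.samples[self.d_idx])

    @property
    def e_amp(self) -> float:
        return float(self.samples[self.e_idx])


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_feet(record: PPGRecord, config: PipelineConfig | None = None) -> np.ndarray:
    """Locate pulse onsets (feet) as local minima preceding steep upstrokes.

    Returns strictly increasing sample indices.  Raises
    :class:`NoPulsatileActivityError` when fewer than two valid feet remain.
    """
    cfg = config or PipelineConfig()
    record.validate_for_processing()
    x = _bandpass(record.samples, record.fs, cfg.bandpass_hz)
    dx = np.gradient(x) * record.fs
    ref = np.percentile(dx, 98)
    if ref <= 0 or np.ptp(record.samples) == 0:
        raise NoPulsatileActivityError("no pulsatile activity")
    thr = cfg.upstroke_height_frac * ref
    min_dist = max(1, int(cfg.beat_duration_bounds_s[0] * record.fs))
    upstrokes, _ = sps.find_peaks(dx, height=thr, distance=min_dist)
    feet = []
    back = int(0.3 * record.fs)
    for u in upstrokes:
        lo = max(0, u - back)
        feet.append(lo + int(np.argmin(x[lo : u + 1])))
    feet = np.unique(np.asarray(feet, dtype=int))
    feet = _gate_intervals(feet, record.fs, cfg.beat_duration_bounds_s)
    if len(feet) < 2:
        raise NoPulsatileActivityError("no pulsatile activity: fewer than 2 feet")
    return feet


def _gate_intervals(feet: np.ndarray, fs: float, bounds: tuple[float, float]) -> np.ndarray:
    """Drop both bounding feet of any inter-foot interval outside ``bounds``."""
    if len(feet) < 2:
        return feet
    lo, hi = bounds
    ivals = np.diff(feet) / fs
    bad = (ivals < lo) | (ivals > hi)
    keep = np.ones(len(feet), dtype=bool)
    keep[:-1][bad] = False
    keep[1:][bad] = False
    return feet[keep]


def segment_beats(
    record: PPGRecord, feet: np.ndarray, config: PipelineConfig | None = None
) -> list[Beat]:
    """Cut the record into foot-to-foot beats and locate peak and notch in each."""
    cfg = config or PipelineConfig()
    beats: list[Beat] = []
    for i in range(len(feet) - 1):
        a, b = int(feet[i]), int(feet[i + 1])
        beat = Beat(samples=record.samples[a : b + 1].copy(), fs=record.fs, start=a)
        locate_systolic_peak(beat, cfg)
        locate_dicrotic_notch(beat, cfg)
        beats.append(beat)
    return beats


def locate_systolic_peak(beat: Beat, config: PipelineConfig | None = None) -> int:
    """Locate the systolic peak: global maximum in the first 60 % of the beat.

    A maximum sitting on the search-window boundary marks the beat unusable.
    """
    cfg = config or PipelineConfig()
    n = len(beat.samples)
    w = max(2, int(np.ceil(cfg.peak_search_frac * n)))
    idx = int(np.argmax(beat.samples[:w]))
    if idx == 0 or idx == w - 1:
        beat.flags.add(FLAG_PEAK_BOUNDARY)
    beat.peak_idx = idx
    return idx


def locate_dicrotic_notch(beat: Beat, config: PipelineConfig | None = None) -> int:
    """Locate the dicrotic notch between the systolic peak and 90 % of the beat.

    Preference order: the first sufficiently prominent local minimum of the
    smoothed beat (the valley after systole that precedes the dicrotic wave;
    in the monotone diastolic descent, later minima can carry spuriously
    large prominence); failing that, an inflection (sign change of the
    smoothed second derivative).  If neither exists the beat is flagged
    "notchless" and the point of smallest second-derivative magnitude is
    recorded as a placeholder.
    """
    cfg = config or PipelineConfig()
    n = len(beat.samples)
    if beat.peak_idx < 0:
        locate_systolic_peak(beat, cfg)
    lo = beat.peak_idx + 1
    hi = max(lo + 1, int(cfg.notch_search_frac * n))
    smooth = _savgol(beat.samples, cfg.savgol_window)
    seg = smooth[lo:hi]
    if len(seg) < 3:
        beat.flags.add(FLAG_NOTCHLESS)
        beat.notch_idx = min(lo, n - 1)
        return beat.notch_idx
    amp = float(np.ptp(beat.samples))
    minima, _ = sps.find_peaks(-seg, prominence=cfg.notch_prominence_frac * amp)
    if len(minima) > 0:
        beat.notch_idx = lo + int(minima[0])
        return beat.notch_idx
    # shoulder fallback for damped notches: an interior local maximum of the
    # (still negative) first derivative — deceleration, re-acceleration,
    # deceleration.  Confined to mid-beat: wiggles near the foot belong to
    # the flat diastolic tail.  A pure decay flank or single arch has no such
    # point and is flagged notchless.
    hi = min(hi, max(lo + 2, int(0.75 * n)))
    d1 = _smooth_first_derivative(beat.samples, beat.fs, cfg.savgol_window)
    d1seg = d1[lo:hi]
    for i in range(1, len(d1seg) - 1):
        if d1seg[i] < 0 and d1seg[i] >= d1seg[i - 1] and d1seg[i] > d1seg[i + 1]:
            beat.notch_idx = lo + i
            return beat.notch_idx
    beat.flags.add(FLAG_NOTCHLESS)
    d2 = _smooth_second_derivative(beat.samples, beat.fs, cfg.savgol_window)
    beat.notch_idx = lo + int(np.argmin(np.abs(d2[lo:hi])))
    return beat.notch_idx


def _savgol(x: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(x) if len(x) % 2 == 1 else len(x) - 1)
    if window < 3:
        return x
    return sps.savgol_filter(x, window, 2)


def _smooth_first_derivative(x: np.ndarray, fs: float, window: int) -> np.ndarray:
    return np.gradient(_savgol(x, window)) * fs


def _smooth_second_derivative(x: np.ndarray, fs: float, window: int) -> np.ndarray:
    d1 = _smooth_first_derivative(x, fs, window)
    return np.gradient(_savgol(d1, window)) * fs


def compute_sdptg(beat: Beat, config: PipelineConfig | None = None) -> SDPTG:
    """Second derivative of the (smoothed) beat with the a–e waves located.

    Five-point quadratic (Savitzky–Golay) smoothing is applied before each
    differentiation; raw double differencing at 50 Hz is noise dominated.
    """
    cfg = config or PipelineConfig()
    n = len(beat.samples)
    if n < 8:
        beat.flags.add(FLAG_TOO_SHORT)
        s = SDPTG(samples=np.zeros(n))
        s.flags.add(FLAG_SDPTG_INCOMPLETE)
        return s
    d2 = _smooth_second_derivative(beat.samples, beat.fs, cfg.savgol_window)
    sd = SDPTG(samples=d2)
    # significance floor: a (near-)linear beat has zero second derivative up
    # to float noise; locating "waves" in that noise is meaningless
    if np.ptp(d2) <= 1e-9 * (np.ptp(beat.samples) + 1.0) * beat.fs**2:
        sd.flags.add(FLAG_SDPTG_INCOMPLETE)
        beat.flags |= sd.flags
        return sd
    _locate_abcde(sd)
    if sd.complete and (sd.a_amp <= 0 or sd.b_amp >= 0):
        sd.flags.add(FLAG_SDPTG_ABNORMAL)
    beat.flags |= sd.flags
    return sd


def _locate_abcde(sd: SDPTG) -> None:
    """a = global max in the first half; b–e = following alternating extrema."""
    d2 = sd.samples
    n = len(d2)
    half = max(3, n // 2)
    a = int(np.argmax(d2[1:half])) + 1
    idx = [a]
    cur, want_min = a, True
    while len(idx) < 5:
        found = -1
        for i in range(cur + 1, n - 1):
            left, mid, right = d2[i - 1], d2[i], d2[i + 1]
            if want_min and mid <= left and mid < right:
                found = i
                break
            if not want_min and mid >= left and mid > right:
                found = i
                break
        if found < 0:
            sd.flags.add(FLAG_SDPTG_INCOMPLETE)
            sd.a_idx = a
            return
        idx.append(found)
        cur, want_min = found, not want_min
    sd.a_idx, sd.b_idx, sd.c_idx, sd.d_idx, sd.e_idx = idx
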
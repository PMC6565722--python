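"""Pipeline configuration.

All defaults are the constants of the estimation method: the 20 % abnormal-beat
budget, the 15 %-of-b SDPTG noise budget, the 30-cycle minimum, 30 selected
beats, 32-point resampling, the 4 + 8 waveform-basis sizes, the ±0.5 mmHg
target perturbation, min leaf size 30, and the stratification cut points
(age 50 y, SBP 120/140 mmHg, PI 0.01).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # signal
    fs: float = 50.0
    bandpass_hz: tuple[float, float] = (0.5, 10.0)
    beat_duration_bounds_s: tuple[float, float] = (0.3, 2.0)
    upstroke_height_frac: float = 0.4
    peak_search_frac: float = 0.6
    notch_search_frac: float = 0.9
    notch_prominence_frac: float = 0.01
    savgol_window: int = 5

    # qc
    outlier_mad_k: float = 3.0
    mad_scale: float = 1.4826
    outlier_rel_floor: float = 0.05  # robust-scale floor as a fraction of |median|
    max_abnormal_fraction: float = 0.20
    noise_fraction_of_b: float = 0.15
    min_good_cycles: int = 30

    # features
    beats_selected: int = 30
    resample_points: int = 32
    n_ppg_components: int = 4
    n_sdptg_components: int = 8
    normalize: str = "minmax"  # "minmax" | "none"

    # model
    n_trees: int = 100
    min_leaf: int = 30
    max_features: float | None = 0.33  # random-subspace fraction per split
    target_perturbation_mmhg: float = 0.5
    aggregate_trim: float = 0.2  # trimmed-mean fraction for per-measurement aggregation

    # stratification
    age_cut_years: float = 50.0
    sbp_group_cuts_mmhg: tuple[float, float, float] = (90.0, 120.0, 140.0)
    pi_cut: float = 0.01

    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(names)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kw[k] = v
        return cls(**kw)
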
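"""Record-to-features orchestration.

`process_record` runs one raw PPG measurement through beat detection, fiducial
location, beat-level QC, the SDPTG noise test, the measurement accept/reject
rules and — when accepted — the 32-point resampling, median-template beat
selection and per-beat scalar feature computation.  The SVD shape coefficients
are *not* computed here: the shape bases are fitted per training set (and
refitted inside every leave-one-subject-out fold), so projection happens at
training/prediction time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features as ft
from . import qc as qcm
from . import signal as sig
from .config import PipelineConfig
from .exceptions import PPGError

# per-row scalar features kept alongside the shape streams
SCALAR_NAMES = ("HR", "b_a", "c_a", "d_a", "e_a", "SI")


@dataclass
class ProcessedMeasurement:
    """A QC-accepted measurement reduced to model-ready per-beat arrays."""

    measurement_id: str
    subject_id: str
    ppg_shapes: np.ndarray  # (k, 32) normalised PPG beats
    sdptg_shapes: np.ndarray  # (k, 32) normalised SDPTG beats
    scalars: np.ndarray  # (k, 6): HR, b/a, c/a, d/a, e/a, SI
    beat_indices: np.ndarray  # original beat ordinals of the selected beats
    bmi: float
    age: float
    height_cm: float
    ref_sbp: float
    ref_dbp: float
    mean_pi: float
    qc: qcm.MeasurementQC | None = None

    @property
    def n_beats(self) -> int:
        return self.ppg_shapes.shape[0]

    def feature_matrix(
        self, ppg_basis: ft.WaveformBasis, sdptg_basis: ft.WaveformBasis
    ) -> np.ndarray:
        """Project the shape streams and assemble the (k, 19) feature matrix."""
        rows = []
        for i in range(self.n_beats):
            p = ft.project_beat(self.ppg_shapes[i], ppg_basis)
            s = ft.project_beat(self.sdptg_shapes[i], sdptg_basis)
            hr, ba, ca, da, ea, si = self.scalars[i]
            rows.append(ft.assemble_features(p, s, hr, (ba, ca, da, ea), si, self.bmi))
        return np.vstack(rows)


@dataclass
class RejectedMeasurement:
    """A measurement that failed QC, with the reasons."""

    measurement_id: str
    subject_id: str
    qc: qcm.MeasurementQC | None
    reason: str = ""


def process_record(
    record: sig.PPGRecord,
    *,
    age: float,
    height_cm: float,
    bmi: float,
    ref_sbp: float = float("nan"),
    ref_dbp: float = float("nan"),
    config: PipelineConfig | None = None,
) -> ProcessedMeasurement | RejectedMeasurement:
    """Full single-measurement pipeline up to (but excluding) basis projection."""
    cfg = config or PipelineConfig()
    try:
        feet = sig.detect_feet(record, cfg)
    except PPGError as exc:
        return RejectedMeasurement(record.measurement_id, record.subject_id, None, str(exc))
    beats = sig.segment_beats(record, feet, cfg)
    if len(beats) < 5:
        return RejectedMeasurement(
            record.measurement_id, record.subject_id, None, "fewer than 5 beats"
        )

    sdptgs: list[sig.SDPTG] = []
    qualities: list[qcm.BeatQuality] = []
    for i, b in enumerate(beats):
        sd = sig.compute_sdptg(b, cfg)
        sdptgs.append(sd)
        qualities.append(
            qcm.BeatQuality(
                beat_index=i,
                pi=qcm.perfusion_index(b),
                si=qcm.stiff_index(b, height_cm),
                hr=qcm.beat_heart_rate(b),
                area1=(qcm.beat_areas(b) or (np.nan, np.nan))[0],
                area2=(qcm.beat_areas(b) or (np.nan, np.nan))[1],
                flags=set(b.flags),
            )
        )
        res = qcm.sdptg_noise_test(sd, b.notch_idx, len(b.samples) - 1, cfg)
        qualities[-1].noise_fail = res is False

    qcm.flag_abnormal_beats(qualities, cfg)

    good = [
        i
        for i, q in enumerate(qualities)
        if not q.abnormal and not q.noise_fail and sdptgs[i].complete and q.si is not None
    ]

    # candidate shapes for template selection
    if len(good) >= cfg.min_good_cycles:
        ppg_shapes = np.vstack(
            [ft.normalize_minmax(ft.resample_beat(beats[i].samples, cfg.resample_points))
             if cfg.normalize == "minmax"
             else ft.resample_beat(beats[i].samples, cfg.resample_points)
             for i in good]
        )
        sd_shapes = np.vstack(
            [ft.normalize_maxabs(ft.resample_beat(sdptgs[i].samples, cfg.resample_points))
             for i in good]
        )
        template = ft.build_template(ppg_shapes)
        sel = ft.select_beats(ppg_shapes, template, cfg.beats_selected)
        n_sel = len(sel)
    else:
        n_sel = len(good)

    mqc = qcm.qc_measurement(qualities, n_sel, cfg)
    if not mqc.accepted:
        return RejectedMeasurement(
            record.measurement_id, record.subject_id, mqc, ";".join(mqc.reject_reasons)
        )

    good_arr = np.asarray(good)
    scal = np.vstack(
        [
            [
                qualities[i].hr,
                *ft.sdptg_ratios(sdptgs[i]),
                qualities[i].si,
            ]
            for i in good_arr[sel]
        ]
    )
    return ProcessedMeasurement(
        measurement_id=record.measurement_id,
        subject_id=record.subject_id,
        ppg_shapes=ppg_shapes[sel],
        sdptg_shapes=sd_shapes[sel],
        scalars=scal,
        beat_indices=good_arr[sel],
        bmi=bmi,
        age=age,
        height_cm=height_cm,
        ref_sbp=ref_sbp,
        ref_dbp=ref_dbp,
        mean_pi=mqc.mean_pi,
        qc=mqc,
    )


def process_dataset(
    records: list[sig.PPGRecord],
    biometrics: dict[str, dict],
    references: dict[str, dict],
    config: PipelineConfig | None = None,
) -> tuple[list[ProcessedMeasurement], list[RejectedMeasurement]]:
    """Process many records; biometrics keyed by subject_id, references by measurement_id.

    Reference rows carrying a truthy ``cuff_discrepancy_flag`` (the two cuff
    readings differed by more than 5 mmHg) are disqualified up front.
    """
    cfg = config or PipelineConfig()
    accepted, rejected = [], []
    for rec in records:
        bio = biometrics[rec.subject_id]
        ref = references.get(rec.measurement_id, {})
        if ref.get("cuff_discrepancy_flag", 0):
            rejected.append(
                RejectedMeasurement(rec.measurement_id, rec.subject_id, None, "cuff discrepancy")
            )
            continue
        out = process_record(
            rec,
            age=bio["age"],
            height_cm=bio["height_cm"],
            bmi=bio["bmi"],
            ref_sbp=ref.get("ref_sbp", float("nan")),
            ref_dbp=ref.get("ref_dbp", float("nan")),
            config=cfg,
        )
        (accepted if isinstance(out, ProcessedMeasurement) else rejected).append(out)
    return accepted, rejected
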
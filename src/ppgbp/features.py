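"""Beat normalisation, waveform bases (SVD) and the 19-element feature vector.

Each good beat is linearly resampled to 32 points.  Per measurement, a median
template is built and the 30 beats most similar to it (Euclidean distance) are
selected.  Across the training set, a singular value decomposition of the
stacked 32-point beats yields an orthonormal shape basis: 4 components for the
PPG stream (P1–P4) and 8 for the SDPTG stream (S1–S8).  A beat's feature
vector is [P1..P4, S1..S8, HR, b/a, c/a, d/a, e/a, SI, BMI] — 19 scalars.

Beats are baseline-shifted and peak-normalised before the SVD so the
coefficients encode shape, not perfusion amplitude (the perfusion index enters
the analysis separately through QC and stratification).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FeatureAssemblyError, InsufficientCyclesError, RankDeficiencyError
from .signal import SDPTG

FEATURE_NAMES = (
    ["P1", "P2", "P3", "P4"]
    + [f"S{i}" for i in range(1, 9)]
    + ["HR", "b_a", "c_a", "d_a", "e_a", "SI", "BMI"]
)
N_FEATURES = 19


@dataclass
class NormalizedBeat:
    """A beat resampled to a fixed-length grid."""

    shape: np.ndarray
    beat_index: int = -1


def resample_beat(samples: np.ndarray, n: int = 32) -> np.ndarray:
    """Linear interpolation of a beat onto ``n`` equally spaced points.

    Endpoints are preserved exactly.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 4:
        raise ValueError(f"beat too short to resample: {len(samples)} samples")
    grid = np.linspace(0.0, len(samples) - 1.0, n)
    return np.interp(grid, np.arange(len(samples)), samples)


def normalize_minmax(shape: np.ndarray) -> np.ndarray:
    """Shift baseline to zero and scale the peak to one (shape-only encoding)."""
    y = shape - shape.min()
    peak = y.max()
    return y / peak if peak > 0 else y


def normalize_maxabs(shape: np.ndarray) -> np.ndarray:
    """Scale by the largest absolute value (for signed SDPTG shapes)."""
    m = np.abs(shape).max()
    return shape / m if m > 0 else shape


def build_template(shapes: np.ndarray) -> np.ndarray:
    """Pointwise median across beats — the measurement's waveform template."""
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    if shapes.shape[0] == 0:
        raise ValueError("cannot build a template from zero beats")
    return np.median(shapes, axis=0)


def select_beats(shapes: np.ndarray, template: np.ndarray, k: int = 30) -> np.ndarray:
    """Indices of the k beats closest (Euclidean) to the template.

    Ties are broken in favour of the earlier beat.  Returned indices are in
    original (temporal) order.
    """
    shapes = np.atleast_2d(shapes)
    if shapes.shape[0] < k:
        raise InsufficientCyclesError(
            f"insufficient cycles: {shapes.shape[0]} available, {k} required"
        )
    dist = np.linalg.norm(shapes - template, axis=1)
    chosen = np.argsort(dist, kind="stable")[:k]
    return np.sort(chosen)


@dataclass
class WaveformBasis:
    """Orthonormal shape basis from an SVD of training beats."""

    mean_shape: np.ndarray
    components: np.ndarray  # (n_components, n_points)
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean_shape": self.mean_shape.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance_fraction": self.explained_variance_fraction.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "WaveformBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            mean_shape=np.array(d["mean_shape"]),
            components=np.array(d["components"]),
            explained_variance_fraction=np.array(d["explained_variance_fraction"]),
        )


def fit_waveform_basis(training_beats: np.ndarray, n_components: int) -> WaveformBasis:
    """Centre the stacked training beats and keep the first right singular vectors.

    The component count is fixed by configuration (4 for the PPG stream, 8 for
    SDPTG); explained-variance fractions are reported as diagnostics, not used
    for selection.  Component signs are fixed so each component's largest-
    magnitude element is positive.
    """
    X = np.atleast_2d(np.asarray(training_beats, dtype=float))
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} training beats, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s[0] > 0 else 0
    if rank < n_components:
        raise RankDeficiencyError(
            f"training matrix rank {rank} < requested {n_components} components"
        )
    comps = vt[:n_components].copy()
    for j in range(n_components):
        if comps[j, np.argmax(np.abs(comps[j]))] < 0:
            comps[j] = -comps[j]
    var = s**2
    evf = var[:n_components] / var.sum()
    return WaveformBasis(mean_shape=mean, components=comps, explained_variance_fraction=evf)


def project_beat(shape: np.ndarray, basis: WaveformBasis) -> np.ndarray:
    """Coefficients of the centred shape on the basis components, in order."""
    return (np.asarray(shape, dtype=float) - basis.mean_shape) @ basis.components.T


def sdptg_ratios(sdptg: SDPTG) -> tuple[float, float, float, float]:
    """The signed amplitude ratios b/a, c/a, d/a, e/a of the SDPTG waves."""
    if not sdptg.complete:
        raise FeatureAssemblyError("sdptg-incomplete beat has no amplitude ratios")
    a = sdptg.a_amp
    if a == 0:
        raise FeatureAssemblyError("a-wave amplitude is zero; ratios undefined")
    return (sdptg.b_amp / a, sdptg.c_amp / a, sdptg.d_amp / a, sdptg.e_amp / a)


def assemble_features(
    p: np.ndarray,
    s: np.ndarray,
    hr: float,
    ratios: tuple[float, float, float, float],
    si: float | None,
    bmi: float,
) -> np.ndarray:
    """The fixed-order 19-element input vector of the regression model."""
    if len(p) != 4 or len(s) != 8:
        raise FeatureAssemblyError(f"expected 4 PPG + 8 SDPTG coefficients, got {len(p)} + {len(s)}")
    if si is None:
        raise FeatureAssemblyError("stiff index missing (notchless beat)")
    vec = np.concatenate([p, s, [hr], ratios, [si, bmi]])
    if vec.shape != (N_FEATURES,) or not np.all(np.isfinite(vec)):
        raise FeatureAssemblyError("feature vector has wrong length or non-finite entries")
    return vec


def feature_table(
    rows: list[tuple[str, int, np.ndarray]],
) -> pd.DataFrame:
    """Delimited-table form: one row per beat with named feature columns."""
    return pd.DataFrame(
        [
            {"measurement_id": mid, "beat_idx": bi, **dict(zip(FEATURE_NAMES, vec))}
            for mid, bi, vec in rows
        ]
    )
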
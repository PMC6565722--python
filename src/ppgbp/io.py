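"""Plain-text file formats: raw PPG dumps and the delimited tables.

Raw PPG is the device-dump format: one sample (integer or float device count)
per line, optionally preceded by a header line ``# fs=50`` overriding the
default sampling rate.  Tables (biometrics, references, QC, features,
predictions) are comma-delimited with headers, written with a fixed float
format so repeated runs are byte-identical.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import PPGRecord

FLOAT_FORMAT = "%.6g"
_FS_RE = re.compile(r"#\s*fs\s*=\s*([0-9.]+)")


def read_ppg_text(
    path: str | Path, fs: float = 50.0, measurement_id: str = "", subject_id: str = ""
) -> PPGRecord:
    """Read a one-sample-per-line PPG dump; ``# fs=...`` header overrides fs."""
    path = Path(path)
    lines = path.read_text().splitlines()
    samples = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            m = _FS_RE.match(ln)
            if m:
                fs = float(m.group(1))
            continue
        samples.append(float(ln))
    return PPGRecord(
        samples=np.asarray(samples),
        fs=fs,
        measurement_id=measurement_id or path.stem,
        subject_id=subject_id,
    )


def write_ppg_text(record: PPGRecord, path: str | Path) -> None:
    path = Path(path)
    body = "\n".join(FLOAT_FORMAT % v for v in record.samples)
    path.write_text(f"# fs={record.fs:g}\n{body}\n")


def read_biometrics(path: str | Path) -> dict[str, dict]:
    """subject_id, age, height_cm, weight_kg, bmi → dict keyed by subject."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "height_cm", "weight_kg", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biometrics table missing columns: {sorted(missing)}")
    return {
        r.subject_id: {
            "age": r.age,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "bmi": r.bmi,
        }
        for r in df.itertuples()
    }


def read_references(path: str | Path) -> dict[str, dict]:
    """measurement_id, subject_id, ref_sbp, ref_dbp[, cuff_discrepancy_flag]."""
    df = pd.read_csv(path, dtype={"measurement_id": str, "subject_id": str})
    required = {"measurement_id", "subject_id", "ref_sbp", "ref_dbp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if "cuff_discrepancy_flag" not in df.columns:
        df["cuff_discrepancy_flag"] = 0
    return {
        r.measurement_id: {
            "subject_id": r.subject_id,
            "ref_sbp": r.ref_sbp,
            "ref_dbp": r.ref_dbp,
            "cuff_discrepancy_flag": int(r.cuff_discrepancy_flag),
        }
        for r in df.itertuples()
    }


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer (fixed float format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
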
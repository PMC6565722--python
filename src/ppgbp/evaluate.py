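"""Agreement statistics, stratified error summaries and significance tests.

Errors are (estimated − reference) BP in mmHg.  Agreement is summarised by the
mean error, its sample SD, the Pearson correlation between estimated and
reference BP, and Bland–Altman bias with 95 % limits of agreement
(bias ± 1.96 SD).  Measurements are stratified three ways: by age (young ≤ 50 y
vs older), by reference SBP level (group I: 90 < SBP < 120; II: 120 ≤ SBP
< 140; III: SBP ≥ 140; an explicit below-range bucket for SBP ≤ 90), and by
mean perfusion index (low < 0.01 vs high ≥ 0.01).

Two significance tests: a two-sample t-test comparing errors between the low-
and high-PI groups, and a one-sided paired t-test that personal calibration
shrinks absolute errors.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

AGE_GROUPS = ("young", "older")
SBP_GROUPS = ("below-range", "I", "II", "III")
PI_GROUPS = ("low", "high")


@dataclass
class ErrorSummary:
    n: int
    mean_error: float
    sd_error: float
    pearson_r: float  # NaN when undefined (constant input)
    bias: float
    loa_low: float
    loa_high: float


def summarize_errors(preds, refs) -> ErrorSummary:
    """Mean/SD of errors, Pearson R and Bland–Altman limits of agreement."""
    preds = np.asarray(preds, float)
    refs = np.asarray(refs, float)
    if preds.shape != refs.shape or preds.size < 2:
        raise ValueError("need >= 2 paired values")
    err = preds - refs
    mean, sd = float(err.mean()), float(err.std(ddof=1))
    if np.ptp(refs) == 0 or np.ptp(preds) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(preds, refs).statistic)
    return ErrorSummary(
        n=preds.size,
        mean_error=mean,
        sd_error=sd,
        pearson_r=r,
        bias=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


def age_group(age: float, cut: float = 50.0) -> str:
    return "young" if age <= cut else "older"


def sbp_group(sbp: float, cuts=(90.0, 120.0, 140.0)) -> str:
    low, mid, high = cuts
    if sbp <= low:
        return "below-range"
    if sbp < mid:
        return "I"
    if sbp < high:
        return "II"
    return "III"


def pi_group(pi: float, cut: float = 0.01) -> str:
    return "low" if pi < cut else "high"


def stratify(df: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Attach age/SBP/PI group labels (columns age, ref_sbp, mean_pi required).

    Assignment within each axis is disjoint and exhaustive; SBP values at or
    below 90 mmHg go to an explicit "below-range" bucket, never dropped.
    """
    cfg = config or PipelineConfig()
    out = df.copy()
    out["age_group"] = [age_group(a, cfg.age_cut_years) for a in df["age"]]
    out["sbp_group"] = [sbp_group(s, cfg.sbp_group_cuts_mmhg) for s in df["ref_sbp"]]
    out["pi_group"] = [pi_group(p, cfg.pi_cut) for p in df["mean_pi"]]
    return out


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    significant_05: bool
    significant_001: bool
    n1: int
    n2: int


def _flags(p: float) -> tuple[bool, bool]:
    return (bool(p < 0.05), bool(p < 0.001)) if np.isfinite(p) else (False, False)


def compare_pi_groups(errors_low, errors_high) -> TTestResult:
    """Two-sample t-test of fitting errors between low- and high-PI measurements."""
    a, b = np.asarray(errors_low, float), np.asarray(errors_high, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return TTestResult(float("nan"), float("nan"), False, False, a.size, b.size)
    res = stats.ttest_ind(a, b)
    s05, s001 = _flags(res.pvalue)
    return TTestResult(float(res.statistic), float(res.pvalue), s05, s001, a.size, b.size)


def compare_calibration(errors_free, errors_cal) -> TTestResult:
    """One-sided paired t-test that calibrated errors are smaller in magnitude."""
    a, b = np.asarray(errors_free, float), np.asarray(errors_cal, float)
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal lengths")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    d = np.abs(a) - np.abs(b)
    if np.ptp(d) == 0:
        # constant difference: no within-pair variance; report by convention
        if d[0] == 0:
            return TTestResult(0.0, 0.5, False, False, a.size, b.size)
        p = 0.0 if d[0] > 0 else 1.0
        return TTestResult(float("inf") if d[0] > 0 else float("-inf"), p, *_flags(p), a.size, b.size)
    res = stats.ttest_rel(np.abs(a), np.abs(b), alternative="greater")
    s05, s001 = _flags(res.pvalue)
    return TTestResult(float(res.statistic), float(res.pvalue), s05, s001, a.size, b.size)


def _summary_row(grp: pd.DataFrame, which: str) -> dict:
    if len(grp) < 2:
        return {"n": len(grp)}
    s = summarize_errors(grp[f"test_{which}"], grp[f"ref_{which}"])
    return {
        "n": s.n,
        f"{which}_mean_error": s.mean_error,
        f"{which}_sd_error": s.sd_error,
        f"{which}_pearson_r": s.pearson_r,
        f"{which}_loa_low": s.loa_low,
        f"{which}_loa_high": s.loa_high,
    }


def report(loso: pd.DataFrame, calib: pd.DataFrame | None = None,
           config: PipelineConfig | None = None) -> dict:
    """Build the four table families: by age, by SBP group, by PI group, calibration.

    Returns a dict of DataFrames plus a "tests" entry with the two significance
    tests (computed for SBP and DBP errors separately, labelled).
    """
    cfg = config or PipelineConfig()
    df = stratify(loso, cfg)
    out: dict = {}

    def family(key: str, groups) -> pd.DataFrame:
        rows = []
        for g in groups:
            grp = df[df[key] == g]
            row = {"group": g}
            for which in ("sbp", "dbp"):
                row.update(_summary_row(grp, which))
            rows.append(row)
        return pd.DataFrame(rows)

    out["by_age"] = family("age_group", AGE_GROUPS)
    out["by_sbp_group"] = family("sbp_group", SBP_GROUPS)
    out["by_pi"] = family("pi_group", PI_GROUPS)

    tests = {}
    low, high = df[df.pi_group == "low"], df[df.pi_group == "high"]
    if len(low) >= 2 and len(high) >= 2:
        for which in ("sbp", "dbp"):
            t = compare_pi_groups(low[f"err_{which}"], high[f"err_{which}"])
            tests[f"pi_{which}"] = asdict(t)
    if calib is not None and len(calib) >= 2:
        rows = []
        for which in ("sbp", "dbp"):
            free, cal = calib[f"err_{which}_free"], calib[f"err_{which}_cal"]
            t = compare_calibration(free, cal)
            tests[f"calibration_{which}"] = asdict(t)
            rows.append(
                {
                    "which": which,
                    "n": len(calib),
                    "free_mean": float(free.mean()),
                    "free_sd": float(free.std(ddof=1)),
                    "cal_mean": float(cal.mean()),
                    "cal_sd": float(cal.std(ddof=1)),
                    "paired_p": t.pvalue,
                }
            )
        out["calibration"] = pd.DataFrame(rows)
    out["tests"] = tests
    return out


def write_report(rep: dict, outdir: str | Path, float_format: str = "%.6g") -> None:
    """Delimited tables plus one structured JSON summary; deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, obj in sorted(rep.items()):
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False, float_format=float_format)
            summary[name] = json.loads(obj.to_json(orient="records"))
        else:
            summary[name] = obj
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def make_plots(loso: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Optional scatter and Bland–Altman figures (reference BP on the x-axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for which in ("sbp", "dbp"):
        ref, test = loso[f"ref_{which}"], loso[f"test_{which}"]
        err = test - ref
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].scatter(ref, test, s=8, alpha=0.6)
        lims = [min(ref.min(), test.min()) - 5, max(ref.max(), test.max()) + 5]
        axes[0].plot(lims, lims, "k--", lw=1)
        axes[0].set_xlabel(f"reference {which.upper()} (mmHg)")
        axes[0].set_ylabel(f"estimated {which.upper()} (mmHg)")
        bias, sd = err.mean(), err.std(ddof=1)
        axes[1].scatter(ref, err, s=8, alpha=0.6)
        for y, style in ((bias, "-"), (bias + 1.96 * sd, "--"), (bias - 1.96 * sd, "--")):
            axes[1].axhline(y, color="r", ls=style, lw=1)
        axes[1].set_xlabel(f"reference {which.upper()} (mmHg)")
        axes[1].set_ylabel("error (mmHg)")
        fig.tight_layout()
        p = outdir / f"agreement_{which}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
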
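"""Statistical validation of CCIA against the clinical reference indices.

Recomputes every per-patient CCIA from the packaged contrast-intensity
table, correlates the index with FFR (n=15) and iFR (n=11, four patients
unmeasured) by Pearson's product-moment method, summarizes bench
replicates as mean +/- sample SD, and — when a simulator grid is supplied —
checks the ordinal bench trends (CCIA and FFR decreasing with stenosis
severity, FFR also with length).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_stack import load_table2
from .tic_core import ccia as ccia_ratio

__all__ = [
    "CorrelationReport",
    "ReplicateSummary",
    "pearson",
    "recompute_table2",
    "replicate_summary",
    "validate_report",
]


@dataclass
class CorrelationReport:
    """Pearson r with its two-sided p and the OLS line of y on x."""

    r: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass
class ReplicateSummary:
    mean: float
    sd: float | None  # None when undefined (n = 1)
    n: int


def pearson(x, y) -> CorrelationReport:
    """Pearson correlation with two-sided p (t transform, n-2 df) and the
    ordinary least-squares best-fit line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError(f"need n >= 3, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationReport(float(res.statistic), float(res.pvalue),
                             len(x), float(slope), float(intercept))


def recompute_table2(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each patient's CCIA from the printed intensity columns.

    Adds ``ccia_recomputed`` (stenotic / proximal) and ``ccia_match``
    (recomputed value rounded to 2 dp equals the printed CCIA; Python's
    round-half-to-even, under which all printed rows agree).
    """
    if table is None:
        table = load_table2()
    out = table.copy()
    recomputed = []
    for _, row in out.iterrows():
        recomputed.append(
            ccia_ratio(float(row["proximal"]), float(row["stenotic"])).ccia)
    out["ccia_recomputed"] = recomputed
    out["ccia_match"] = [round(v, 2) == round(float(p), 2)
                         for v, p in zip(recomputed, out["ccia"])]
    return out


def replicate_summary(values) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator); SD undefined for a single value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty replicate set")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return ReplicateSummary(mean, sd, int(v.size))


# the nine bench per-model means as printed: (length mm, %DS, FFR, mean CCIA)
BENCH_MEANS = [
    (6, 30, 0.90, 0.82), (6, 50, 0.86, 0.68), (6, 70, 0.85, 0.61),
    (18, 30, 0.84, 0.78), (18, 50, 0.64, 0.69), (18, 70, 0.61, 0.44),
    (30, 30, 0.69, 0.80), (30, 50, 0.37, 0.64), (30, 70, 0.33, 0.40),
]


def _ordinal_checks(grid: pd.DataFrame) -> dict:
    """Monotone bench trends on a simulator grid (means over replicates)."""
    means = (grid.groupby(["length", "percent_ds"])[["ccia", "ffr"]]
             .mean().reset_index())
    checks = {}
    ccia_ok = ffr_ds_ok = True
    for length, sub in means.groupby("length"):
        sub = sub.sort_values("percent_ds")
        ccia_ok &= bool(np.all(np.diff(sub["ccia"]) < 0))
        ffr_ds_ok &= bool(np.all(np.diff(sub["ffr"]) < 0))
    ffr_len_ok = True
    for ds, sub in means.groupby("percent_ds"):
        sub = sub.sort_values("length")
        ffr_len_ok &= bool(np.all(np.diff(sub["ffr"]) < 0))
    checks["ccia_decreasing_in_severity"] = ccia_ok
    checks["ffr_decreasing_in_severity"] = ffr_ds_ok
    checks["ffr_decreasing_in_length"] = ffr_len_ok
    return checks


def validate_report(grid: pd.DataFrame | None = None,
                    out_path: str | Path | None = None) -> dict:
    """Build the full validation report as one JSON-serializable document.

    Contains the per-patient CCIA recomputation, the CCIA–FFR and
    CCIA–iFR correlations with their best-fit lines, the nine-model bench
    mean correlation (displayed, not asserted: the printed per-model means
    do not themselves reproduce the bench correlation), and — when a
    simulator grid is given — the ordinal trend checks. ``passed`` is the
    conjunction of every asserted check.
    """
    table = recompute_table2()
    ccia_vals = table["ccia"].to_numpy(float)
    ffr_vals = table["ffr"].to_numpy(float)
    rep_ffr = pearson(ccia_vals, ffr_vals)
    has_ifr = table["ifr"].notna()
    rep_ifr = pearson(table.loc[has_ifr, "ccia"].to_numpy(float),
                      table.loc[has_ifr, "ifr"].to_numpy(float))
    bench = pd.DataFrame(BENCH_MEANS,
                         columns=["length", "percent_ds", "ffr", "ccia"])
    rep_bench = pearson(bench["ccia"], bench["ffr"])

    report = {
        "table2": {
            "n": int(len(table)),
            "n_matches": int(table["ccia_match"].sum()),
            "mismatched_patients": table.loc[~table["ccia_match"],
                                             "patient"].tolist(),
        },
        "ccia_vs_ffr": asdict(rep_ffr),
        "ccia_vs_ifr": asdict(rep_ifr),
        "bench_nine_mean_correlation": asdict(rep_bench),  # informational only
    }
    checks = {
        "all_ccia_match": bool(table["ccia_match"].all()),
        "ffr_p_below_0.05": rep_ffr.p_value < 0.05,
        "ifr_p_below_0.01": rep_ifr.p_value < 0.01,
    }
    if grid is not None:
        checks.update(_ordinal_checks(grid))
    report["checks"] = checks
    report["passed"] = all(checks.values())
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
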
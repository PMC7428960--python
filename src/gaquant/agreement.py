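"""Method-agreement statistics for measurement tables.

Implements Lin's concordance correlation coefficient (CCC) with the
Fisher-z confidence interval, two-way ANOVA intraclass correlation
coefficients (random-effects / absolute-agreement and mixed-effects /
consistency forms, single and average-of-k units) with F-based
confidence intervals, the conventional agreement-category limits, a
Mann-Whitney U comparison, and a validation report that runs the full
analysis grid — overall and stratified by lesion shape and lesion count —
on an eye x rater/replicate table.

Tables use the column schema ``eye_id, rater_1..R, sw_1..S`` with values
in mm^2 (areas) or mm (perimeters).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "lin_ccc",
    "icc_twoway",
    "categorize_agreement",
    "mann_whitney_u",
    "validation_report",
    "save_report",
    "load_measurement_table",
]

_STRATA = ("whole", "regular", "irregular", "single", "multiple")


@dataclass
class AgreementResult:
    """A CCC or ICC estimate with its 95% CI and agreement category."""

    statistic: str  # "ccc" or "icc"
    estimate: float
    ci95: tuple[float, float]
    model: str  # e.g. "ccc", "random", "mixed"
    unit: str  # "single" or "average"
    category: str
    n: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-9 <= self.estimate <= hi + 1e-9):
            raise ValueError("estimate must lie inside its confidence interval")


def categorize_agreement(v: float) -> str:
    """Agreement category for a CCC/ICC estimate.

    poor < 0.90 <= moderate < 0.95 <= substantial < 0.99 <= almost perfect.
    """
    if not (-1.0 <= v <= 1.0):
        raise ValueError("agreement estimates lie in [-1, 1]")
    if v < 0.90:
        return "poor"
    if v < 0.95:
        return "moderate"
    if v < 0.99:
        return "substantial"
    return "almost perfect"


def lin_ccc(x, y, *, alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient between paired vectors.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (1/n) moment estimators.  The 95% CI comes from the Fisher
    z-transformation with Lin's variance for the transformed estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("CCC requires at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both inputs constant with equal means")
    ccc = 2.0 * sxy / denom

    # Fisher-z CI with Lin's (1989, corrected 2000) variance
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if sx2 > 0 and sy2 > 0 and abs(ccc) < 1:
        r = sxy / np.sqrt(sx2 * sy2)
        u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
        if abs(r) > 0:
            var_z = (
                (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
                + 4 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
                - 2 * ccc**4 * u2**2 / (r**2 * (1 - ccc**2) ** 2)
            ) / (n - 2)
            var_z = max(var_z, 0.0)
            z = np.arctanh(ccc)
            lo, hi = np.tanh(z - zcrit * np.sqrt(var_z)), np.tanh(z + zcrit * np.sqrt(var_z))
        else:
            lo, hi = -1.0, 1.0
    else:
        lo, hi = (ccc, ccc) if abs(ccc) == 1 else (-1.0, 1.0)

    return AgreementResult(
        statistic="ccc",
        estimate=float(ccc),
        ci95=(float(min(lo, ccc)), float(max(hi, ccc))),
        model="ccc",
        unit="single",
        category=categorize_agreement(float(np.clip(ccc, -1, 1))),
        n=n,
    )


def _sb(icc1: float, k: int) -> float:
    """Spearman-Brown step-up from a single-measure ICC to average-of-k."""
    if icc1 >= 1.0:
        return 1.0
    return k * icc1 / (1.0 + (k - 1) * icc1)


def icc_twoway(
    data, model: str = "random", unit: str = "single", *, alpha: float = 0.05
) -> AgreementResult:
    """Two-way ANOVA intraclass correlation for an n x k complete matrix.

    ``model="random"`` gives the absolute-agreement form (interchangeable
    raters, Shrout–Fleiss 2,1 / 2,k); ``model="mixed"`` the consistency
    form for fixed raters/replicates (3,1 / 3,k).  ``unit`` selects the
    single-measure or average-of-k estimate; 95% CIs use the F-based
    bounds of McGraw & Wong.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D subjects x raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("ICC requires at least 3 subjects and 2 raters")
    if not np.isfinite(X).all():
        raise ValueError("incomplete matrix: ICC requires a complete n x k table")
    if model not in ("random", "mixed") or unit not in ("single", "average"):
        raise ValueError("model must be random|mixed and unit single|average")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    # snap float-rounding residue to exact zero (e.g. identical columns)
    tol = 1e-12 * max(msr, msc, mse)
    msc = 0.0 if msc <= tol else msc
    mse = 0.0 if mse <= tol else mse

    if np.isclose(np.var(row_means), 0.0):
        warnings.warn("zero between-subject variance: ICC set to 0", stacklevel=2)
        est = 0.0
        lo, hi = 0.0, 0.0
        return AgreementResult("icc", est, (lo, hi), model, unit, categorize_agreement(est), n)

    fcrit = lambda d1, d2: stats.f.ppf(1 - alpha / 2, d1, d2)  # noqa: E731

    if model == "mixed":
        if mse == 0:
            icc1, lo1, hi1 = 1.0, 1.0, 1.0
        else:
            icc1 = (msr - mse) / (msr + (k - 1) * mse)
            fobs = msr / mse
            fl = fobs / fcrit(n - 1, (n - 1) * (k - 1))
            fu = fobs * fcrit((n - 1) * (k - 1), n - 1)
            lo1 = (fl - 1) / (fl + k - 1)
            hi1 = (fu - 1) / (fu + k - 1)
    else:  # random / absolute agreement
        if mse == 0 and msc == 0:
            icc1, lo1, hi1 = 1.0, 1.0, 1.0
        else:
            icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            fj = msc / mse if mse > 0 else np.inf
            a_ = k * icc1 / (n * (1 - icc1)) if icc1 < 1 else np.inf
            b_ = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
            if np.isfinite(fj) and np.isfinite(a_):
                v = (a_ * fj + b_) ** 2 / (a_**2 * fj**2 / (k - 1) + b_**2 / ((n - 1) * (k - 1)))
                f_up = fcrit(n - 1, v)
                f_lo = fcrit(v, n - 1)
                lo1 = n * (msr - f_up * mse) / (
                    f_up * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi1 = n * (f_lo * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_lo * msr)
            else:
                lo1 = hi1 = icc1

    if unit == "average":
        est, lo, hi = _sb(icc1, k), _sb(lo1, k), _sb(hi1, k)
    else:
        est, lo, hi = icc1, lo1, hi1
    lo, hi = min(lo, est), max(hi, est)
    return AgreementResult(
        "icc",
        float(est),
        (float(lo), float(hi)),
        model,
        unit,
        categorize_agreement(float(np.clip(est, -1, 1))),
        n,
    )


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney rank-sum U and two-sided p-value.

    Uses the exact null distribution when both samples are small
    (min(n) <= 10) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def load_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an ``eye_id, rater_*, sw_*`` CSV table."""
    df = pd.read_csv(path)
    return validate_table(df)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    manual = [c for c in df.columns if c.startswith("rater_")]
    software = [c for c in df.columns if c.startswith("sw_")]
    if "eye_id" not in df.columns or not manual or not software:
        raise ValueError("table must have eye_id, rater_* and sw_* columns")
    if len(df) < 2:
        raise ValueError("table must have at least 2 rows")
    vals = df[manual + software]
    if vals.isna().any().any():
        bad = int(np.flatnonzero(vals.isna().any(axis=1))[0])
        raise ValueError(f"missing measurement in table row {bad}")
    if (vals <= 0).any().any():
        bad = int(np.flatnonzero((vals <= 0).any(axis=1))[0])
        raise ValueError(f"nonpositive measurement in table row {bad}")
    return df


def _result_row(sample: str, res: AgreementResult | None) -> dict:
    if res is None:
        return {
            "sample": sample,
            "estimate": np.nan,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
            "category": "not estimable",
            "n": 0,
        }
    return {
        "sample": sample,
        "estimate": res.estimate,
        "ci_lo": res.ci95[0],
        "ci_hi": res.ci95[1],
        "category": res.category,
        "n": res.n,
    }


def validation_report(
    table: pd.DataFrame,
    strata: pd.DataFrame | None = None,
    *,
    icc_unit: str = "average",
    min_stratum: int = 3,
) -> dict:
    """The full agreement analysis grid on a measurement table.

    Computes, overall and per stratum (lesion shape regular/irregular,
    lesion count single/multiple): the CCC between the mean manual and
    mean software measurements; the interobserver ICC (two-way random
    effects) across manual raters; the intrasoftware ICC (two-way mixed
    effects) across software replicates; and a descriptive summary
    (mean +/- SD, range) with a Mann-Whitney comparison of automatic vs
    manual values.  Strata with fewer than ``min_stratum`` eyes are
    reported as not estimable.

    Parameters
    ----------
    table : DataFrame with columns ``eye_id, rater_1..R, sw_1..S``.
    strata : optional DataFrame with ``eye_id, shape_class, number_class``.

    Returns
    -------
    dict with DataFrames ``ccc``, ``interobserver_icc``,
    ``intrasoftware_icc``, ``summary`` and the metadata used.
    """
    table = validate_table(table)
    manual_cols = sorted(c for c in table.columns if c.startswith("rater_"))
    sw_cols = sorted(c for c in table.columns if c.startswith("sw_"))

    labels = pd.DataFrame({"eye_id": table["eye_id"]})
    labels["shape_class"] = None
    labels["number_class"] = None
    if strata is not None:
        merged = labels[["eye_id"]].merge(strata, on="eye_id", how="left")
        labels["shape_class"] = merged["shape_class"].to_numpy()
        labels["number_class"] = merged["number_class"].to_numpy()

    def _subset(name: str) -> pd.DataFrame:
        if name == "whole":
            return table
        if name in ("regular", "irregular"):
            return table[labels["shape_class"].to_numpy() == name]
        return table[labels["number_class"].to_numpy() == name]

    ccc_rows, inter_rows, intra_rows = [], [], []
    for name in _STRATA:
        sub = _subset(name)
        if len(sub) < min_stratum:
            ccc_rows.append(_result_row(name, None))
            inter_rows.append(_result_row(name, None))
            intra_rows.append(_result_row(name, None))
            continue
        manual_mean = sub[manual_cols].mean(axis=1).to_numpy()
        sw_mean = sub[sw_cols].mean(axis=1).to_numpy()
        ccc_rows.append(_result_row(name, lin_ccc(manual_mean, sw_mean)))
        inter_rows.append(
            _result_row(name, icc_twoway(sub[manual_cols].to_numpy(), "random", icc_unit))
        )
        intra_rows.append(
            _result_row(name, icc_twoway(sub[sw_cols].to_numpy(), "mixed", icc_unit))
        )

    manual_mean_all = table[manual_cols].mean(axis=1).to_numpy()
    sw_mean_all = table[sw_cols].mean(axis=1).to_numpy()
    _, p = mann_whitney_u(sw_mean_all, manual_mean_all)
    summary = pd.DataFrame(
        [
            {
                "method": "automatic",
                "mean": sw_mean_all.mean(),
                "sd": sw_mean_all.std(ddof=1),
                "min": sw_mean_all.min(),
                "max": sw_mean_all.max(),
                "p_mann_whitney": p,
            },
            {
                "method": "manual",
                "mean": manual_mean_all.mean(),
                "sd": manual_mean_all.std(ddof=1),
                "min": manual_mean_all.min(),
                "max": manual_mean_all.max(),
                "p_mann_whitney": p,
            },
        ]
    )
    return {
        "ccc": pd.DataFrame(ccc_rows),
        "interobserver_icc": pd.DataFrame(inter_rows),
        "intrasoftware_icc": pd.DataFrame(intra_rows),
        "summary": summary,
        "meta": {
            "n_eyes": int(len(table)),
            "manual_columns": manual_cols,
            "software_columns": sw_cols,
            "icc_unit": icc_unit,
        },
    }


def save_report(report: dict, outdir: str | Path) -> None:
    """Write the validation report as per-table CSVs plus report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "ccc": "table2_ccc.csv",
        "interobserver_icc": "table3_interobserver.csv",
        "intrasoftware_icc": "table4_intrasoftware.csv",
        "summary": "table5_summary.csv",
    }
    payload = {"meta": report["meta"]}
    for key, fname in files.items():
        report[key].to_csv(outdir / fname, index=False)
        payload[key] = report[key].to_dict(orient="records")
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=float))
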
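"""Cohort statistics: indexing, group tests, agreement and ROC analysis.

Volumes are indexed to vessel length and body surface area (Du Bois),
diameters to BSA.  Group differences use the two-sided independent-samples
t-test (Welch by default).  Observer agreement is quantified with
Shrout-Fleiss intraclass correlation coefficients and Bland-Altman limits of
agreement.  Discrimination of patients from controls is summarized by the
ROC area under the curve with a DeLong confidence interval, plus
sensitivity/specificity/PPV/NPV at a fixed cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "RocResult",
    "du_bois_bsa",
    "index_measurements",
    "vol_composites",
    "group_ttest",
    "icc_shrout_fleiss",
    "bland_altman",
    "roc_auc",
    "cutoff_metrics",
]


@dataclass
class AgreementResult:
    icc: float = np.nan
    icc_form: str = ""
    icc_p: float = np.nan
    mean_diff: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan
    n: int = 0


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p: float = np.nan
    cutoff: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    ppv: float = np.nan
    npv: float = np.nan


# --------------------------------------------------------------------------
# indexing
# --------------------------------------------------------------------------

def du_bois_bsa(weight_kg: float, height_cm: float) -> float:
    """Du Bois & Du Bois body surface area: 0.007184 * W^0.425 * H^0.725 (m^2)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def index_measurements(measurement, bsa_m2: float):
    """Index one vessel measurement: volume / (length * BSA) in
    ul/(cm*m^2) and diameters / BSA in mm/m^2.

    Returns a dict; an excluded measurement propagates as excluded.
    """
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    if measurement.excluded:
        return {"vessel": measurement.vessel, "excluded": True, "reason": measurement.reason}
    if measurement.length_cm <= 0:
        raise ValueError("vessel length must be positive for indexing")
    return {
        "vessel": measurement.vessel,
        "excluded": False,
        "vol3d": measurement.volume_ul / (measurement.length_cm * bsa_m2),
        "d3d_mean": measurement.mean_d / bsa_m2,
        "d3d_min": measurement.min_d / bsa_m2,
        "d3d_max": measurement.max_d / bsa_m2,
        "volume_ul": measurement.volume_ul,
        "length_cm": measurement.length_cm,
    }


def vol_composites(table: pd.DataFrame, method: str = "vol3d", aggregate_reads: bool = True) -> pd.DataFrame:
    """Per-subject VOL_AVG = (RPA + LPA)/2 and VOL_TOT = RPA + LPA on indexed
    volumes.  A subject missing either side gets NaN composites (mirrors the
    pairwise exclusion of failed segmentations).

    Expects the tidy cohort layout (columns subject, group, vessel, method,
    read, value).  Reads are averaged per subject first unless
    ``aggregate_reads=False`` (then composites are per read).
    """
    t = table[(table["method"] == method) & table["vessel"].isin(["RPA", "LPA"])]
    keys = ["subject", "group"] + ([] if aggregate_reads else ["read"])
    wide = (
        t.groupby(keys + ["vessel"])["value"].mean().unstack("vessel")
        .reindex(columns=["RPA", "LPA"])
    )
    out = wide.reset_index()
    out["VOL_AVG"] = (out["RPA"] + out["LPA"]) / 2.0
    out["VOL_TOT"] = out["RPA"] + out["LPA"]
    return out


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

def group_ttest(a, b, welch: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test; Welch by default.

    Degenerate case of zero variance in both groups with equal means is
    reported as (0, 1) by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

def icc_shrout_fleiss(matrix, form: str = "(2,1)") -> AgreementResult:
    """Single-rater Shrout-Fleiss intraclass correlation from an
    n-subjects x k-raters matrix (rows with missing cells are dropped).

    Forms: "(1,1)" one-way random; "(2,1)" two-way random, absolute
    agreement; "(3,1)" two-way mixed, consistency.  The p-value comes from
    the F ratio of the corresponding ANOVA.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("matrix must be n x k")
    m = m[~np.any(np.isnan(m), axis=1)]
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows

    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    msw = ss_within / (n * (k - 1))  # within subjects (one-way)

    if msr <= 0:
        return AgreementResult(icc=0.0, icc_form=form, icc_p=1.0, n=n)

    if form == "(1,1)":
        denom = msr + (k - 1) * msw
        icc = (msr - msw) / denom if denom > 0 else 0.0
        f = msr / msw if msw > 0 else np.inf
        df2 = n * (k - 1)
    elif form == "(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else 0.0
        f = msr / mse if mse > 0 else np.inf
        df2 = (n - 1) * (k - 1)
    elif form == "(3,1)":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else 0.0
        f = msr / mse if mse > 0 else np.inf
        df2 = (n - 1) * (k - 1)
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    p = float(stats.f.sf(f, n - 1, df2)) if np.isfinite(f) else 0.0
    return AgreementResult(icc=float(icc), icc_form=form, icc_p=p, n=n)


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement of paired measurements: mean difference and
    limits of agreement mean +/- 1.96 * SD (sample SD, n-1)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean_diff=md, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd, n=len(d))


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> RocResult:
    """ROC AUC as the Mann-Whitney pair statistic (ties count 0.5), with a
    95% CI from the DeLong variance estimator (truncated to [0, 1]) and a
    two-sided p-value against AUC = 0.5."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    allr = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    lo = float(np.clip(auc - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.96 * se, 0.0, 1.0))
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(auc=float(auc), ci_low=lo, ci_high=hi, p=p)


def cutoff_metrics(scores, labels, cutoff: float) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV at a fixed cutoff (positive if
    score >= cutoff); 0/0 ratios are reported as NaN, not 0."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else np.nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
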
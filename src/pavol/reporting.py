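"""Study-style result tables from a tidy measurement cohort.

Reproduces the shape of the study outputs: per-vessel group means +/- SD
with p-values and intra-/interobserver ICCs, and a ROC report for the
volume composites and manual diameters with fixed-cutoff classification
metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_stats import (
    cutoff_metrics,
    group_ttest,
    icc_shrout_fleiss,
    roc_auc,
    vol_composites,
)

__all__ = ["group_summary", "roc_report", "VOL_CUTOFF", "DIAM_CUTOFF"]

#: sex-independent cutoffs: indexed RPA/LPA average volume, ul/(cm*m^2),
#: and manual RPA/LPA diameter, mm/m^2
VOL_CUTOFF = 2500.0
DIAM_CUTOFF = 12.5

INTRA_READS = ("r1a", "r1b")  # reader 1, 6 months apart
INTER_READS = ("r1a", "r2")  # reader 1 vs reader 2


def _subject_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean over reads for each (vessel, method)."""
    return (
        table.groupby(["subject", "group", "vessel", "method"])["value"].mean().reset_index()
    )


def _read_matrix(table: pd.DataFrame, vessel: str, method: str, reads) -> np.ndarray:
    t = table[(table["vessel"] == vessel) & (table["method"] == method) & table["read"].isin(reads)]
    wide = t.pivot_table(index="subject", columns="read", values="value")
    wide = wide.reindex(columns=list(reads)).dropna()
    return wide.to_numpy()


def group_summary(table: pd.DataFrame, welch: bool = True) -> pd.DataFrame:
    """Per (vessel, method) row: group mean +/- SD (of per-subject read
    means), two-sided t-test p, and intra-/interobserver ICC.

    Intraobserver agreement compares reader 1's two reads with ICC(3,1)
    (fixed rater, consistency); interobserver compares reader 1 vs reader 2
    with ICC(2,1) (random raters, absolute agreement).  Methods read only
    once have no ICCs.
    """
    means = _subject_means(table)
    rows = []
    for (vessel, method), g in means.groupby(["vessel", "method"], sort=False):
        pat = g.loc[g["group"] == "patient", "value"].to_numpy()
        ctl = g.loc[g["group"] == "control", "value"].to_numpy()
        if len(pat) >= 2 and len(ctl) >= 2:
            _, p = group_ttest(pat, ctl, welch=welch)
        else:
            p = np.nan
        icc_intra = icc_inter = np.nan
        m_intra = _read_matrix(table, vessel, method, INTRA_READS)
        if m_intra.shape[0] >= 3 and m_intra.shape[1] == 2:
            icc_intra = icc_shrout_fleiss(m_intra, form="(3,1)").icc
        m_inter = _read_matrix(table, vessel, method, INTER_READS)
        if m_inter.shape[0] >= 3 and m_inter.shape[1] == 2:
            icc_inter = icc_shrout_fleiss(m_inter, form="(2,1)").icc
        rows.append(
            {
                "vessel": vessel,
                "method": method,
                "patient_mean": pat.mean() if len(pat) else np.nan,
                "patient_sd": pat.std(ddof=1) if len(pat) > 1 else np.nan,
                "control_mean": ctl.mean() if len(ctl) else np.nan,
                "control_sd": ctl.std(ddof=1) if len(ctl) > 1 else np.nan,
                "p_value": p,
                "icc_intra": icc_intra,
                "icc_inter": icc_inter,
                "n_patients": len(pat),
                "n_controls": len(ctl),
            }
        )
    return pd.DataFrame(rows)


def roc_report(
    table: pd.DataFrame,
    vol_cutoff: float = VOL_CUTOFF,
    diam_cutoff: float = DIAM_CUTOFF,
) -> pd.DataFrame:
    """ROC/AUC of the candidate predictors of pulmonary hypertension.

    Predictors: VOL_AVG and VOL_TOT (indexed volume composites), manual MPA
    diameter, mean manual RPA/LPA diameter, and the greatest manual
    diameter.  Classification metrics are reported at the fixed cutoffs for
    VOL_AVG and the RPA/LPA diameter.
    """
    means = _subject_means(table)
    comps = vol_composites(table)
    predictors: dict[str, tuple[pd.Series, pd.Series, float | None]] = {}

    labelled = comps.dropna(subset=["VOL_AVG"])
    y = (labelled["group"] == "patient").astype(int)
    predictors["VOL_AVG"] = (labelled["VOL_AVG"], y, vol_cutoff)
    predictors["VOL_TOT"] = (labelled["VOL_TOT"], y, 2 * vol_cutoff)

    axial = means[means["method"] == "manual_axial"]
    if len(axial):
        wide = axial.pivot_table(index=["subject", "group"], columns="vessel", values="value").reset_index()
        y2 = (wide["group"] == "patient").astype(int)
        if "MPA" in wide:
            predictors["MPA_diameter_axial"] = (wide["MPA"], y2, None)
        if {"RPA", "LPA"} <= set(wide.columns):
            rl = (wide["RPA"] + wide["LPA"]) / 2.0
            predictors["RPA_LPA_diameter_axial"] = (rl, y2, diam_cutoff)
            greatest = wide[["MPA", "RPA", "LPA"]].max(axis=1) if "MPA" in wide else wide[["RPA", "LPA"]].max(axis=1)
            predictors["greatest_diameter_axial"] = (greatest, y2, None)

    rows = []
    for name, (scores, labels, cutoff) in predictors.items():
        ok = scores.notna()
        res = roc_auc(scores[ok], labels[ok])
        row = {
            "predictor": name,
            "auc": res.auc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p,
            "n": int(ok.sum()),
        }
        if cutoff is not None:
            row["cutoff"] = cutoff
            row.update(cutoff_metrics(scores[ok], labels[ok], cutoff))
        rows.append(row)
    return pd.DataFrame(rows)
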
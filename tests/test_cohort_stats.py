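from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pavol import cohort_stats as cs
from pavol.volumetry import VesselMeasurement


class TestDuBoisBsa:
    def test_reference_value(self):
        assert cs.du_bois_bsa(70, 180) == pytest.approx(1.886, abs=0.001)

    def test_power_law_homogeneity(self):
        base = cs.du_bois_bsa(70, 180)
        assert cs.du_bois_bsa(70 * 2 ** (1 / 0.425), 180) == pytest.approx(2 * base, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cs.du_bois_bsa(0, 180)
        with pytest.raises(ValueError):
            cs.du_bois_bsa(70, -1)


class TestIndexing:
    M = VesselMeasurement(vessel="MPA", volume_ul=3141.6, length_cm=4.0,
                          mean_d=19.8, min_d=18.0, max_d=21.0)

    def test_indexed_volume(self):
        idx = cs.index_measurements(self.M, 1.8)
        assert idx["vol3d"] == pytest.approx(3141.6 / (4.0 * 1.8), rel=1e-12)
        assert idx["vol3d"] == pytest.approx(436.3, abs=0.05)

    def test_corrected_diameter(self):
        idx = cs.index_measurements(self.M, 1.8)
        assert idx["d3d_mean"] == pytest.approx(11.0, abs=1e-9)

    def test_unit_bsa_is_identity_on_diameters(self):
        idx = cs.index_measurements(self.M, 1.0)
        assert idx["d3d_mean"] == self.M.mean_d
        assert idx["vol3d"] == self.M.volume_ul / self.M.length_cm

    def test_excluded_propagates(self):
        m = VesselMeasurement(vessel="RPA", excluded=True, reason="qc")
        assert cs.index_measurements(m, 1.8)["excluded"] is True


def tidy(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "vessel", "method", "read", "value"])


class TestVolComposites:
    def test_worked_group_means(self):
        """RPA 3522 and LPA 3093 give VOL_AVG 3307.5 and VOL_TOT 6615."""
        t = tidy([("s1", "patient", "RPA", "vol3d", "r1a", 3522.0),
                  ("s1", "patient", "LPA", "vol3d", "r1a", 3093.0)])
        out = cs.vol_composites(t)
        assert out.loc[0, "VOL_AVG"] == pytest.approx(3307.5)
        assert out.loc[0, "VOL_TOT"] == pytest.approx(6615.0)

    def test_symmetry(self):
        t = tidy([("s1", "control", "RPA", "vol3d", "r1a", 1700.0),
                  ("s1", "control", "LPA", "vol3d", "r1a", 1700.0)])
        out = cs.vol_composites(t)
        assert out.loc[0, "VOL_AVG"] == 1700.0
        assert out.loc[0, "VOL_TOT"] == 3400.0

    def test_missing_side_gives_missing_composites(self):
        t = tidy([("s1", "patient", "LPA", "vol3d", "r1a", 3093.0)])
        out = cs.vol_composites(t)
        assert np.isnan(out.loc[0, "VOL_AVG"]) and np.isnan(out.loc[0, "VOL_TOT"])


class TestGroupTtest:
    def test_identical_groups(self):
        t, p = cs.group_ttest([1.0, 1.0, 2.0], [1.0, 1.0, 2.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        _, p = cs.group_ttest([1, 2, 3], [101, 102, 103])
        assert p < 0.01

    def test_zero_variance_equal_means(self):
        assert cs.group_ttest([5, 5, 5], [5, 5])[1] == 1.0

    def test_matches_permutation_oracle(self):
        """Welch p vs the exact label-permutation null at n=8 per group."""
        rng = np.random.default_rng(12)
        for _ in range(3):
            a = rng.normal(0.0, 1.0, 8)
            b = rng.normal(0.8, 1.0, 8)
            t_obs, p_welch = cs.group_ttest(a, b)
            pooled = np.concatenate([a, b])
            idx = np.arange(16)
            count = 0
            total = 0
            for left in combinations(idx, 8):
                right = np.setdiff1d(idx, left)
                t_perm, _ = cs.group_ttest(pooled[list(left)], pooled[right])
                count += abs(t_perm) >= abs(t_obs) - 1e-12
                total += 1
            assert abs(p_welch - count / total) < 0.05


class TestIcc:
    def test_perfect_agreement(self):
        m = np.column_stack([np.arange(10.0)] * 3)
        for form in ("(1,1)", "(2,1)", "(3,1)"):
            assert cs.icc_shrout_fleiss(m, form).icc == pytest.approx(1.0)

    def test_hand_sums_of_squares_oracle(self):
        """5x2 matrix: ICC(2,1) from explicit hand-computed mean squares."""
        m = np.array([[9.0, 10.0], [6.0, 8.0], [8.0, 7.0], [7.0, 9.0], [10.0, 13.0]])
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((m - m.mean(1, keepdims=True) - m.mean(0, keepdims=True) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert cs.icc_shrout_fleiss(m, "(2,1)").icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        m = rng.normal(10, 2, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
        df = pd.DataFrame(m).reset_index().melt(id_vars="index", var_name="rater")
        res = pg.intraclass_corr(df, targets="index", raters="rater", ratings="value")
        res = res.set_index("Type")["ICC"]
        assert cs.icc_shrout_fleiss(m, "(1,1)").icc == pytest.approx(res["ICC(1,1)"], abs=1e-9)
        assert cs.icc_shrout_fleiss(m, "(2,1)").icc == pytest.approx(res["ICC(A,1)"], abs=1e-9)
        assert cs.icc_shrout_fleiss(m, "(3,1)").icc == pytest.approx(res["ICC(C,1)"], abs=1e-9)

    def test_rater_bias_hits_agreement_not_consistency(self):
        rng = np.random.default_rng(8)
        base = rng.normal(10, 3, size=(20, 2))
        base[:, 1] = base[:, 0] + rng.normal(0, 0.1, 20)
        biased = base.copy()
        biased[:, 1] += 5.0
        assert cs.icc_shrout_fleiss(biased, "(2,1)").icc < cs.icc_shrout_fleiss(base, "(2,1)").icc
        assert cs.icc_shrout_fleiss(biased, "(3,1)").icc == pytest.approx(
            cs.icc_shrout_fleiss(base, "(3,1)").icc, abs=1e-9)

    def test_variance_component_recovery(self):
        """ICC(3,1) recovers sigma_b^2/(sigma_b^2 + sigma_e^2) within 0.02
        at n=500 simulated subjects."""
        rng = np.random.default_rng(9)
        sb, se = 2.0, 1.0
        truth = sb**2 / (sb**2 + se**2)
        subj = rng.normal(0, sb, size=(500, 1))
        m = subj + rng.normal(0, se, size=(500, 3))
        assert cs.icc_shrout_fleiss(m, "(3,1)").icc == pytest.approx(truth, abs=0.02)

    def test_zero_between_subject_variance(self):
        m = np.tile([5.0, 5.0], (6, 1))
        assert cs.icc_shrout_fleiss(m, "(2,1)").icc == 0.0


class TestBlandAltman:
    def test_worked_triple(self):
        """Pairs (10,12),(11,9),(10,10): diffs -2,2,0 -> mean 0, SD 2,
        LoA +/- 3.92."""
        r = cs.bland_altman([10, 11, 10], [12, 9, 10])
        assert r.mean_diff == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(-3.92)
        assert r.loa_high == pytest.approx(3.92)

    def test_identity(self):
        r = cs.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mean_diff, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)

    def test_antisymmetry(self):
        a, b = np.array([10.0, 11, 10, 14]), np.array([12.0, 9, 10, 11])
        r1, r2 = cs.bland_altman(a, b), cs.bland_altman(b, a)
        assert r2.mean_diff == -r1.mean_diff
        assert r2.loa_low == pytest.approx(-r1.loa_high)
        assert r2.loa_high == pytest.approx(-r1.loa_low)


def empirical_roc_trapezoid(scores, labels):
    """Independent AUC oracle: trapezoidal area under the empirical ROC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    P, N = (labels == 1).sum(), (labels == 0).sum()
    for th in thresholds:
        tpr.append(np.sum((scores >= th) & (labels == 1)) / P)
        fpr.append(np.sum((scores >= th) & (labels == 0)) / N)
    return float(np.trapezoid(tpr, fpr))


class TestRoc:
    def test_perfect_separation(self):
        assert cs.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_interleaved(self):
        assert cs.roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_all_ties(self):
        assert cs.roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_pair_statistic_equals_trapezoid(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = rng.integers(6, 25)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(labels, 1.2), 1)  # ties likely
            ours = cs.roc_auc(scores, labels).auc
            assert ours == pytest.approx(empirical_roc_trapezoid(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.0)
        assert cs.roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([0, 1], 20)
        scores = rng.normal(labels, 1.0)
        r = cs.roc_auc(scores, labels)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.roc_auc([1, 2, 3], [1, 1, 1])


class TestCutoffMetrics:
    def test_worked_confusion_matrix(self):
        m = cs.cutoff_metrics([3000, 2600, 2400, 1000], [1, 1, 0, 0], 2500)
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "ppv": 1.0, "npv": 1.0}

    def test_cutoff_below_all(self):
        m = cs.cutoff_metrics([1, 2, 3, 4], [0, 1, 0, 1], 0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert np.isnan(m["npv"])  # no negative predictions -> 0/0

    def test_cutoff_above_all(self):
        m = cs.cutoff_metrics([1, 2, 3, 4], [0, 1, 0, 1], 10)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0
        assert np.isnan(m["ppv"])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.0)
        sens, spec = [], []
        for c in np.linspace(scores.min() - 1, scores.max() + 1, 40):
            m = cs.cutoff_metrics(scores, labels, c)
            sens.append(m["sensitivity"])
            spec.append(m["specificity"])
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)
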
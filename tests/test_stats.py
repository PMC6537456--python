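"""Repeated-measures statistics: oracle equality, degenerate cases,
null-uniformity, power calculation."""

import numpy as np
import pytest
from scipy import stats as sst

from myofatigue import (fisher_lsd, relative_change, rm_anova_oneway,
                        rm_power, rm_power_sample_size)
from myofatigue.errors import (IncompleteDesignError, InsufficientDataError,
                               InvalidControlError)


def _anova_oracle(x):
    """From-first-principles sums of squares with explicit loops."""
    x = np.asarray(x, float)
    n, m = x.shape
    grand = x.mean()
    ss_subj = sum(m * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_time = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(m))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(m))
    ss_err = ss_tot - ss_subj - ss_time
    f = (ss_time / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))
    p = sst.f.sf(f, m - 1, (n - 1) * (m - 1))
    return f, p, ss_err / ((n - 1) * (m - 1))


class TestRelativeChange:
    def test_basic(self):
        np.testing.assert_allclose(relative_change([10.0, 5.0]), [0.0, -50.0])

    def test_constant_series(self):
        np.testing.assert_allclose(relative_change([3.0, 3.0, 3.0]),
                                   np.zeros(3))

    def test_group_mean_modulus_ratio(self):
        """Ratio of printed group means 9.3 -> 6.1 kPa is -34.41%: the
        ratio-of-means statistic, distinct from the mean of per-subject
        ratios the cohort summary reports."""
        chg = relative_change([9.3, 8.1, 7.5, 7.4, 6.9, 6.7, 6.1])
        assert chg[-1] == pytest.approx(-34.41, abs=0.01)

    def test_zero_control_rejected(self):
        with pytest.raises(InvalidControlError):
            relative_change([0.0, 1.0])


class TestRmAnova:
    def test_constant_subjects_give_null(self):
        x = np.tile([[3.0], [5.0], [9.0]], (1, 4))
        res = rm_anova_oneway(x)
        assert res.f == 0.0
        assert res.p == 1.0

    def test_zero_error_degenerate_sentinel(self):
        """Pure additive time effect: SS_time = 6, SS_error = 0 ->
        F = inf sentinel, p = 0."""
        x = np.array([[10.0, 9.0, 8.0], [12.0, 11.0, 10.0],
                      [14.0, 13.0, 12.0]])
        res = rm_anova_oneway(x)
        n, m = 3, 3
        ss_time = n * sum((np.mean(x[:, j]) - x.mean()) ** 2
                          for j in range(m))
        assert ss_time == pytest.approx(6.0)
        assert res.f == np.inf and res.p == 0.0

    def test_matches_first_principles_oracle(self, rng):
        x = rng.normal(10.0, 2.0, (4, 3))
        res = rm_anova_oneway(x)
        f, p, _ = _anova_oracle(x)
        assert res.f == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        x = rng.normal(10.0, 2.0, (8, 5)) + np.linspace(0, 1, 5)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 5),
            "time": np.tile(np.arange(5), 8),
            "y": x.ravel(),
        })
        ref = pg.rm_anova(df, dv="y", within="time", subject="subject")
        res = rm_anova_oneway(x)
        assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_shift_invariances(self, rng):
        x = rng.normal(0.0, 1.0, (6, 4))
        base = rm_anova_oneway(x)
        global_shift = rm_anova_oneway(x + 42.0)
        subj_shift = rm_anova_oneway(x + rng.normal(0, 5, (6, 1)))
        assert global_shift.f == pytest.approx(base.f, rel=1e-9)
        assert subj_shift.f == pytest.approx(base.f, rel=1e-9)

    def test_null_pvalues_are_uniform(self):
        """Under no time effect, ANOVA p-values are Uniform(0,1)."""
        rng = np.random.default_rng(77)
        pvals = np.empty(2000)
        for i in range(2000):
            pvals[i] = rm_anova_oneway(
                rng.normal(0.0, 1.0, (10, 7))
                + rng.normal(0, 1, (10, 1))).p
        assert sst.kstest(pvals, "uniform").pvalue > 0.01

    def test_incomplete_design_rejected(self):
        with pytest.raises(IncompleteDesignError):
            rm_anova_oneway([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(InsufficientDataError):
            rm_anova_oneway([[1.0, 2.0]])


class TestFisherLsd:
    def test_identical_means_give_p_one(self, rng):
        noise = rng.normal(0, 1, (6, 1))
        x = np.tile(noise, (1, 4)) + rng.normal(0, 1e-12, (6, 4))
        res = fisher_lsd(x, require_omnibus=False)
        assert np.all(np.abs(res.t[1:]) < 1e-3)
        assert np.all(res.p[1:] > 0.99)

    def test_hand_computed_contrast(self, rng):
        x = rng.normal(10.0, 2.0, (5, 3)) + np.array([0.0, 1.0, 2.5])
        res_anova = rm_anova_oneway(x)
        _, _, ms_err = _anova_oracle(x)
        lsd = fisher_lsd(x, anova=res_anova, require_omnibus=False)
        for j in (1, 2):
            t = (x[:, j].mean() - x[:, 0].mean()) / np.sqrt(2 * ms_err / 5)
            p = 2 * sst.t.sf(abs(t), res_anova.df2)
            assert lsd.t[j] == pytest.approx(t, rel=1e-12)
            assert lsd.p[j] == pytest.approx(p, rel=1e-12)

    def test_omnibus_gate(self, rng):
        x = rng.normal(0.0, 1.0, (6, 4))   # null data
        res = fisher_lsd(x)
        if rm_anova_oneway(x).p >= 0.05:
            assert not res.tested
        assert np.isnan(res.p[0])   # reference column

    def test_paired_construction_equivalence(self, rng):
        """LSD t for one contrast equals the difference of means over the
        pooled-MS_error standard error of a paired design."""
        x = rng.normal(5.0, 1.0, (7, 4)) + np.linspace(0, 2, 4)
        res = rm_anova_oneway(x)
        lsd = fisher_lsd(x, anova=res, require_omnibus=False)
        se = np.sqrt(2.0 * res.ms_error / 7)
        for j in range(1, 4):
            assert lsd.t[j] == pytest.approx(
                (x[:, j] - x[:, 0]).mean() / se, rel=1e-12)


class TestPower:
    def test_study_sample_size(self):
        assert rm_power_sample_size(0.40, 0.05, 0.95, 7, 0.5, 1.0) == 11

    def test_monotone_in_effect_size(self):
        ns = [rm_power_sample_size(f, 0.05, 0.95, 7, 0.5)
              for f in (0.2, 0.3, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(ns) <= 0)

    def test_monotone_in_power_and_corr(self):
        assert rm_power_sample_size(0.4, 0.05, 0.99, 7, 0.5) >= \
            rm_power_sample_size(0.4, 0.05, 0.90, 7, 0.5)
        assert rm_power_sample_size(0.4, 0.05, 0.95, 7, 0.8) <= \
            rm_power_sample_size(0.4, 0.05, 0.95, 7, 0.3)

    def test_power_verified_by_simulation(self):
        """Analytic noncentral-F power at the returned n agrees with a
        10,000-replicate Monte-Carlo ANOVA simulation within +/-0.01."""
        f, m, corr = 0.40, 7, 0.5
        n = rm_power_sample_size(f, 0.05, 0.95, m, corr)
        analytic = rm_power(n, f, 0.05, m, corr)
        rng = np.random.default_rng(2718)
        a = np.zeros(m)
        a[0], a[1] = 1.0, -1.0
        mu = f * np.sqrt(m / np.sum((a - a.mean()) ** 2)) * a
        hits = 0
        reps = 10_000
        for _ in range(reps):
            y = (mu + rng.normal(0, np.sqrt(corr), (n, 1))
                 + rng.normal(0, np.sqrt(1 - corr), (n, m)))
            hits += rm_anova_oneway(y).p < 0.05
        assert hits / reps == pytest.approx(analytic, abs=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rm_power_sample_size(-0.1)
        with pytest.raises(ValueError):
            rm_power_sample_size(0.4, alpha=1.5)
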
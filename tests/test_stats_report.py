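"""Repeated-measures ANOVA, Bonferroni pairwise tests and cohort summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from renoximetry.stats_report import (
    DegenerateDataError,
    pairwise_bonferroni,
    rm_anova,
    significance_stars,
    summarize_cohort,
)


def long_table(matrix, conditions=None, parameter="svo2", site="left_kidney"):
    """Long-format table from a subjects x conditions value matrix."""
    matrix = np.asarray(matrix, dtype=float)
    conditions = conditions or [f"c{j}" for j in range(matrix.shape[1])]
    rows = []
    for i, row in enumerate(matrix):
        for j, value in enumerate(row):
            if np.isnan(value):
                continue
            rows.append(dict(subject=f"S{i}", condition=conditions[j], site=site,
                             parameter=parameter, value=value))
    return pd.DataFrame(rows)


def anova_oracle(matrix):
    """From-scratch sums-of-squares decomposition on a complete matrix."""
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


TOY = [
    [10.0, 12.0, 14.0],
    [11.0, 12.5, 15.0],
    [9.0, 11.0, 12.5],
    [10.5, 13.0, 14.5],
]


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        res = rm_anova(long_table(TOY))
        assert res.f_stat == pytest.approx(anova_oracle(TOY), abs=1e-10)
        assert (res.df_num, res.df_den) == (2, 6)
        assert res.n_subjects_used == 4

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = long_table(TOY)
        pg = pingouin.rm_anova(data=df, dv="value", within="condition", subject="subject")
        res = rm_anova(df)
        p_col = "p_unc" if "p_unc" in pg.columns else "p-unc"
        assert res.f_stat == pytest.approx(float(pg["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(pg[p_col].iloc[0]), rel=1e-9)

    def test_invariant_to_per_subject_constant(self):
        shifted = np.asarray(TOY) + np.array([[5.0], [-3.0], [100.0], [0.0]])
        assert rm_anova(long_table(shifted)).f_stat == pytest.approx(
            rm_anova(long_table(TOY)).f_stat, rel=1e-10
        )

    def test_listwise_deletion_of_incomplete_subjects(self):
        data = np.asarray(TOY + [[10.0, np.nan, 13.0]])
        res = rm_anova(long_table(data))
        assert res.n_subjects_used == 4  # incomplete fifth subject dropped

    def test_null_type_one_error_rate(self):
        # No condition effect, huge subject effects: F calibrated at alpha 0.05.
        rng = np.random.default_rng(8)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            y = 10.0 * rng.standard_normal((10, 1)) + rng.standard_normal((10, 4))
            if rm_anova(long_table(y)).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_degenerate_zero_error_variance(self):
        constant = np.tile([[10.0], [12.0], [14.0]], (1, 3))
        with pytest.raises(DegenerateDataError):
            rm_anova(long_table(constant))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match=">= 3"):
            rm_anova(long_table(TOY[:2]))

    def test_greenhouse_geisser_option(self):
        res = rm_anova(long_table(TOY), correction="gg")
        assert res.gg_epsilon is not None
        assert 0.5 <= res.gg_epsilon <= 1.0
        assert res.p_value >= rm_anova(long_table(TOY)).p_value - 1e-12


class TestPairwiseBonferroni:
    def test_adjustment_multiplies_and_caps(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.0, 1.0, (8, 4))
        y[:, 1] += 3.0  # one strong contrast
        results = pairwise_bonferroni(long_table(y))
        assert len(results) == 6  # 4 conditions -> 6 pairs
        for pw in results:
            assert pw.n_comparisons == 6
            assert pw.adjusted_p == pytest.approx(min(1.0, pw.raw_p * 6), rel=1e-12)
            assert pw.adjusted_p <= 1.0

    def test_adjusted_monotone_in_raw(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0.0, 1.0, (9, 4)) + np.array([0.0, 0.5, 1.5, 3.0])
        results = sorted(pairwise_bonferroni(long_table(y)), key=lambda r: r.raw_p)
        adj = [r.adjusted_p for r in results]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_identical_samples_incomparable(self):
        y = np.asarray(TOY)
        y[:, 1] = y[:, 0]  # two identical conditions
        results = pairwise_bonferroni(long_table(y))
        flagged = [r for r in results if r.note]
        assert len(flagged) == 1
        assert np.isnan(flagged[0].raw_p) and np.isnan(flagged[0].adjusted_p)
        assert "incomparable" in flagged[0].note


class TestSummaries:
    def test_single_record_has_zero_sd(self):
        df = pd.DataFrame(
            [dict(subject="S0", condition="baseline", site="left_kidney",
                  parameter="bfr", value=412.0)]
        )
        out = summarize_cohort(df)
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "mean_rounded"] == 410.0  # tens rounding for flows

    def test_saturations_displayed_in_percent(self):
        df = pd.DataFrame(
            [
                dict(subject=s, condition="baseline", site="left_kidney",
                     parameter="svo2", value=v)
                for s, v in [("S0", 0.90), ("S1", 0.94)]
            ]
        )
        out = summarize_cohort(df)
        assert out.loc[0, "mean_rounded"] == 92.0
        assert "92" in out.loc[0, "display"]

    def test_mean_of_differences_equals_difference_of_means(self):
        supra = np.array([2400.0, 2440.0])
        infra = np.array([1380.0, 1400.0])
        rows = []
        for i in range(2):
            rows.append(dict(subject=f"S{i}", condition="baseline", site="bilateral",
                             parameter="delta_bfr", value=supra[i] - infra[i]))
        out = summarize_cohort(pd.DataFrame(rows))
        assert out.loc[0, "mean"] == pytest.approx(supra.mean() - infra.mean())

    def test_significance_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""
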
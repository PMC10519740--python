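import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ace_subtypes import SimConfig, simulate_cohort
from ace_subtypes.pgs_groups import (ancova_adjusted, assign_quadrant,
                                     one_way_anova, pgs_quadrant_report,
                                     pgs_table, tukey_posthoc, two_sample_t)


class TestAssignQuadrant:
    @pytest.mark.parametrize("isi,label,expected", [
        (9, "short", 1),
        (8, "short", 2),
        (8, "normal_long", 4),
        (28, "normal_long", 3),
        (0, "short", 2),
    ])
    def test_mapping(self, isi, label, expected):
        assert assign_quadrant(isi, label) == expected

    def test_missing_inputs_excluded(self):
        assert assign_quadrant(np.nan, "short") is None
        assert assign_quadrant(9, None) is None


class TestOneWayAnova:
    def test_identical_group_means_give_zero_f(self):
        values = [1, 2, 3, 1, 2, 3]
        labels = ["a"] * 3 + ["b"] * 3
        f, p = one_way_anova(values, labels)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_worked_three_group_example(self, rng):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0],
                  "c": [5.0, 5.5, 6.5]}
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 3)
        f, p = one_way_anova(values, labels)
        # explicit sum-of-squares oracle
        grand = values.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                  for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_oracle, abs=1e-12)
        # and the library cross-check
        f_sp, p_sp = stats.f_oneway(*groups.values())
        assert f == pytest.approx(f_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-10)

    def test_null_pvalues_are_uniform(self, rng):
        pvals = []
        for _ in range(500):
            v = rng.standard_normal(80)
            labels = np.repeat([1, 2, 3, 4], 20)
            pvals.append(one_way_anova(v, labels)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(12) + 0.3
        f, pf = one_way_anova(np.concatenate([a, b]),
                              ["a"] * 15 + ["b"] * 12)
        t, pt = two_sample_t(a, b)
        assert f == pytest.approx(t ** 2, abs=1e-10)
        assert pf == pytest.approx(pt, abs=1e-10)

    def test_constant_values_signalled(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestAncova:
    def test_constant_covariate_equals_plain_anova(self, rng):
        v = rng.standard_normal(60)
        labels = np.repeat(["a", "b", "c"], 20)
        f0, p0 = one_way_anova(v, labels)
        f1, p1 = ancova_adjusted(v, labels, np.ones(60))
        assert f1 == pytest.approx(f0, abs=1e-10)
        assert p1 == pytest.approx(p0, abs=1e-10)

    def test_independent_covariate_close_to_anova(self, rng):
        v = rng.standard_normal(400)
        labels = np.repeat(["a", "b", "c", "d"], 100)
        cov = rng.standard_normal(400)
        f0, _ = one_way_anova(v, labels)
        f1, _ = ancova_adjusted(v, labels, cov)
        assert f1 == pytest.approx(f0, rel=0.1)

    def test_group_effect_explained_by_covariate(self, rng):
        labels = np.repeat(["a", "b"], 100)
        cov = np.where(labels == "a", 0.0, 1.0) + 0.01 * rng.standard_normal(200)
        v = 2.0 * cov + 0.01 * rng.standard_normal(200)
        f_adj, p_adj = ancova_adjusted(v, labels, cov)
        f_raw, _ = one_way_anova(v, labels)
        assert f_adj < 0.05 * f_raw

    def test_denominator_df_reduced_by_covariates(self, rng):
        # with one covariate, p must correspond to (k-1, n-k-1) df
        v = rng.standard_normal(30)
        labels = np.repeat(["a", "b", "c"], 10)
        cov = rng.standard_normal(30)
        f, p = ancova_adjusted(v, labels, cov)
        assert p == pytest.approx(float(stats.f.sf(f, 2, 30 - 3 - 1)),
                                  abs=1e-12)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_flips_sign_keeps_p(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(9) + 1
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_formula_on_hand_example(self):
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([4.0, 5.0, 5.5, 6.0, 6.5])
        t, p = two_sample_t(a, b)
        sp2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 5))
        assert t == pytest.approx(t_oracle, abs=1e-12)
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-10)

    def test_zero_pooled_variance_signalled(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestQuadrantReport:
    def _hand_cohort(self):
        return pd.DataFrame({
            "pair_id": range(1, 9), "zyg": ["MZ"] * 8,
            "sex1": ["F", "M"] * 4, "sex2": ["F", "M"] * 4,
            "age": [16.0] * 8,
            "hours1": [6, 6, 6, 6, 8, 8, 8, 8],
            "hours2": [8.0] * 8,
            "isi1": [10, 12, 4, 6, 10, 12, 4, 6],
            "isi2": [5.0] * 8,
            "pgs": [0.5, 0.7, 0.1, 0.3, -0.2, 0.0, -0.5, -0.3],
        })

    def test_hand_cohort_descriptives(self):
        rep = pgs_quadrant_report(self._hand_cohort(), pgs_cols=("pgs",))[0]
        assert rep.n_by_quadrant == {1: 2, 2: 2, 3: 2, 4: 2}
        assert rep.mean_by_quadrant[1] == pytest.approx(0.6)
        assert rep.sd_by_quadrant[4] == pytest.approx(np.std([-0.5, -0.3],
                                                             ddof=1))
        assert rep.n_excluded == 0

    def test_quadrant_counts_conserve_n(self, default_cohort):
        rep = pgs_quadrant_report(default_cohort)[0]
        assert sum(rep.n_by_quadrant.values()) + rep.n_excluded \
            == len(default_cohort)

    def test_null_pgs_rarely_significant(self):
        rejections = 0
        for seed in range(40):
            coh = simulate_cohort(SimConfig(n_pairs=800, seed=1000 + seed,
                                            pgs_r2=0.0))
            rep = pgs_quadrant_report(coh, pgs_cols=("pgs_p1",))[0]
            rejections += rep.anova_p < 0.05
        # binomial(40, .05): 3 SE above the mean is ~6 rejections
        assert rejections <= 6

    def test_monotone_shift_detected_and_direction_reported(self, rng):
        # quadrant means shifted 4 < 3 < 2 < 1 by 0.1 SD steps at the
        # reference group sizes
        sizes = {1: 110, 2: 70, 3: 391, 4: 2495}
        rows = []
        for q, n in sizes.items():
            rows.append(pd.DataFrame({
                "quadrant": q,
                "pgs": rng.standard_normal(n) + 0.1 * (4 - q)}))
        df = pd.concat(rows, ignore_index=True)
        f, p = one_way_anova(df["pgs"], df["quadrant"])
        means = df.groupby("quadrant")["pgs"].mean()
        assert means[1] > means[4]
        assert p < 0.5  # direction check; power at these sizes is modest

    def test_report_invariant_to_affine_pgs_transform(self, small_cohort):
        rep1 = pgs_quadrant_report(small_cohort, pgs_cols=("pgs_p1",))[0]
        coh2 = small_cohort.copy()
        coh2["pgs_p1"] = 3.0 * coh2["pgs_p1"] + 1.0
        rep2 = pgs_quadrant_report(coh2, pgs_cols=("pgs_p1",))[0]
        assert rep1.anova_f == pytest.approx(rep2.anova_f, rel=1e-10)
        assert rep1.p_1_vs_3 == pytest.approx(rep2.p_1_vs_3, rel=1e-10)

    def test_report_invariant_to_row_order(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=1)
        rep1 = pgs_quadrant_report(small_cohort, pgs_cols=("pgs_p1",))[0]
        rep2 = pgs_quadrant_report(shuffled, pgs_cols=("pgs_p1",))[0]
        assert rep1.anova_f == pytest.approx(rep2.anova_f, rel=1e-10)

    def test_table_flattening(self, small_cohort):
        reports = pgs_quadrant_report(small_cohort)
        table = pgs_table(reports)
        assert len(table) == 12  # 3 thresholds x 4 quadrants
        assert {"mean_pgs", "anova_p", "p_1_vs_3"} <= set(table.columns)


class TestTukey:
    def test_matches_scipy_pvalues(self, rng):
        v = np.concatenate([rng.standard_normal(20) + d for d in (0, 0.5, 1)])
        labels = np.repeat(["a", "b", "c"], 20)
        table = tukey_posthoc(v, labels)
        assert len(table) == 3
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
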
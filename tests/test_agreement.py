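"""Diagnostic accuracy, Bland-Altman, ICC and paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synthlge as sl
from synthlge.agreement import clopper_pearson


class TestAccuracy:
    def test_patient_level_sensitivity(self):
        table = sl.ContingencyTable(tp=22, fp=1, fn=1, tn=190, level="patient")
        m = sl.accuracy(table)
        assert sl.round_half_up(m.sensitivity.value) == 96
        assert sl.round_half_up(m.specificity.value) == 99
        assert sl.round_half_up(m.npv.value, 1) == 99.5

    def test_subsegment_level_ppv(self):
        table = sl.ContingencyTable(tp=97, fp=3, fn=1, tn=5891)
        m = sl.accuracy(table)
        assert sl.round_half_up(m.ppv.value, 1) == 97.0
        assert sl.round_half_up(m.sensitivity.value) == 99
        assert sl.round_half_up(m.specificity.value) == 100
        assert sl.round_half_up(m.npv.value, 1) == 100.0

    def test_perfect_table(self):
        m = sl.accuracy(sl.ContingencyTable(tp=10, fp=0, fn=0, tn=90))
        for metric in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert metric.value == 100.0
            assert metric.ci_low <= metric.value <= metric.ci_high

    def test_zero_denominator_reported_undefined(self):
        m = sl.accuracy(sl.ContingencyTable(tp=0, fp=0, fn=0, tn=50))
        assert m.sensitivity.value is None
        assert m.ppv.value is None
        assert m.specificity.value == 100.0

    def test_clopper_pearson_brackets_the_point(self):
        lo, hi = clopper_pearson(22, 23)
        assert lo <= 22 / 23 <= hi
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0


class TestBuildContingency:
    def test_identical_vectors(self):
        v = np.array([True, False, True, False])
        t = sl.build_contingency(v, v)
        assert (t.fp, t.fn) == (0, 0)
        assert t.total == 4

    def test_reproduces_printed_subsegment_counts(self):
        """97 concordant positives, 1 reference-only, 3 index-only and the
        rest of 214 x 28 double-negative give 5,891 true negatives."""
        total = 214 * 28
        ref = np.zeros(total, dtype=bool)
        idx = np.zeros(total, dtype=bool)
        ref[:97] = idx[:97] = True
        ref[97] = True  # missed by the index channel
        idx[98:101] = True  # index-only
        t = sl.build_contingency(idx, ref)
        assert (t.tp, t.fn, t.fp, t.tn) == (97, 1, 3, 5891)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_matches_exhaustive_four_way_count(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(60) < 0.3
        b = rng.random(60) < 0.3
        t = sl.build_contingency(a, b)
        counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for x, y in zip(a, b):
            counts[{(1, 1): "tp", (1, 0): "fp", (0, 1): "fn", (0, 0): "tn"}[(x, y)]] += 1
        assert (t.tp, t.fp, t.fn, t.tn) == tuple(counts.values())
        assert t.total == 60

    def test_patient_level_collapses_by_any(self):
        idx = np.array([[True, False], [False, False], [False, True]])
        ref = np.array([[False, True], [False, False], [False, False]])
        t = sl.build_contingency(idx, ref, level="patient")
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 0, 1)


class TestBlandAltman:
    def test_identical_inputs(self):
        ba = sl.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == 0.0
        assert ba.sd_difference == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)

    def test_plus_minus_one_closed_form(self):
        ba = sl.bland_altman([1.0, -1.0], [0.0, 0.0])
        assert ba.mean_difference == 0.0
        assert ba.sd_difference == pytest.approx(np.sqrt(2), abs=1e-12)
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2), abs=1e-12)

    def test_matches_direct_recomputation(self, rng):
        a = rng.normal(2.0, 1.0, 50)
        b = a + rng.normal(-0.03, 0.15, 50)
        ba = sl.bland_altman(a, b)
        d = a - b
        mean = d.sum() / len(d)
        sd = np.sqrt(((d - mean) ** 2).sum() / (len(d) - 1))
        assert ba.mean_difference == pytest.approx(mean, abs=1e-12)
        assert ba.sd_difference == pytest.approx(sd, abs=1e-12)
        assert ba.loa_low == pytest.approx(mean - 1.96 * sd, abs=1e-12)


class TestICC:
    def test_identical_nonconstant_inputs(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert sl.icc_absolute(a, a).icc == pytest.approx(1.0)

    def test_variance_component_recovery(self, rng):
        """sigma2_subject = 9, sigma2_error = 1 gives ICC 0.9 at n = 500."""
        subj = rng.normal(0.0, 3.0, 500)
        a = subj + rng.normal(0.0, 1.0, 500)
        b = subj + rng.normal(0.0, 1.0, 500)
        res = sl.icc_absolute(a, b)
        assert res.icc == pytest.approx(0.9, abs=0.02)
        assert res.ci_low < res.icc < res.ci_high

    def test_constant_bias_penalised_unlike_pearson(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = a + 2.0
        res = sl.icc_absolute(a, b)
        assert res.icc < 1.0
        assert sl.paired_tests(a, b).pearson_r == pytest.approx(1.0)

    def test_agrees_with_pingouin(self, rng):
        """Independent cross-check of ICC(2,1) against pingouin's ICC2."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a = rng.normal(5.0, 2.0, 40)
        b = a + rng.normal(0.2, 0.8, 40)
        res = sl.icc_absolute(a, b)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile([0, 1], 40),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds the CI to two decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=6e-3)


class TestPairedTests:
    def test_all_zero_differences_convention(self):
        res = sl.paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.wilcoxon_p == 1.0
        assert any("zero" in n for n in res.notes)

    def test_constant_input_r_undefined(self):
        res = sl.paired_tests([1.0, 1.0, 1.0], [0.5, 1.0, 2.0])
        assert np.isnan(res.pearson_r)
        assert any("constant" in n for n in res.notes)

    def test_anticorrelated_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = sl.paired_tests(a, -a)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_paired_t_matches_closed_form(self, rng):
        a = rng.normal(2.0, 1.0, 30)
        b = a + rng.normal(0.1, 0.2, 30)
        res = sl.paired_tests(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.ttest_stat == pytest.approx(t, abs=1e-9)


class TestRunStudy:
    def test_zero_jitter_cohort_is_perfect(self):
        cohort = sl.make_cohort(
            sl.CohortSpec(n_patients=30, n_positive=6, reader_jitter_sd=0.0, seed=3)
        )
        rep = sl.run_cohort_study(cohort)
        for m in (rep.patient_metrics, rep.subsegment_metrics):
            assert m.sensitivity.value == 100.0
            assert m.specificity.value == 100.0
        assert rep.bland_altman.mean_difference == 0.0
        assert rep.tests.pearson_r == pytest.approx(1.0)
        assert rep.excluded_patients == ()

    def test_reproduced_discordance_pattern_patient_npv(self):
        """The 23-positive / 214-patient cohort with one FN and one FP patient
        yields patient-level NPV 99.5 at one decimal."""
        cohort = sl.make_cohort(
            sl.CohortSpec(n_patients=214, n_positive=23,
                          n_false_negative_patients=1, n_false_positive_patients=1,
                          seed=1)
        )
        rep = sl.run_cohort_study(cohort)
        t = rep.patient_table
        assert (t.tp, t.fn, t.fp, t.tn) == (22, 1, 1, 190)
        assert sl.round_half_up(rep.patient_metrics.npv.value, 1) == 99.5
        assert sl.round_half_up(rep.patient_metrics.sensitivity.value) == 96
        assert sl.round_half_up(rep.prevalence_pct, 1) == 10.7
        assert rep.n_quantitative == t.tp
        assert len(rep.excluded_patients) == 2

    def test_subsegment_count_conservation(self):
        cohort = sl.make_cohort(sl.CohortSpec(n_patients=25, n_positive=5, seed=8))
        rep = sl.run_cohort_study(cohort)
        assert rep.subsegment_table.total == 25 * 28
        assert rep.patient_table.total == 25
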
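"""Whole-cohort agreement between two quantification channels.

Generates a 214-patient cohort (23 scar-positive) with 0.1 g reader jitter
on both channels and one injected false-negative and false-positive patient,
then computes the full study-level comparison: contingency tables at patient
and subsegment level, accuracy metrics with exact binomial CIs, Pearson
correlation, Bland-Altman limits of agreement and ICC(2,1) on the
concordant-positive patients.
"""

import synthlge as sl

cohort = sl.make_cohort(
    sl.CohortSpec(
        n_patients=214,
        n_positive=23,
        n_false_negative_patients=1,
        n_false_positive_patients=1,
        fp_subsegments=3,
        reader_jitter_sd=0.1,
        seed=3,
    )
)
rep = sl.run_cohort_study(cohort)

t = rep.patient_table
print(f"patient contingency: TP={t.tp} FN={t.fn} FP={t.fp} TN={t.tn}")
pm = rep.patient_metrics
print(f"patient sensitivity {sl.round_half_up(pm.sensitivity.value)}% "
      f"({pm.sensitivity.ci_low:.1f}-{pm.sensitivity.ci_high:.1f}), "
      f"NPV {sl.round_half_up(pm.npv.value, 1)}%")
print(f"prevalence: {sl.round_half_up(rep.prevalence_pct, 1)}%")
print(f"excluded from quantitative analysis (discordant patients): "
      f"{list(rep.excluded_patients)}")

ba = rep.bland_altman
print(f"\nquantitative agreement over {rep.n_quantitative} concordant positives:")
print(f"  Pearson r = {rep.tests.pearson_r:.3f}")
print(f"  Bland-Altman: mean diff {ba.mean_difference:+.3f} g, "
      f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] g")
print(f"  ICC(2,1) = {rep.icc.icc:.3f} ({rep.icc.ci_low:.3f}-{rep.icc.ci_high:.3f})")
print(f"  median mass: index {rep.tests.median_a:.2f} g, "
      f"reference {rep.tests.median_b:.2f} g (Wilcoxon p = {rep.tests.wilcoxon_p:.2f})")
# With 0.1 g jitter on few-gram scars the channels agree almost perfectly:
# r and ICC near 0.99 and limits of agreement of about +/-0.28 g.
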
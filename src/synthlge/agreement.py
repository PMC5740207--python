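"""Diagnostic-accuracy and method-agreement statistics.

Given paired scar calls and masses from two quantification channels (an
index method and a reference standard), this module computes:

* contingency tables at the patient and subsegment level (patient level
  collapses a patient's 28 subsegment calls by "any positive"),
* sensitivity / specificity / PPV / NPV with exact Clopper-Pearson
  binomial confidence intervals,
* Pearson correlation, Bland-Altman mean difference with 1.96-SD limits of
  agreement, the paired t test and the Wilcoxon signed-rank test,
* the intraclass correlation coefficient ICC(2,1): two-way random effects,
  absolute agreement, single measures, with the McGraw-Wong F-based CI.

`run_study` ties these together for a whole cohort, excluding patients whose
patient-level calls disagree between the channels from the quantitative
agreement analysis (they have no meaningful paired mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .core import SEGMENTS_PER_LEVEL


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, matching how clinical papers display percents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "subsegment"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts cannot be negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricCI:
    value: float | None  # percent; None when the denominator is zero
    ci_low: float | None
    ci_high: float | None


@dataclass(frozen=True)
class AccuracyMetrics:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    ci_method: str = "clopper-pearson"

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: MetricCI = getattr(self, name)
            out[name] = {"value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high}
        out["ci_method"] = self.ci_method
        return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for k successes out of n, as proportions."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _metric(k: int, n: int, alpha: float) -> MetricCI:
    if n == 0:
        return MetricCI(None, None, None)
    lo, hi = clopper_pearson(k, n, alpha)
    return MetricCI(100.0 * k / n, 100.0 * lo, 100.0 * hi)


def accuracy(table: ContingencyTable, alpha: float = 0.05) -> AccuracyMetrics:
    """Sensitivity, specificity, PPV and NPV in percent with exact CIs.

    Metrics with a zero denominator are reported as undefined (None), never
    as zero. Values are unrounded; round for display with
    :func:`round_half_up`.
    """
    return AccuracyMetrics(
        sensitivity=_metric(table.tp, table.tp + table.fn, alpha),
        specificity=_metric(table.tn, table.tn + table.fp, alpha),
        ppv=_metric(table.tp, table.tp + table.fp, alpha),
        npv=_metric(table.tn, table.tn + table.fn, alpha),
    )


def build_contingency(
    calls_index, calls_reference, level: str = "subsegment"
) -> ContingencyTable:
    """Cross-tabulate paired boolean calls.

    At ``level="patient"`` the inputs are (n_patients, n_subsegments)
    matrices collapsed by any-positive per patient; at ``level="subsegment"``
    the inputs are flattened element-wise.
    """
    a = np.asarray(calls_index, dtype=bool)
    b = np.asarray(calls_reference, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired call arrays must have equal shape")
    if level == "patient":
        if a.ndim != 2:
            raise ValueError("patient level expects (n_patients, n_subsegments) matrices")
        a = a.any(axis=1)
        b = b.any(axis=1)
    elif level == "subsegment":
        a = a.ravel()
        b = b.ravel()
    else:
        raise ValueError("level must be 'patient' or 'subsegment'")
    return ContingencyTable(
        tp=int(np.sum(a & b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
        level=level,
    )


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(a, b) -> BlandAltman:
    """Mean difference (a - b), its SD (n-1) and 1.96-SD limits of agreement."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, len(d))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way random, absolute agreement, single measures (ICC(2,1))"


def icc_absolute(a, b, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) from the two-way ANOVA mean squares, with F-based CI.

    Subjects are rows, the two measurement channels are columns. Absolute
    agreement is assessed: a constant offset between channels lowers the
    ICC even though it leaves the Pearson correlation at 1.
    """
    y = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations for the ICC")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else np.nan

    # McGraw & Wong (1996) confidence bounds for ICC(A,1)
    if np.isfinite(icc) and mse > 0:
        a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b_ = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_):
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        else:
            lo = hi = 1.0
    else:
        lo = hi = np.nan
    return ICCResult(float(icc), float(lo), float(hi))


@dataclass(frozen=True)
class PairedTests:
    wilcoxon_p: float
    ttest_p: float
    ttest_stat: float
    pearson_r: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    notes: tuple[str, ...] = ()


def paired_tests(a, b) -> PairedTests:
    """Wilcoxon signed-rank, paired t, Pearson r, and medians with IQRs.

    Zero differences are dropped from the Wilcoxon statistic (Wilcoxon's
    original rule); when every difference is zero the p-value is reported as
    1.0 with a note. Pearson r on constant input is undefined and reported
    as NaN with a note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    notes = []
    d = a - b
    if np.all(d == 0):
        wp = 1.0
        notes.append("all differences zero; Wilcoxon p set to 1 by convention")
        tp_, tstat = 1.0, 0.0
    else:
        wp = float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)
        tres = sps.ttest_rel(a, b)
        tp_, tstat = float(tres.pvalue), float(tres.statistic)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = np.nan
        notes.append("constant input; Pearson r undefined")
    else:
        r = float(sps.pearsonr(a, b).statistic)

    def iqr(x):
        return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))

    return PairedTests(
        wilcoxon_p=wp,
        ttest_p=tp_,
        ttest_stat=tstat,
        pearson_r=r,
        median_a=float(np.median(a)),
        iqr_a=iqr(a),
        median_b=float(np.median(b)),
        iqr_b=iqr(b),
        notes=tuple(notes),
    )


@dataclass
class AgreementReport:
    """Everything the study-level comparison of two channels produces."""

    patient_table: ContingencyTable
    subsegment_table: ContingencyTable
    patient_metrics: AccuracyMetrics
    subsegment_metrics: AccuracyMetrics
    prevalence_pct: float
    n_patients: int
    n_quantitative: int  # concordant-positive patients entering mass analysis
    excluded_patients: tuple[int, ...]
    bland_altman: BlandAltman | None
    icc: ICCResult | None
    tests: PairedTests | None

    def as_dict(self) -> dict:
        def tbl(t: ContingencyTable) -> dict:
            return {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "total": t.total}

        out = {
            "patient_table": tbl(self.patient_table),
            "subsegment_table": tbl(self.subsegment_table),
            "patient_metrics": self.patient_metrics.as_dict(),
            "subsegment_metrics": self.subsegment_metrics.as_dict(),
            "prevalence_pct": self.prevalence_pct,
            "n_patients": self.n_patients,
            "n_quantitative": self.n_quantitative,
            "excluded_patients": list(self.excluded_patients),
        }
        if self.bland_altman is not None:
            ba = self.bland_altman
            out["bland_altman"] = {
                "mean_difference_g": ba.mean_difference,
                "sd_difference_g": ba.sd_difference,
                "loa_low_g": ba.loa_low,
                "loa_high_g": ba.loa_high,
                "n": ba.n,
            }
        if self.icc is not None:
            out["icc"] = {
                "icc": self.icc.icc,
                "ci_low": self.icc.ci_low,
                "ci_high": self.icc.ci_high,
                "model": self.icc.model,
            }
        if self.tests is not None:
            t = self.tests
            out["paired_tests"] = {
                "wilcoxon_p": t.wilcoxon_p,
                "ttest_p": t.ttest_p,
                "ttest_stat": t.ttest_stat,
                "pearson_r": t.pearson_r,
                "median_index_g": t.median_a,
                "iqr_index_g": list(t.iqr_a),
                "median_reference_g": t.median_b,
                "iqr_reference_g": list(t.iqr_b),
                "notes": list(t.notes),
            }
        return out


def run_study(
    calls_index,
    calls_reference,
    masses_index,
    masses_reference,
) -> AgreementReport:
    """Full study-level comparison of an index channel against the reference.

    Inputs: (n_patients, n_subsegments) boolean call matrices and per-patient
    total masses (grams) for each channel. Patients whose patient-level calls
    disagree between channels are excluded from the quantitative agreement
    statistics (correlation, Bland-Altman, ICC, paired tests), which run on
    the concordant-positive patients.
    """
    ci = np.asarray(calls_index, dtype=bool)
    cr = np.asarray(calls_reference, dtype=bool)
    mi = np.asarray(masses_index, dtype=float)
    mr = np.asarray(masses_reference, dtype=float)
    if ci.shape != cr.shape or ci.ndim != 2:
        raise ValueError("call matrices must be equal-shape (n_patients, n_subsegments)")
    n_patients = ci.shape[0]
    if mi.shape != (n_patients,) or mr.shape != (n_patients,):
        raise ValueError("need one mass per patient and channel")

    patient_table = build_contingency(ci, cr, level="patient")
    subseg_table = build_contingency(ci, cr, level="subsegment")

    pos_i = ci.any(axis=1)
    pos_r = cr.any(axis=1)
    discordant = pos_i != pos_r
    concordant_pos = pos_i & pos_r

    prevalence = 100.0 * pos_r.sum() / n_patients

    ba = icc = tests = None
    n_quant = int(concordant_pos.sum())
    if n_quant >= 2:
        ba = bland_altman(mi[concordant_pos], mr[concordant_pos])
        tests = paired_tests(mi[concordant_pos], mr[concordant_pos])
    if n_quant >= 3:
        icc = icc_absolute(mi[concordant_pos], mr[concordant_pos])

    return AgreementReport(
        patient_table=patient_table,
        subsegment_table=subseg_table,
        patient_metrics=accuracy(patient_table),
        subsegment_metrics=accuracy(subseg_table),
        prevalence_pct=float(prevalence),
        n_patients=n_patients,
        n_quantitative=n_quant,
        excluded_patients=tuple(int(i) for i in np.flatnonzero(discordant)),
        bland_altman=ba,
        icc=icc,
        tests=tests,
    )


def run_cohort_study(cohort) -> AgreementReport:
    """Convenience wrapper: :func:`run_study` on a phantom CohortDataset."""
    return run_study(
        cohort.calls_matrix("index"),
        cohort.calls_matrix("reference"),
        cohort.masses("index"),
        cohort.masses("reference"),
    )
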
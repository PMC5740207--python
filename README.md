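# synthlge

Early synthetic gadolinium enhancement (ESGE) analysis for cardiac MRI, as a
tested Python library with a thin CLI.

## The problem

Myocardial scar is conventionally assessed with late gadolinium enhancement
(LGE) imaging acquired ~10 minutes after a second contrast bolus. A
post-contrast T1 map acquired only 2–3 minutes after the first bolus already
contains the same information: from the per-pixel T1, a phase-sensitive
inversion-recovery (PSIR) image can be *computed* at any inversion time,
replacing the conventional acquisition and shortening the exam. This package
implements the full analysis chain needed to study that substitution, for
imaging scientists who want a reproducible, data-free testbed:

1. **`phantom`** — synthetic short-axis left-ventricle T1 maps (5 slices:
   2 basal, 2 mid, 1 apical) with scar wedges of known mass, simulated MOLLI
   stacks, and whole-cohort datasets (default: 214 patients, 23 scar-positive).
2. **`relaxometry`** — MOLLI 4(1)3(1)2 timing (9 images in 11 heartbeats,
   initial TI 100 ms, 80 ms increments) and per-pixel fitting of the
   three-parameter model *S(t) = A − B e^(−t/T1\*)* with exhaustive polarity
   restoration and the Look-Locker correction *T1 = T1\*(B/A − 1)*.
3. **`synth_ir`** — synthetic PSIR images *S(TI) = 1 − 2 e^(−TI/T1)* at any
   TI; the default series is 40 images from 200 ms in 25 ms steps.
4. **`scar_quant`** — AHA segmentation (6 segments basal/mid, 4 apical,
   28 subsegments per LV), 5-SD thresholding against a ≥100-pixel
   normal-myocardium ROI, and mass in grams
   (pixels × spacing² × thickness × 1.05 g/ml).
5. **`agreement`** — sensitivity/specificity/PPV/NPV with exact
   Clopper-Pearson CIs at patient and subsegment level, Pearson r,
   Bland-Altman limits of agreement, ICC(2,1), Wilcoxon/paired-t tests.
6. **`pipeline` / `cli`** — the staged
   `simulate → fit → synthesize → quantify → evaluate` pipeline with NIfTI/
   JSON/YAML artifacts and a `synthlge` command-line entry point.

## Worked example

`examples/05_cohort_agreement.py` generates a 214-patient cohort (23
scar-positive, 0.1 g reader jitter, one injected false-negative and
false-positive patient) and runs the full study-level comparison:

```
patient contingency: TP=22 FN=1 FP=1 TN=190
patient sensitivity 96.0% (78.1-99.9), NPV 99.5%
prevalence: 10.7%
excluded from quantitative analysis (discordant patients): [0, 23]

quantitative agreement over 22 concordant positives:
  Pearson r = 0.991
  Bland-Altman: mean diff +0.012 g, LoA [-0.291, +0.316] g
  ICC(2,1) = 0.991 (0.978-0.996)
  median mass: index 2.97 g, reference 2.93 g (Wilcoxon p = 0.75)
```

Reading the numbers: of 23 patients with scar by the reference channel, the
index channel detects 22 (sensitivity 96%); 190 of 191 scar-free patients are
correctly negative (NPV 99.5%); the two discordant patients are excluded from
the mass comparison, which shows near-perfect correlation and agreement —
a mean difference of ~0.01 g on median scar masses of ~3 g, with limits of
agreement set by the 0.1 g reader jitter (±1.96·0.1√2 ≈ ±0.28 g).

The other examples each demonstrate one capability (phantom + MOLLI
simulation, whole-map T1 fitting, PSIR synthesis and null-point selection,
5-SD quantification); run them with `python examples/<name>.py`.

The same pipeline is available from the shell:

```bash
synthlge run-all --out run/ --seed 1       # writes run/report.json
synthlge quantify --out run/ --config cfg.yaml
```

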
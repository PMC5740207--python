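# Methods

This note documents the models, parameter choices and numerical decisions
behind `synthlge`, and what the synthetic phantom does and does not emulate.

## Signal models

**Inversion recovery.** A pixel with longitudinal relaxation time T1,
inverted at t = 0, recovers as S(t) = A − B·e^(−t/T1\*). In a Look-Locker
acquisition the repeated readouts shorten the apparent relaxation time to
T1\*, and the true T1 is recovered with the standard correction
T1 = T1\*·(B/A − 1). For an ideal inversion (B = 2A) the correction is the
identity, T1 = T1\*. The MOLLI simulator parameterises ground truth as
A = 1, B = A·(1 + η) with inversion efficiency η ∈ (0, 1], and
T1\* = T1/η, so that correcting the fitted parameters returns the map's T1
exactly. (Note the consistent direction of the relation: T1\* = T1/(B/A−1);
writing T1\* = T1·A/B would contradict the correction formula and break the
simulate→fit round trip.)

**Synthetic PSIR.** Image synthesis from a fitted map assumes full recovery
between inversions and ideal inversion, with equilibrium magnetisation
normalised to 1: S(TI) = 1 − 2·e^(−TI/T1), signed (phase-sensitive) by
default, magnitude on request. Proton density, surface-coil shading, T2\*
and readout effects are not modelled. The null point is TI = T1·ln 2;
`optimal_ti` uses ln 2 × the mean T1 inside a myocardial mask, optionally
snapped to the synthesis grid.

**Noise.** MOLLI noise is zero-mean Gaussian added to the signed signal
before the magnitude operation (Rician-like). Phantom T1-map noise is
Gaussian in milliseconds, clipped at 1 ms to keep T1 positive.

## MOLLI timing

A scheme b₀(r₀)b₁(r₁)… acquires bₖ images per inversion block with rₖ
recovery beats after block k. Block k uses inversion delay
initial_ti + k·ti_increment (defaults 100 ms and 80 ms → block delays
100/180/260 ms), and image j of a block reads out j heartbeats after the
delay. The heart period is a fixed scalar per series (default 857 ms ≈ 70
bpm); beat-to-beat variability is not modelled. The delays are assigned per
block in acquisition order — an alternative reading (increments applied after
TI-sorting) would give the same set for the default scheme but is not used.

## Fitting

Two engines fit the same model:

* `fit_molli` (single curve): scipy trust-region least squares with analytic
  Jacobian, initialisation A₀ = max|S|, B₀ = 2A₀, T1\*₀ = median TI, bounds
  T1\* ∈ (1, 5000) ms, tolerances 1e−14.
* `fit_t1_map` (whole image): a variable-projection solver. At fixed T1\*
  the model is linear in (A, B), so the 2×2 normal equations are solved in
  closed form and the residual sum of squares is profiled over T1\* only.
  A 64-point log-spaced T1\* grid brackets the minimum, then 80
  golden-section iterations refine it; the RSS is accumulated from explicit
  residuals (not the normal-equation identity), which avoids cancellation
  and resolves the minimum to near machine precision — noiseless round trips
  reproduce the source T1 to ~1e−13 ms. All pixels and polarity hypotheses
  are processed as one vectorised batch (a 64×64 slice fits in ~2 s on one
  core).

Polarity restoration is exhaustive in both engines: magnitude data are
sign-flipped for the m earliest samples, m = 0…n−1, and the hypothesis with
the smallest residual wins (ties go to the smallest m). A fit is flagged
unconverged — never raised — when A ≤ 0, B/A ≤ 1, T1\* pins to a bound or
the signal is flat (e.g. an all-zero pixel).

## Phantom

The LV cross-section is a circular annulus: blood pool inside the
endocardial radius (12 mm), myocardium to the epicardial radius (22 mm),
background outside, at 1.65 mm in-plane spacing and 8 mm slice thickness on
a 64×64 grid (the annulus needs only ~27 pixels of radius; acquisition-size
matrices would add nothing). Five slices (2 basal, 2 mid, 1 apical) give
the standard 28 AHA subsegments. Default post-contrast T1s — myocardium
500 ms, scar 300 ms, blood 350 ms — are literature-informed round numbers
chosen so scar is hyperintense at the conventional display TI of 300 ms;
they are configurable and not measured values. Scar wedges are defined by
slice, angular start/span (counterclockwise from the ray through a
reference point placed outside and below the inferior wall) and
transmurality (fraction of the wall from the endocardium outward).

Ground-truth masses are exact pixel counts × pixel area × thickness ×
density. Density is 1.05 g/ml (standard myocardial density; quantification
reports "volume (g)", i.e. volume times density). Phantom and
quantification rasterise contours through the same polygon path, so
ground-truth and measured masks agree pixel-for-pixel on noiseless data.

**Cohort generator.** 214 patients, 23 scar-positive, each positive patient
carrying 1–3 wedges (span 45–120°, transmurality 0.4–0.9), which lands
per-patient masses in the few-gram range typical of patients without prior
infarction. The two quantification channels are the ground-truth mass plus
independent zero-mean reader jitter (default SD 0.1 g, matching
interobserver Bland-Altman SDs of ~0.1 g at this scale). Discordance
injection (a false-negative patient carrying a single-subsegment wedge the
index channel misses; a false-positive patient with 3 spurious subsegments)
is off by default and used to reproduce a study's observed discordance
pattern. All randomness descends from one root `SeedSequence`, so cohorts
are bit-reproducible.

**What the phantom does not emulate:** anatomy beyond a circular annulus,
papillary muscles, partial-volume edges, motion, k-space/SSFP readout
physics, B1/coil shading, or contrast-kinetics time dependence. Passing
tests on the phantom therefore demonstrates correctness of the *analysis
chain* (timing, fitting, synthesis, thresholding, bookkeeping, statistics),
not robustness to real-data artefacts.

## Quantification choices

* Reference ROI: sample SD with n−1 denominator; at least 100 pixels
  enforced (shortfall named in the error).
* Threshold: strictly greater than mean + n_sd·SD; ties are non-scar; a
  constant image yields an empty mask, not an error.
* Subsegment positivity: ≥ 1 supra-threshold pixel (configurable
  `min_pixels`).
* No island/connectivity filtering by default; `min_island_pixels` enables
  it explicitly.
* Segment numbering starts at the inferior reference direction and proceeds
  counterclockwise; equal 60° (basal/mid) or 90° (apical) sectors.
* The automatic reference-ROI helper accumulates whole segments in
  ascending order of mean signal until 100 pixels — a stand-in for a
  manually drawn remote-myocardium ROI, adequate on phantoms where scar is
  confined to few sectors.

## Statistics

* Accuracy metrics are percentages with exact Clopper-Pearson binomial CIs;
  zero-denominator metrics are reported as undefined (None), never 0. The
  CI method in the source studies is typically unnamed, so only point
  estimates should be compared across implementations. Display rounding
  uses decimal half-up (integer percent for sensitivity/specificity, one
  decimal for PPV/NPV/prevalence).
* Patient-level contingency collapses a patient's 28 subsegment calls by
  any-positive.
* Bland-Altman: mean difference, SD (n−1), limits mean ± 1.96 SD.
* ICC is ICC(2,1) — two-way random effects, absolute agreement, single
  measures — computed from the ANOVA mean squares with the McGraw-Wong
  F-based CI; absolute agreement penalises constant bias that Pearson r
  ignores. The flavour is labelled in the output.
* Wilcoxon drops zero differences (Wilcoxon's original rule); when all
  differences are zero the p-value is reported as 1.0 with a note. Pearson
  r on constant input is NaN with a note.
* `run_study` excludes patients whose patient-level calls disagree between
  channels from the quantitative agreement analysis (they have no
  meaningful paired mass); the quantitative n equals the
  concordant-positive count.

## Pipeline

The staged pipeline writes NIfTI images with JSON sidecars (plain-text
matrices are available as a secondary format), skips stages whose artifacts
already exist (resume after partial failure; `--force` recomputes), and is
byte-identical across re-runs with the same config: reports are serialised
with sorted keys and all randomness derives from the config seed. The
conventional-enhancement channel is represented as a second quantification
channel: a PSIR image synthesised from the ground-truth T1 map at TI
300 ms, quantified with the same 5-SD rule as the early-synthetic channel
(which uses the *fitted* map at the myocardium-nulling TI).

## Problem sizes

Defaults used by the test suite and the reproduction script: 48–64 px
phantoms, 500-replicate noise studies for T1 recovery, 100 seeded phantoms
for mass recovery, 200 seeded cohorts for the jitter-variance check, and
full 214-patient cohorts for the agreement statistics. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances while keeping
a full run in the tens of seconds.

## Known limitations

* Incomplete recovery between MOLLI inversion blocks is not simulated
  (synthesis and simulation both assume full recovery), so systematic
  MOLLI underestimation of T1 seen in vivo is absent.
* The ICC CI uses the large-sample F approximation; very small n gives
  conservative bounds.
* `fit_t1_map` holds one (n_hypotheses × n_TIs × n_pixels) batch in memory;
  for very large 3-D volumes, fit slice-wise.
* The automatic ROI helper assumes scar does not contaminate the
  lowest-signal segments; with circumferential scar, supply an explicit ROI.
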
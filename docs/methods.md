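# Methods

## Problem and scope

`vfat1` models the measurement chain of variable-flip-angle (VFA) T1
mapping in the liver and the statistics used to characterize it as a
quantitative imaging biomarker: accuracy (bias against a literature
reference), test–retest repeatability on one scanner, reproducibility
across scanners of different vendors and field strengths, and spatial
heterogeneity within the liver. Because raw multi-scanner volunteer data
are rarely shareable, the package pairs the analysis chain with a
synthetic study generator that emulates a traveling-volunteer design:
8 subjects, 6 scanners (1.5 T and 3.0 T from three vendors S, P, G),
2 scans per subject per scanner, and three methods — breath-hold VFA
(`VFA_BH`), free-breathing VFA (`VFA_FB`), and a MOLLI-style
inversion-recovery reference (`MOLLI`, available on a 3-scanner subset).

## Signal models

The steady-state RF-spoiled gradient-echo (SPGR) signal at prescribed
flip angle α, repetition time TR, and transmit-field (B1+) ratio k
(actual/prescribed angle) is

    S(α) = M0 · sin(kα) · (1 − E1) / (1 − E1 · cos(kα)),   E1 = e^(−TR/T1).

The Ernst angle arccos(E1) maximizes S. For inversion recovery sampled
Look-Locker style the apparent recovery is S(TI) = A − B·e^(−TI/T1*),
corrected to T1 = T1*·(B/A − 1).

All interfaces take angles in degrees and times in milliseconds; radians
are internal only.

## Fitting

**VFA.** With y = S/sin α and x = S/tan α, the SPGR model is the line
y = E1·x + M0(1 − E1). Ordinary (unweighted) least squares gives
T1 = −TR/ln(slope) and M0 = intercept/(1 − slope). Slopes outside (0, 1)
have no physical T1; such voxels (including all-zero input) are flagged
invalid and excluded, never imputed — downstream ROI statistics are
median-based and tolerate exclusions. The linearized estimator and a
brute-force nonlinear SPGR fit agree to better than 0.1% on noise-free
data; on model-inconsistent data (e.g. signals generated with a wrong k)
they differ slightly because they weight residuals differently.

**MOLLI.** The three-parameter fit is solved by variable projection:
at a trial T1* the amplitudes (A, B) are a 2-unknown linear solve, so
the fit reduces to a one-dimensional search over T1*, implemented as a
40-point log-spaced grid (T1* bounds 0.05× the shortest to 20× the
longest TI) followed by ~55 golden-section iterations. Everything is
vectorized over voxels, so map fitting is array arithmetic rather than a
per-voxel optimizer loop. Magnitude data loses the sign of early
samples; polarity is restored by refitting with the leading j = 0…n
points sign-flipped and keeping the lowest residual. Physical fits
(A > 0) are preferred over unphysical ones — this resolves the exact
global sign-flip degeneracy of magnitude data — and residual ties break
toward the later zero-crossing. Noiseless recovery is exact to < 1e−6
relative; fits with A ≤ 0 or non-positive corrected T1 are invalid.

## Synthetic study generator

The generator's defaults are the study conditions; they are fixed, not
tuning knobs.

* **Anatomy.** A 64×64×5 multi-slice slab: an elliptical liver
  (semi-axes 0.42/0.34 of the grid) with uniform subject-specific T1 and
  M0 = 1000, plus a tubular vessel (blood) compartment at 2× liver T1
  and 1.4× M0, widest on the central slice. A 2D slab is sufficient for
  every statistic in scope.
* **Subjects.** One multiplicative factor per subject, Gaussian with
  CV 7.5%, scales the literature liver T1 at both field strengths
  (602 ms at 1.5 T, 752 ms at 3.0 T); this yields a ≈15%
  (100×1.96×CV) between-subject variation on an unbiased measurement.
  A body-size factor U(0.8, 1.2) scales the B1+ amplitude per subject.
* **B1+ fields.** Smooth seeded sums of three broad Gaussian bumps,
  scaled by a per-scanner (center, amplitude) pair and clipped to the
  reported in-vivo ratio range [0.4, 1.3]. 3.0 T scanners get larger
  amplitudes than 1.5 T; the 3.0 T vendor-S profile carries a strong
  low-ratio offset (center 0.80, amplitude 0.22) making it the dominant
  vendor effect, while vendor S at 1.5 T is nearly unbiased — the
  qualitative vendor/field structure the analysis is meant to detect.
  Scan 2 redraws the field pattern (same center) so repeatability
  includes a transmit-field component as well as noise.
* **Noise.** Rician: |S + n1 + i·n2| with i.i.d. Gaussian channels,
  SD 1.0 per profile against peak liver SPGR signals of ≈48 (SNR ≈ 50).
* **Acquisition modes.** `VFA_BH`: one noisy stack over six flip angles
  {2, 5, 8, 10, 12, 15}° (TRs 3.19–6.04 ms across profiles). `VFA_FB`:
  10 repeats per flip angle, each displaced by a random integer in-plane
  translation up to ±3 voxels (repeat 1 is at the reference position)
  before noise. `MOLLI`: an 8-point 5(3)3-style TI scheme at a simulated
  heart rate of 80 bpm; contrast uses B/A = 2.1 and T1* = T1/(B/A − 1),
  so the Look-Locker correction recovers truth exactly, and the
  inversion is treated as ideal (B1-insensitive) — MOLLI is the low-bias
  reference arm by construction.
* **Seeding.** One root seed; each session derives an independent
  `SeedSequence` keyed by (subject, scanner, method, scan), so any
  session regenerates identically regardless of iteration order.

What the generator does **not** emulate: deformable breathing motion,
receiver-gain drift, imperfect spoiling, magnetization transfer,
fat/iron/glycogen confounds, slice profiles, or realistic organ shape.
Passing tests therefore validate the analysis chain and the direction
and rough magnitude of B1-driven effects — not the numerical values any
particular scanner fleet would produce.

## Preprocessing

Free-breathing repeats are registered to the first repeat of their flip
angle by exhaustive integer-shift search (window ±3 voxels) maximizing
normalized cross-correlation over the overlap, ties toward the smaller
displacement, then magnitude-averaged; voxels not covered by every
shifted repeat are averaged over contributing repeats and flagged. The
rigid search is a deliberate, testable simplification of deformable
registration.

## ROI and summaries

The ROI is liver ∧ valid-fit ∧ (T1 < vessel threshold), restricted by
default to the slice with the largest excluded-vessel cross-section
(the slice a reader would choose to contain the portal vein at its
widest). The threshold defaults to 1.5× the literature liver T1 at the
scan's field strength and is configurable — under strong transmit-field
bias the fitted liver itself can approach a fixed threshold, which is a
real failure mode of threshold-based vessel removal. Summaries are the
median, IQR (linear interpolation between order statistics — the
heterogeneity value depends on this convention, so it is fixed), and
spatial heterogeneity 100×IQR/median.

## Metrics

With the sample (n−1) standard deviation throughout:
bias% = 100·(mean of scans 1,2 − reference)/reference;
repeatability RE% = 100·1.96·SD(scan1, scan2)/mean;
reproducibility RE% = 100·1.96·SD across scanners/mean (per field
strength, from scan-averaged values, also restricted to vendor pairs);
between-subject variation% = 100·1.96·SD across subjects/mean per
scanner and method. Metrics are computed per subject and averaged over
the cohort; population values carry a 95% CI half-width 1.96·SD/√n
(the z-based construction; configurable). Missing cells (a withdrawn
subject) are handled available-case and logged.

## Inference

Means are compared with a one-way within-subject (repeated-measures)
ANOVA, F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df, with listwise
deletion of incomplete subjects and no sphericity correction;
significant effects are followed by paired t-tests. Variances are
compared with Levene's test, mean-centered by default (median-centered
Brown–Forsythe available). Raw two-sided p-values are reported without
multiplicity adjustment.

Type-I calibration is verified on a homoscedastic Gaussian null study of
50 subjects × 3 conditions over 1,000 seeded replicates, where each
test's reference distribution is the operative approximation; all three
tests reject at 3.5–6.5%. A known limitation: the mean-centered Levene
test is anticonservative at this study's own group size (≈6.7% true
rejection at 3 groups of 8, ≈7.7% at 6 groups of 8, measured by
simulation), so its p-values at n = 8 should be read with that inflation
in mind. The implementation itself is verified against a from-scratch
deviation-ANOVA oracle independently of sample size.

## Numerical and design choices

* Degenerate inputs: all-zero VFA signals and non-physical slopes are
  invalid flags, not exceptions; an empty ROI is an explicit error;
  paired t with constant nonzero differences is a degenerate-input
  error, while all-zero differences report t = 0, p = 1.
* The analytic B1+ bias prediction runs the same linearized fit used on
  data (not the small-angle k² approximation), so the −84%/+70% range at
  ratios 0.4/1.3 emerges from the production code path; in the
  small-angle limit it converges to 100·(k² − 1).
* The exact per-scanner flip-angle sets and TRs of any real fleet vary;
  the defaults {2, 5, 8, 10, 12, 15}° span the liver Ernst angle
  (≈5–8°) at both field strengths and are configurable per profile.
* Test problem sizes are scaled to desk hardware: study-level property
  checks use 32×32×1 slabs and 4-subject cohorts; the full default
  study (8 subjects, 64×64×5, all methods, 240 sessions) runs in a few
  minutes through the CLI.

## Known limitations

Rigid translational registration only; ideal-inversion MOLLI (no T2/B1
dependence of inversion efficiency); vessel exclusion by a fixed
threshold rather than anatomical segmentation; no B1+ mapping or
correction (by design — the package quantifies the uncorrected error);
single-scanner-per-profile simulation cannot separate scanner-to-scanner
from vendor-to-vendor variation.
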
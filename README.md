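# vfat1

Bias, repeatability, and reproducibility of variable-flip-angle (VFA)
liver T1 mapping — signal models, voxelwise fitting, a synthetic
multi-subject multi-scanner study generator, and the statistical surface
of a traveling-volunteer test–retest design.

## The problem

Three-dimensional VFA methods are the practical choice for volumetric T1
mapping of the liver, but they inherit the errors of the steady-state
SPGR signal model — above all transmit-field (B1+) nonuniformity, which
rescales every prescribed flip angle by an unknown spatial ratio k and
biases the fitted T1 by roughly k². Anyone using liver T1 as a
quantitative biomarker across scanners, vendors, or field strengths
needs to know how large that bias is, how well a measurement repeats on
one scanner, and how badly it disperses across a fleet. This package
implements that entire measurement-and-analysis chain and a synthetic
study on which it can be exercised end to end, with known ground truth.

## Models and statistics

SPGR signal at flip angle α, repetition time TR, transmit ratio k:

    S(α) = M0 · sin(kα) · (1 − E1) / (1 − E1 · cos(kα)),  E1 = e^(−TR/T1)

VFA fitting linearizes this as y = E1·x + M0(1 − E1) with y = S/sin α,
x = S/tan α, giving T1 = −TR/ln(slope). The MOLLI reference fits
S(TI) = A − B·e^(−TI/T1*) with Look-Locker correction T1 = T1*(B/A − 1).
With the sample standard deviation and literature liver references
(602 ms at 1.5 T, 752 ms at 3.0 T):

    bias%               = 100 · (mean of scans 1,2 − ref) / ref
    repeatability RE%   = 100 · 1.96 · SD(scan1, scan2) / mean
    reproducibility RE% = 100 · 1.96 · SD across scanners / mean
    heterogeneity%      = 100 · IQR / median  (within the liver ROI)
    between-subject%    = 100 · 1.96 · SD across subjects / mean

Metrics are computed per volunteer and averaged, reported ± 1.96·SD/√n.
Means are compared by one-way within-subject ANOVA (paired t post hoc),
variances by Levene's test. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

Analytic bias from a transmit-field error, at the liver operating point:

```python
>>> from vfat1 import Tissue, VfaAcquisition, predict_b1_bias
>>> acq = VfaAcquisition(tr=3.5)           # six angles 2-15 degrees
>>> liver = Tissue(t1=752.0, m0=1000.0)    # healthy liver at 3.0 T
>>> round(predict_b1_bias(0.4, liver, acq), 1)
-84.0
>>> round(predict_b1_bias(1.3, liver, acq), 1)
69.6
```

So over the flip-angle-ratio range 0.4–1.3 reported in vivo in the liver
at 3.0 T, uncorrected VFA T1 can be anywhere from 84% low to 70% high.

A full synthetic study (8 subjects × 6 scanners × 2 scans, three
methods; ~4 minutes on one core):

```python
>>> from vfat1 import simulate_study, study_table, compute_metric_report
>>> table = study_table(simulate_study(n_subjects=8, seed=1))
>>> print(compute_metric_report(table).table2_style())
method                         MOLLI       VFA_BH       VFA_FB
row
bias                       1.7 ± 3.7    8.4 ± 6.2   10.4 ± 4.1
heterogeneity              2.3 ± 0.0    9.4 ± 1.6    7.6 ± 0.8
repeatability_re           0.1 ± 0.0   19.8 ± 5.6   21.3 ± 3.9
reproducibility_re [1.5T]        NaN   21.8 ± 3.6   20.2 ± 3.5
reproducibility_re [3.0T]  0.1 ± 0.0  63.1 ± 18.9  65.5 ± 18.2
```

Reading the table: the MOLLI arm is nearly unbiased and tightly
repeatable (it is simulated as B1-insensitive, and has no reproducibility
row at 1.5 T because only one 1.5 T scanner carries it); both VFA arms
overestimate T1 and disperse strongly across the 3.0 T scanners, driven
by the deliberately offset vendor-S 3.0 T transmit-field profile —
restricting to the well-aligned G–P vendor pair drops the VFA
reproducibility RE to ~10–11%, and vendor S at 3.0 T shows the largest
between-subject variation (≈58%). The same pipeline is scriptable:

```
vfat1 simulate --seed 1 --out runs/sim
vfat1 fit --manifest runs/sim/manifest.csv --out runs/fit
vfat1 analyze --study-table runs/fit/study_table.csv --out runs/analysis
```

`simulate` writes NIfTI signal stacks plus a ground-truth manifest,
`fit` produces T1 maps and the long-format study table, `analyze` writes
the metric report, between-subject variation, pairwise-vendor
reproducibility, and the rANOVA/Levene test tables. Real acquisitions
can enter at the `fit` stage with a hand-written manifest.

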
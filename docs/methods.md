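# Methods

This note documents the statistical procedures, the choices made where
the design was genuinely open, and what the synthetic-data generators do
and do not emulate.

## Enrichment calling

**Model.** A gene × sample count table with an apical/basal two-level
design (≥2 replicates per domain). Counts are assumed
negative-binomially distributed around a per-domain mean after
correcting for per-sample sequencing depth.

**Normalization.** Median-of-ratios size factors: for sample *j*,
`s_j = median_g( c_gj / geomean(c_g·) )` over the reference genes with a
nonzero count in every sample. If no such gene exists the factors are
undefined and the model refuses to fit (an explicit error, not a
fallback). This is the classical depth estimator for differential
expression; it is written out in full here so the whole procedure is
specifiable.

**Per-gene test.** The canonical tool for this design is a
negative-binomial Wald test with dispersion shrinkage. We deliberately
substitute a fully specified alternative: the per-gene fold change is
`log2fc = log2((mean_A + pc) / (mean_B + pc))` on normalized counts with
pseudocount `pc = 0.5`, and the p-value is a two-sided Welch t-test on
`log2(normalized + pc)` between domains. The substitution trades some
small-sample power (no information sharing across genes) for complete
transparency: there is no hidden shrinkage, so every number is
reproducible by hand. Consequences: on raw counts the called gene *set*
is statistically equivalent but not gene-for-gene identical to an NB
Wald analysis; on an externally produced differential table
(log2FC + FDR columns ingested through `read_enrichment_table`) the
classification stage applies exactly and reproduces published class
counts.

Degenerate cases: genes with all-zero counts in both domains are
dropped and logged; genes with zero variance in both domains carry no
distributional evidence and get p = 1 with a `degenerate` flag (never a
silent 0 or NaN). The pseudocount is applied after normalization and is
the same value in the fold change and the test transform.

**Multiple testing.** Benjamini–Hochberg step-up, clipped to 1
(statsmodels' `fdr_bh` behind the package's `benjamini_hochberg`
surface).

**Classification.** The FDR gate is a strict inequality (`fdr < 0.1` by
default). Significant genes split by fold change at the contaminant
cutoff (default 3): `log2fc > 3` oocyte contaminant, `0 < log2fc ≤ 3`
bona fide apical, `−3 ≤ log2fc < 0` bona fide basal, `log2fc < −3`
muscle contaminant. Both ±3 ties are bona fide — the boundary is
asymmetric in prose ("|log2FC| > 3 indicates contamination") but the
class definitions place equality on the bona fide side, and we follow
the class definitions. A significant gene at exactly log2fc = 0 has no
direction and is classed not significant. The rationale for the triage:
tissue fragments cut from sections carry over RNA from the adjacent
oocyte (apical side) or circular muscle (basal side); such transcripts
are nearly absent from the depleted domain and therefore show extreme
fold changes, unlike genuinely localized transcripts of the epithelium
itself.

Replicate-outlier exclusion (e.g. dropping a replicate by PCA
dissimilarity) is out of scope: the model consumes the replicates it is
given.

**Validation regression.** smFISH-vs-RNA-seq fold-change agreement is
summarised by a through-origin regression `y = b·x` (slope
`Σxy/Σx²`, df = n − 1): with both axes being log fold changes of the
same transcripts, a zero intercept is forced by the design and a slope
near 1 indicates quantitative agreement.

## Degree of Apicality

`DoA = (apical − bg) / (basal − bg)` on mean fluorescence intensities.
Measurements with either signal not above background are invalid: they
are excluded with a logged reason, never clamped, because a clamped
denominator would fabricate arbitrarily large DoAs.

KD/wt pairing: knockdown and wild-type cell groups measured in the same
image stack are paired by the group-id stem (a trailing `_wt`/`_kd`
suffix is stripped; ids without the suffix pair on the full id). This
pairing convention is this package's own — upstream practice is simply
"within the same Z-stack" — and each paired stack contributes one KD/wt
ratio to the per-RNA t-test, i.e. n counts stacks, not cells. The
whole-mutant variant divides a single mutant egg chamber's DoA by the
arithmetic mean of the wild-type DoAs.

Test battery: one-sample t against 1 (two-sided for localization
change, lower-tailed for total-signal degradation), pooled Student and
Welch two-sample t, one-way ANOVA with Tukey HSD post-hoc tests
(Tukey–Kramer for unequal n, via the studentized-range distribution),
and paired A/B ratio tests. Zero-variance samples report p = 1 (mean on
the null) or p = 0 (all values agreeing on a departure) with an
explicit degenerate flag rather than raising — experiments sometimes
aggregate as few as two replicates, and an exception would make such
panels unanalyzable.

## Axis profiles

Profiles are sampled intensities along strictly increasing positions,
0 at the apical end. 0–1 normalization is min–max on values and affine
on positions; constant profiles normalize to all zeros with a logged
flag (NaN would poison downstream aggregation).

`auc50`: cumulative trapezoidal area from the apical end; the half-area
point is located by linear interpolation inside the bracketing segment,
with plateau ties resolved to the apical-most crossing. Trapezoidal
integration is the natural rule for piecewise-linear line plots; the
linear crossing search makes the statistic exactly antisymmetric under
profile reversal (`auc50(reverse) = 1 − auc50`) and invariant under
intensity scaling. auc50 is computed on the values as supplied —
background subtraction, if wanted, is the caller's preprocessing step.

Subdomain fractions: values below the threshold are zeroed, then the
trapezoidal integrated density is split at `apical_boundary/3` (the
apical-cortical third of the apical region), `apical_boundary`, and the
basal remainder, and expressed as percentages of the total. The apical
boundary is a required analyst input — in practice the apical/basal
split of a follicle cell is determined visually per egg chamber — and
the boundary here is a fraction of the profile axis standing in for
that judgement. All-below-threshold signal raises a distinct error
(`NoSignalError`) rather than returning 0/0/0.

Peak coincidence: local maxima with prominence ≥ 0.1 of the normalized
range (configurable); the score is the fraction of reference-channel
peaks within a positional tolerance of any peak in the other channel.
A reference profile without peaks raises rather than returning 0, since
"no peaks" and "peaks that never coincide" are different findings.

## Meta-analysis

Translation efficiency is `RFP[TPM] / RNA[TPM]` per gene; genes with
`rna_tpm ≤ 0` are dropped from comparisons with a logged count (a ratio
over zero is undefined, and such genes carry no usable signal). Only
bona fide apical/basal classes enter group comparisons; contaminant
classes are excluded by construction. The two-sided Wilcoxon rank-sum
test uses exact enumeration for combined n ≤ 12 without ties, otherwise
the normal approximation with midranks, tie correction and continuity
correction; two fully tied groups return p = 1 with a degenerate flag
(the tie-corrected variance is zero there).

## Synthetic data

The generators define the study conditions for all self-contained
tests; one explicitly seeded `numpy.random.Generator` per call, no
global state, bit-identical outputs under a fixed config.

**Counts.** Negative binomial with variance `μ + dispersion·μ²`
(`size = dispersion⁻¹`; dispersion 0 gives Poisson). Defaults: 2000
genes, 4+4 replicates, baseline means log-uniform over 10^1.7–10^3
(well-expressed genes, where a t-test on logs is well behaved),
dispersion 0.05, library-size CV 0.1 (lognormal factors, mean 1).
Class fractions 0.15 / 0.11 / 0.001 / 0.0165 mirror the observed
proportions of apical, basal, oocyte-contaminant and muscle-contaminant
calls per 2000 genes in the follicle-cell study design. Bona fide genes
draw |log2FC| from (1.5, 2.5) split geometrically between domains;
contaminants draw |log2FC| ≥ 5 with the depleted-domain mean fixed at
0.5 counts — a small positive floor ("absent or in very low number")
that keeps every fold change defined while preserving extreme
magnitudes. The contamination magnitude is a free parameter, not a
calibrated estimate: no quantitative contamination-rate model exists to
calibrate against.

**Polarity.** `basal = bg + S·(1+ε_b)`, `apical = bg + S·DoA_target·(1+ε_a)`
with signal scale S = 100 a.u., background 20 a.u., ε ~ N(0, noise_cv)
resampled while a factor is non-positive (at the default CV 0.1 this
never triggers; resampling rather than clipping avoids a point mass at
the validity boundary). Note the measured mean DoA exceeds the target
by a ratio-bias term ≈ noise_cv²·DoA; tests account for it.

**Profiles.** Shape `exp(−bias·x)` on [0, 1] rescaled to peak 1, with
additive Gaussian noise clipped at 0; `true_auc50` is the analytic
half-area point of the noise-free shape,
`−ln(1 − (1 − e^{−b})/2)/b` (0.5 at b = 0).

**TPM tables.** `rna ~ 10^N(1.5, 0.5)`, per-gene log2 TE ~ N(0, 0.5)
with the basal group shifted by the configured amount (positive shift =
basal more translated), `rfp = rna · 2^TE`.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: GC/length biases and mappability artifacts
in counts; correlated replicates or batch effects; segmentation error
and bleed-through in fluorescence; spatially correlated profile noise
or point-spread blurring; and any coupling between expression level and
localization. The recovery and calibration results demonstrate the
statistics are implemented correctly and behave as designed under their
own assumptions, not that those assumptions hold for any particular
microscope or library prep.

## Problem sizes and runtime

Self-contained checks run at the study's design scale where it is
known (2000 genes × 8 samples; 10 paired stacks per polarity
experiment; 100-run power/false-positive batteries; profile grids of
101–4001 points), which keeps the full suite and the acceptance script
in the tens of seconds on one CPU.

## Known limitations

* The enrichment test is not the NB Wald test; exact reproduction of a
  published per-gene list from raw counts is not expected (the
  classification stage on the published processed table is).
* Whether published processed fold changes are shrunken is not always
  stated; `read_enrichment_table`'s column map lets the user choose
  which fold-change column feeds classification.
* The KD/wt pairing convention (group-id stem) and the subdomain
  boundary convention (fraction of the profile axis) are this package's
  explicit stand-ins for judgements made at the microscope.
* `compare_groups` reproduces the *procedure* of published
  meta-analyses; external per-gene EJC/TE values are not bundled, so
  published p-values are only reproducible given those tables.
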
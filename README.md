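# apicobasal

Quantitative analysis of subcellular RNA localization along the
apical–basal axis of polarized epithelia, built around the *Drosophila*
follicular epithelium: follicle cells whose apical surface faces the
oocyte and whose basal surface faces the basal lamina.

The package is for researchers who have already collected one (or more)
of these measurement types and need the downstream statistics:

* **LCM RNA-seq count tables** — apical vs. basal tissue fragments cut
  by laser-capture microdissection, ≥2 replicates per domain.
  `ApicalBasalEnrichment` normalizes counts by median-of-ratios size
  factors, tests each gene with a two-sided Welch t-test on
  `log2(normalized + pseudocount)`, adjusts with Benjamini–Hochberg,
  and classifies significant genes (FDR < 0.1) by fold change:
  `log2FC > 3` → oocyte contaminant, `0 < log2FC ≤ 3` → bona fide
  apical, `−3 ≤ log2FC < 0` → bona fide basal, `log2FC < −3` → muscle
  contaminant. The `|log2FC| > 3` triage reflects that cross-tissue
  carry-over during microdissection produces transcripts nearly absent
  from the depleted domain, hence extreme fold changes.
* **smFISH polarity measurements** — per-cell-group apical, basal and
  background mean fluorescence intensities. The Degree of Apicality is

  ```
  DoA = (apical m.f.i. − bg m.f.i.) / (basal m.f.i. − bg m.f.i.)
  ```

  (DoA > 1 = apical bias). Localization changes in mutant clones are
  KD/wt DoA ratios between paired knockdown and wild-type cell groups
  of the same image stack, tested against the no-change null of 1 with
  a one-sample t-test (`PolarityExperiment`). Whole-mutant egg chambers
  use the single-mutant-over-mean-wild-type variant. Student/Welch
  two-sample t, one-way ANOVA + Tukey HSD, total-signal degradation
  checks and paired A/B ratio tests round out the battery.
* **Axis intensity profiles** — line scans from the apical (position 0)
  to the basal end. Localization is summarised by the position at which
  the cumulative trapezoidal area reaches 50% of the total (`auc50`;
  uniform signal → 0.5, apical concentration → < 0.5), compared between
  conditions by Welch t-test; thresholded signal is split into
  apical-cortical / subapical / basal subdomain percentages; a
  peak-coincidence score quantifies channel colocalization.
* **Translation-efficiency / EJC meta-analysis** — per-gene
  `TE = RFP[TPM] / RNA-seq[TPM]` or an external EJC-IP log2FC, compared
  between the bona fide apical and basal sets with the two-sided
  Wilcoxon rank-sum test (exact for small tie-free samples).

`apicobasal.synthetic` generates all four input kinds with known ground
truth (negative-binomial counts with planted enrichment and contaminant
genes, polarity measurements with a configurable knockdown effect,
exponential-shape profiles with an analytic auc50, and TPM tables with
a group-wise TE shift), so the whole pipeline is testable end to end
without imaging or sequencing data.

## Worked example

```python
import apicobasal as ab

# synthetic LCM experiment: 2000 genes, 4 apical + 4 basal replicates
table, truth = ab.simulate_lcm_counts(ab.SimCountConfig(seed=1))
res = ab.ApicalBasalEnrichment(table.counts, table.sample_domains).fit()
print(res.summary())
```

```
Apical-basal enrichment results
=============================================
genes tested                     2000
FDR threshold                     0.1
|log2FC| contaminant cutoff         3
pseudocount                       0.5
---------------------------------------------
apically enriched                 311
basally enriched                  272
  oocyte_contaminant                2
  bona_fide_apical                309
  bona_fide_basal                 239
  muscle_contaminant               33
  not_significant                1417
```

The class counts are the genes passing the FDR < 0.1 gate split by the
fold-change boundaries; the two contaminant rows are the planted
extreme-fold-change genes recovered by the `|log2FC| > 3` triage.

```python
ms, _ = ab.simulate_polarity_measurements(
    ab.SimPolarityConfig(kd_effect=2.0, seed=3))
print(ab.PolarityExperiment(ms).fit().summary())
```

```
KD/wt Degree-of-Apicality summary
======================================================================
rna       condition         mean      sd   n        t           p  sig
----------------------------------------------------------------------
simRNA    sim              1.951   0.565  10    5.327   4.767e-04  ***
```

A mean KD/wt DoA of 1.95 over 10 paired stacks rejects the no-change
null (p ≈ 5e-4): the knockdown shifted the RNA apically by about
two-fold, matching the simulated effect.

There is also a CLI (`apicobasal simulate-counts | enrich | classify |
doa | profile-auc | subdomains | meta | run-all`); `run-all` writes
every stage's tables plus a `manifest.json` that reproduces the run
bit-identically from the same seed.

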
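# pepmarker

Discovery and validation of peptide biomarkers in cerebrospinal fluid (CSF)
peptidomics, built around the workflow used to find ALS biomarker
candidates: an untargeted screen of endogenous peptides in a discovery
cohort, a systematic candidate-selection cascade, and targeted parallel
reaction monitoring (PRM) validation with a panel classifier. The package is
for computational proteomics researchers who want the statistical machinery
of that workflow as tested, reusable code, exercised end-to-end on a
synthetic CSF peptidome generator.

## What it implements

**Normalization & QC** (`pepmarker.normqc`). Peak-area matrices are
normalized either to the total ion chromatogram (TIC) or to five spiked-in
non-human standard peptides (StdPep): each sample is divided by the median
over standards *s* of (area<sub>s,sample</sub> / geometric-mean
area<sub>s</sub>), which removes per-sample technical factors exactly under
the multiplicative noise model. QC metrics: %CV = 100·SD/mean on the linear
scale, identification counts, and the rank-abundance dynamic range in
log10 orders of magnitude.

**Differential analysis** (`pepmarker.diffstats`). For each peptide, the
s0-moderated two-sample statistic

    d = (x̄_A − x̄_B) / (s_pooled·√(1/n_A + 1/n_B) + s0),   s0 = 0.1

on log2 abundances, after presence filtering (≥ 70 % of samples per group,
or ≥ 3-per-group variants) and per-sample Gaussian down-shift imputation of
missing values (mean − 1.8·SD, width 0.3·SD — the left-censoring
convention). Multiple testing is controlled with a permutation-based FDR:
for threshold |d| the estimate is E<sub>perm</sub>#{null ≥ |d|} / #{observed
≥ |d|}, monotonized and capped at 1 (SAM-style, 250 balanced label
permutations, full enumeration for small designs). Wilcoxon rank-sum,
Kruskal–Wallis + Dunn post hoc (Holm-adjusted), Spearman correlation
matrices, Ward-linkage clustering specificity and PCA complete the
discovery statistics.

**Tryptic-like peptides** (`pepmarker.tryptic`). Peptides preceded by K/R
in the precursor protein and ending in K/R (a signature of basic-residue-
directed proteolysis), counted and compared per sample between groups.

**Candidate selection** (`pepmarker.candidates`). Union of significant
peptides over five presence-policy criteria with provenance; exclusion
rules (freeze–thaw recovery deviating by > 100 percentage points, protein
blacklist, blood-derived tags); targeted peak QC — normalized spectral
contrast dot product (dotp) > 0.7 with ≥ 10 co-eluting transitions within
retention-time tolerance; explicit reviewed panel edits.

**PRM panel analytics** (`pepmarker.prm`). Light/heavy ratios from summed
transition areas with symmetric interference exclusion, rank-based group
tests, per-peptide ROC/AUC with DeLong 95 % CIs, a combined logistic-
regression panel classifier (tiny ridge engaged automatically on
separation), and external-assay correlation.

**Synthetic CSF peptidome** (`pepmarker.sim`). Parent proteins, a peptide
catalog with true coordinates/flanks, abundances spanning ~8 orders of
magnitude, lognormal technical noise (CV 20 %), abundance-dependent
(left-censored) missingness, spike-in standards, planted fold-change
effects, per-group tryptic-like detection fractions, clinical covariates
with target Spearman correlations, and transition-level PRM reports.

## Worked example

```
python analysis/01_simulate_cohorts.py --seed 1
python analysis/03_differential_discovery.py --seed 1
python analysis/05_prm_validation.py --seed 1
```

The discovery step prints:

```
236 significant peptides at FDR 0.05 (193 up, 43 down); 76.8% of the 56
planted effects recovered; 90% of hits change by more than 100%
hierarchical clustering specificity 100%; PC1 explains 31% of variance
tryptic-like peptides: median 20.0% (Con) vs 24.9% (ALS), Wilcoxon p = 3.1e-09
```

i.e. the permutation test recovers most planted ≥2-fold effects, the
significant peptides separate the groups cleanly, and the planted
tryptic-like detection difference (20 % vs 25 %) is recovered by the
Wilcoxon comparison. The validation step quantifies the eight-peptide panel
(upregulated: NFL, two MAP1B peptides, MYL1, APOC1; downregulated: CADM3,
SCG1, PENK) on a simulated 42 + 67 cohort:

```
  NFL        AUC  95.1% (91.5-98.6%)
  ...
  combined   AUC  98.6% (96.8-100.0%)  <- all peptides, in-sample logistic model
NFL peptide vs external immunoassay: Spearman r = 0.994 (n = 109)
```

The combined logistic model outperforms every single peptide, and the NFL
peptide tracks the simulated external immunoassay almost perfectly — the
qualitative pattern the workflow is designed to detect. The injected matrix
interference on one PENK transition is flagged automatically and excluded
from both channels before ratio calculation.

A `pepmarker` CLI wraps the same stages
(`pepmarker simulate|qc|discover|validate|all`, with `--seed`, `--config`,
`--normalization`, `--s0`, `--fdr`, `--permutations`, `--tryptic-mode`).

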
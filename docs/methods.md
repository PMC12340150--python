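# Methods

## Scope and model

The package implements the statistics of a CSF peptidomics biomarker
workflow: screening-level differential abundance of endogenous peptides
between a disease group (ALS) and non-neurodegenerative controls, selection
of candidates, and targeted PRM validation of a peptide panel. Peptide
abundances are treated as multiplicative: an observed peak area is

    area[p, s] = mean[p, group(s)] · t_s · ε,   ε ~ lognormal(0, σ),

with a per-sample technical factor `t_s` (sample handling, injection) and
per-entry noise with CV ≈ σ for small σ. All differential statistics
operate on log2 areas, where the model is additive.

## Normalization

Spike-in standard (StdPep) normalization divides each sample by

    f_s = median over standards k of ( area[k, s] / geomean_j area[k, j] ).

The geometric-mean reference is a deliberate choice: it makes `f_s`
scale-equivariant, so a per-sample technical factor cancels *exactly* (up
to one constant shared by all samples, which carries no between-sample
information). An arithmetic-mean reference leaves a second-order residual
because the reference itself shifts with the factor. The median over the
five standards tolerates one aberrant standard (e.g. a mis-spiked or
interfered peptide). TIC normalization divides by the sample's total
observed signal and rescales by the mean total; totals use observed values
only, because a missing entry is censored, not zero. CVs are reported on
the linear scale (percent of the mean), matching assay-validation practice.

## Missing values and imputation

Missingness is assumed missing-not-at-random in abundance (left-censoring):
the simulator's detection probability is a logistic function of log10
abundance, strictly increasing, and the analysis imputes missing log2
values per sample from Normal(mean − 1.8·SD, (0.3·SD)²) computed over that
sample's observed values — the down-shift convention whose parameters are
the de-facto standard for label-free proteomics. Observed entries are never
modified; imputation is seeded and reproducible. Columns with fewer than
two observed values fall back, flagged, to the global distribution.

A consequence worth knowing: when two groups differ in *detection* rates
for a peptide class (as the tryptic-like fraction does here by design),
down-shift imputation converts the detection difference into an apparent
abundance difference. This is faithful to how the production pipelines
behave, and the analysis drivers report how many significant peptides are
of this kind. Null-control experiments therefore use equal detection
conditions in both groups.

## Differential test and FDR

The s0-moderated statistic divides the mean log2 difference by
(pooled-variance standard error + s0), with s0 = 0.1 by default; s0 = 0
reduces to the classical pooled two-sample Student t (verified against an
independent implementation at 1e-10). The pooled (Student) rather than
Welch form is the default, with Welch intentionally out of scope for the
headline statistic. s0 damps the significance of tiny-variance peptides,
whose t statistics are otherwise unstable at n ≈ 24 per group.

The FDR estimate is SAM-style: the null distribution is built from
balanced label permutations (default 250, deterministic seed; full
enumeration replaces sampling when the design admits fewer distinct
arrangements). For each threshold |d|:

    FDR(d) = mean over permutations of #{null |d*| ≥ |d|}
             ─────────────────────────────────────────────
             #{observed |d'| ≥ |d|}

capped at 1 and monotonized (a peptide's q is the minimum estimate over all
thresholds at or below its own |d|), so q is non-increasing in |d|. A
peptide is significant when q ≤ 0.05. Under a global-null simulation (500
peptides, 12 vs 12, CV 20 %) the realized false-discovery proportion stays
at the nominal level within Monte-Carlo error; a planted 2-fold effect at
CV 20 %, 24 vs 24 is detected essentially always and its log2 difference is
recovered within ±0.15 — consistent with a screen whose reported hits all
exceeded 100 % change at that design size.

Both q-based significance and the s0 volcano curve describe the same
statistic; the package reports q-based calls and leaves the curve to
plotting.

## Presence criteria and candidate union

Five presence policies are implemented (≥ 70 % per group in each group /
in either group / overall, with imputation; ≥ 3 per group in each / either
group, complete cases only), all with ≥ semantics at the bound (17/24 =
70.8 % passes 70 %). Quality filtering uses an opaque identification score
with an inclusive threshold of 5. The candidate union runs each criterion
independently and records per-candidate provenance and direction
(conflicting directions are flagged for review). Exclusion rules remove
candidates whose freeze–thaw recovery deviates by more than 100 percentage
points (the recovery scale is 100 × treated/reference; "variation over
100 %" is read as |recovery − 100| > 100), blacklisted proteins (albumin,
keratins) and blood-derived-tagged peptides; every removal is written to a
ledger with the rule and value.

## Targeted peak QC and PRM quantification

A targeted peak is accepted when the measured transition pattern matches
the reference spectrum with dotp > 0.7 (normalized spectral contrast dot
product, strict inequality), at least 10 transitions, pairwise apex-RT
spread within 0.1 min (co-elution) and apex RT within 1.0 min of the
reference — the RT tolerance reflects that a standard eluting more than a
minute away fails to confirm identity. L/H ratios are summed light over
summed heavy transition areas; transitions flagged for matrix interference
are excluded from *both* channels, so the ratio stays unbiased. Automatic
interference flagging marks a transition whose median log L/H across
samples deviates from the peptide's transition median by > 5 MADs *and* by
at least 1.5-fold; the absolute floor prevents very precise assays from
flagging clean transitions. A sample with heavy signal but no light signal
is recorded as missing with reason "no peak" (endogenous peptide below the
limit); light without heavy is an assay failure and raises.

## ROC and the combined panel model

Per-peptide AUC is the rank/Mann–Whitney estimator with tie averaging,
oriented so AUC ≥ 0.5 with the orientation recorded, and a DeLong 95 % CI.
The combined classifier is a binary logistic regression on standardized
log2 ratios fitted by maximum likelihood (a two-class multinomial model is
mathematically identical); on separation or non-convergence a tiny ridge
(1e-6, intercept unpenalized) is engaged via IRLS and logged. The combined
ROC uses in-sample fitted probabilities and is labelled as in-sample;
cross-validated claims are deliberately out of scope. Missing ratios are
handled by listwise deletion (reported) or median fill (flagged), never
imputed by default, and peptides missing in more than 30 % of samples are
rejected.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Abundance law**: log10 true means uniform over the configured span
  (default 8 orders, floor 10²), min–max rescaled so the realized span is
  exact — this matches the near-linear rank-abundance curves of deep CSF
  peptidome screens better than a lognormal.
* **Noise**: per-entry lognormal with CV 0.2 (technical), a per-sample
  lognormal factor with CV 0.3, and for the five standards an extra shared
  per-run spiking factor (CV 0.1) plus halved entry noise — so StdPep
  normalization is non-trivial but effective.
* **Missingness**: logistic detection probability in log10 abundance
  (midpoint 10³, steepness 0.4 decades), giving ~85–90 % observed entries
  at the default span. Standards sit far above the midpoint and are
  observed in ≥ 99 % of samples.
* **Effects**: explicit fold ≥ 1 with an up/down direction (down divides),
  planted on evenly spread catalog peptides; the demo discovery cohort
  plants 56 effects with folds 2–6, mirroring a screen whose hits all
  changed by > 100 %.
* **Tryptic-like fractions**: the catalog fraction equals the largest
  per-group target; per-group *observed* fractions are steered by a
  detection-curve shift for tryptic-like peptides solved numerically per
  group (Brent's method on the expected observed share). The shift acts on
  detection only, leaving abundances untouched, so the dynamic range and
  quantitative values are undistorted; equal targets produce identical
  detection in all groups.
* **Clinical covariates**: Gaussian copula against the designated peptide's
  rank scores with the Pearson weight 2·sin(π·r/6) that yields the target
  Spearman r, then a monotone map to clinical scales (age in years,
  ALSFRS-r 0–48, disease duration in months, Qalb). Disease-only scores are
  blank for controls.
* **PRM reports**: light areas scale with a per-sample lognormal abundance
  (biological CV 0.6, optional within-block correlation via shared latent
  factors — the validation demo uses 0.7 within the up- and down-regulated
  blocks, mirroring the strong observed correlations among co-regulated
  panel peptides); heavy areas are the constant standard up to technical
  noise; interference adds a configured fraction to one named light
  transition; below-limit samples lose their light peaks.

What the generator does *not* emulate: spectra (no m/z, isotope envelopes
or retention-time model), identification errors, batch drift beyond the
per-sample factor, inter-peptide correlation in the screening matrix, or
shared-protein structure between catalog peptides. Passing tests therefore
demonstrate the correctness and calibration of the statistics under the
stated generative model, not performance on real CSF data.

## Problem sizes and numerics

Default analysis sizes are chosen for seconds-scale runs: discovery demo
4 000 peptides × (24 + 24 + 3 QC) samples; null-control 500 peptides × 100
replicates × 250 permutations; power check 200 peptides × 40 replicates;
panel-advantage check 50 replicates at 55 + 55. The permutation engine is
vectorized over peptides, so these sizes are not a statistical compromise:
Monte-Carlo standard errors are reported or bounded in the acceptance
checks. Numerical details: logistic IRLS clips linear predictors at ±30;
ties in rank statistics use mid-ranks with the standard tie corrections;
Dunn's z uses the tie-corrected pooled-rank variance with Holm adjustment
(the post hoc adjustment is configurable); q-value monotonization uses a
reverse cumulative minimum; recovery/dilution bands use strict inequality
at the printed bounds ("<20 %", "±30 %").

## Known limitations

In-sample AUCs are optimistic relative to external validation; the
permutation FDR assumes exchangeability under the null within groups; the
detection-shift mechanism for tryptic fractions encodes one of several
biologically plausible routes (increased protease activity raising
abundances is another, which would also change quantitative values); and
the clinical covariate generator targets marginal correlations only, not a
joint clinical model.
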
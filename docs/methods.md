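# Methods

`beetox` re-implements, as a tested and reusable pipeline, the computational
analysis of a bumble bee (*Bombus terrestris*) brain RNA-seq experiment
comparing acute (48 h, high concentration) and chronic (12 day, low
concentration) exposure to three nAChR-targeting pesticides (acetamiprid,
clothianidin, sulfoxaflor).  Because the sequencing reads themselves are not
shipped, every stage is exercised on synthetic data whose statistical
structure mirrors the study design.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The synthetic study (`beetox.simulate`)

**Design.**  Ten source colonies supply microcolonies for seven treatments
(control plus compound × scheme); control and chronic groups carry ten
biological replicates, acute groups eight, giving 64 samples.  Replicate *r*
of each treatment comes from colony *r* mod 10 + 1, so colonies are crossed
with treatments as in the experiment.

**Counts.**  Gene counts are negative binomial.  Sample *j*'s mean vector is
`mu = L_j * softmax(b + c + f + e)` where `L_j` is a log-uniform library
size, `b` a per-gene baseline (log2 scale, N(5, 1.5) for null genes,
N(1.5, 0.8) for designated DE genes), `c` a per-gene-per-colony effect
(N(0, 0.25) log2), `f` the true log2 fold change of the sample's treatment
and `e` replicate-level noise.  The dispersion follows the familiar
decreasing trend `alpha(mu) = 0.02 + 2/mu`.

Defaults worth knowing:

| parameter | default | meaning |
|---|---|---|
| `library_size_range` | (5e6, 1.5e7) | total counts per sample; median gene counts O(10^3), matching deep (tens of millions of reads) libraries |
| `shared_acute_set_size` / `acute_up_fraction` | 61 / 0.91 | genes perturbed identically by all three acute treatments; 56/61 upregulated (round half up) |
| `shared_chronic_set_size` / `chronic_strong_down_lfc` | 12 / −5 | chronic-shared set with one immune-like gene 32-fold down |
| `amplitude_ratio_acute_over_chronic` | 2.7 | mean absolute true log2FC of the shared-acute set over the shared-chronic set, enforced exactly by rescaling |
| `lfc_magnitude_range` | (1.2, 2.8) | uniform magnitude band before scheme scaling |
| `replicate_noise_sd` / `acute_extra_sd_factor` | 0.9 / 1.2 | log2-scale replicate noise on DE genes; acute samples get 1.2× the SD |

Design choices behind these numbers:

* **DE genes start from low constitutive expression** (baseline N(1.5, 0.8)
  instead of N(5, 1.5)).  Strongly induced stress/detoxification genes are
  rarely high-baseline, and this caps the share of the library the induced
  acute set captures.  Without the cap, acute samples suffer a composition
  shift that depresses every other gene's counts and contaminates
  variance comparisons between schemes.
* **Deep libraries.**  With median counts O(10^3), Poisson counting noise is
  negligible next to the biological (log-scale) replicate noise, as in the
  real experiment; at shallow depth the counting noise of low-expressed
  genes dominates the replicate-SD contrast.  Simulation cost does not
  depend on count magnitude.
* **Replicate-variance inflation acts on the log2-mean scale** (lognormal
  mixing), applied to designated DE genes only, with acute samples receiving
  1.2× the SD.  This makes VST-scale SD ratios directly controllable; an
  inflation through the NB dispersion would be attenuated by the
  mean-dependence of the dispersion trend.
* **Rounding** of fractional set counts (e.g. 0.91 × 61) is round half up.

**Survival.**  Exponential event times per bee with treatment-specific
hazard ratios over a baseline of 0.008/day; acute bees are at baseline
hazard until the exposure window opens at day 12 and at elevated hazard only
inside it; all records censor at day 14.  Default hazard ratios emulate the
reported clothianidin mortality (≈54% acute over its window, ≈29% chronic);
with 48–60 bees per treatment the realized percentages carry binomial noise
of ±6–7 points.

**Food intake.**  Per-microcolony average daily intake per bee (mL),
measured every other day: baseline 1.5 + colony offset + slope × day of
exposure + Gaussian noise.  For acute treatments the slope acts on days
after the window opens, so the day-12/day-14 regression recovers it
directly.  Defaults encode the reported clothianidin interactions (−0.063
chronic, −0.51 acute); with zero noise the OLS recovery is exact.

Alternative configurations: `SynthConfig.null()` (no treatment, colony or
replicate effects — the calibration reference), `SynthConfig.scaled_down()`
(400 genes, proportional DE sets, for resampling-heavy work) and
`SynthConfig.colony_stress()` (20 colonies, colony SD 1.5 log2, for the
confounding diagnostic; see below).

## The DE engine (`beetox.de`)

A deliberately transparent negative-binomial Wald engine:

1. **Filter**: keep genes with count ≥ 10 in ≥ 8 samples (boundary
   inclusive).
2. **Size factors**: median-of-ratios over genes with all-positive counts,
   lower median on ties; a documented fallback uses geometric means over
   positive entries when no such gene exists.  Factors are relative; a
   single sample gets factor 1.
3. **Dispersion**: per-gene method of moments around full-design fitted
   means, `alpha = Σ[((y−mu)² − mu)/mu²] / (n − p)`, clamped to
   [0.01, 10], iterated once (Poisson-like start → estimate → refit →
   re-estimate).  Using model residuals means variance explained by
   modelled covariates — notably the source-colony blocking factor — does
   not inflate the dispersion, mirroring the gene-wise step of
   shrinkage-based tools.  No shrinkage across genes is applied.
4. **GLM**: one NB log-link GLM per gene, design = intercept + treatment
   dummies (control reference) + colony dummies (first colony reference),
   fitted by IRLS with fixed gene-wise dispersion, vectorised across genes.
   Non-converged genes carry missing statistics and are excluded from the
   multiple-testing correction.
5. **Wald test**: per contrast, `z = log FC / SE` referred to a Student t
   with `n − p` degrees of freedom.  With unshrunk gene-wise dispersions a
   standard-normal reference leaves the null p-values with inflated extreme
   tails (measured: P(p < 0.001) ≈ 0.0018 under the null); the t reference
   restores uniformity at every quantile.  Benjamini–Hochberg step-up FDR
   across retained genes, significance at FDR < 0.05.
6. **VST**: shifted log, `log2(count/size factor + 1)` — a pragmatic stand-in
   for a fitted variance-stabilising transform, exact under scaling of
   sample and factor together.  **PCA** is an SVD of the gene-centred
   matrix.

Omissions relative to shrinkage-based packages, by design: no
empirical-Bayes dispersion shrinkage, no LFC shrinkage, no independent
filtering, no outlier refitting.  The aim is a calibrated and fully
auditable Wald engine, not bit-compatibility.

Calibration, measured on the fully null configuration (2000 genes, 10
seeds): pooled raw p-values pass a KS uniformity test, and FDR-0.05
discoveries average ≪ 1 gene per dataset.

## Overlap statistics (`beetox.overlap`)

For named DE gene sets over a pool of N expressed genes: exclusive Euler
region counts (guarded at ≤ 10 sets); the exact expectation of the all-way
intersection under independent uniform draws without replacement,
`N·Π(s_i/N)` (linearity of expectation); a simulation null that redraws each
set uniformly without replacement per iteration (default B = 10 000); and an
add-one permutation p-value `(1 + #{null ≥ observed})/(B + 1)`, which counts
the observed configuration as one null draw and is therefore conservative
(floor 1/(B+1)).  Fold enrichment is observed over the simulation mean (the
analytic expectation is also reported, and substituted if the simulation
mean is zero).  "Unique samples" is read as within-set sampling without
replacement, not deduplication of whole iterations — with N ≈ 10^4,
duplicate iterations have negligible probability.

## Scheme contrasts (`beetox.contrasts`)

* **Top-k amplitude**: among FDR-significant genes of two contrasts, select
  the k = 20 with largest |log2FC| (selection by adjusted p is also
  available) and compare the |log2FC| samples by Welch's t; the ratio of
  means is the amplitude ratio.  Because top-k selection reaches into the
  upper tail, the recovered ratio on synthetic data sits slightly above the
  encoded set-mean ratio (≈ 2.9–3.2 vs 2.7 encoded).
* **Proportion of large changes**: 2×2 chi-square (uncorrected by default;
  Yates optional) on the share of significant genes with at least a
  fourfold change.
* **Direction goodness of fit**: chi-square against stated proportions.
  Note that 55–56 upregulated of 61 against a 50:50 null gives X² ≈ 39.4 by
  direct computation; the corresponding statistic printed in the study
  (23.8) is not reproducible from those counts and the exact null used
  there is not stated — the standard statistic is implemented and the
  discrepancy left as is.
* **Replicate-variance contrast**: the gamma GLMM with gene as a random
  effect is replaced by an exactly paired per-gene difference of log
  replicate SDs.  SDs are computed on the VST scale within each treatment
  (so between-compound fold-change differences cannot contaminate them) and
  averaged per scheme on the log scale; the scheme×DE-status interaction is
  then the mean log-SD difference (acute − chronic) of DE genes minus that
  of non-DE genes, with a Welch t between the two groups of per-gene
  differences.  Differencing removes the gene effect exactly, and the
  unequal replicate numbers (8 vs 10) bias log SD identically for DE and
  non-DE genes, so the bias cancels.  Residual attenuation from colony and
  counting variance leaves the recovered coefficient at ≈ 0.15 for an
  encoded log(1.2) ≈ 0.18.
* **Fisher enrichment**: one-sided hypergeometric per annotation term with
  BH across terms.  **KS** and **skewness** wrap the standard asymptotic
  two-sample statistic and the bias-uncorrected third standardised moment.

## Resampling diagnostics (`beetox.resampling`)

**Replicate balance.**  Chronic/control groups (10 replicates) are
subsampled to the acute groups' 8; each of 50 iterations draws a
never-reused joint (control-subset, treatment-subset) pair — uniqueness is
enforced on the joint signature, with the combinatorial bound
`C(10,8)² = 2025` checked up front — reruns the full DE pipeline and records
the FDR-0.05 DE count.  Each acute contrast's full-design DE count is
compared against this distribution with an add-one permutation p-value.

**Colony confounding.**  Matched iterations draw both arms from the same
random half of the source colonies and keep the colony covariate (it is
estimable, and modelling it removes colony variance from the residual
dispersion).  Mismatched iterations draw the arms from complementary
halves: colony is then structurally confounded with treatment, the
covariate cannot be fitted, and it is dropped.  Distributions of DE counts
are summarised by median and skewness and compared by a two-sample KS test.

The directional behaviour (matched median > mismatched median) emerges when
colony effects are strong enough to mask marginal treatment effects in the
mismatched design.  The shipped `colony_stress` conditions use 20 colonies
(one sample per colony per arm, halves of 10) with colony SD 1.5 log2;
under them the matched analysis finds ≈ 2–3× more DE genes than the
mismatched one.  At the study's own scale (halves of 5, five samples per
arm) this engine cannot resolve the direction: the matched model's colony
fit costs residual degrees of freedom that gene-wise dispersion estimation
— without cross-gene shrinkage — cannot afford.  Passing the diagnostic on
the stress conditions therefore demonstrates the mechanism, not the
magnitude observed on real data.

## Survival and dose (`beetox.survival`)

Single-covariate Cox proportional-hazards fits (treatment vs control) by
Newton–Raphson on the Breslow partial likelihood; the score test at β = 0
equals the log-rank test, which also supplies the p-value when the
likelihood is monotone (all events on one side — common in short acute
windows at desk scale; such fits are flagged, not hidden).  Acute
comparisons restrict both arms to bees alive when the exposure window opens
and re-zero time there.  Kaplan–Meier mortality at a horizon uses
`lifelines`; food-intake regression (colony + treatment + day +
day×treatment, OLS) uses `statsmodels`, with the acute variant restricted
to days 12 and 14.  Concentration conversion divides µg/L by the solution
density (1130 g/L for 30% sucrose) and rounds half-up to one decimal
(5 → 4.4 ppb, 25 → 22.1 ppb; the study's figure caption says 21.5 ppb for
the acute solution but the arithmetic supports 22.1, and the Methods value
is used).  Cumulative dose per bee integrates per-bee daily intake over the
exposure window times concentration.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure the analyses assume:
NB counts with a mean-dispersion trend, colony blocking, scheme-dependent
replicate variance, designed overlap structure, exponential survival,
linear intake trends.  It does not emulate transcript-level quantification,
sequence content, mapping artefacts, correlated gene modules, or the
continuous spectrum of effect sizes of a real brain transcriptome (true
fold changes are drawn from a band, so DE-count statistics are
threshold-sharp rather than smooth).  Passing tests therefore demonstrate
that the pipeline's statistics are correct and calibrated under the assumed
model, not that the biological conclusions of any particular dataset would
be recovered.

## Numerical choices and degenerate inputs

IRLS: linear predictor clipped at ±30 (natural log), ridge 1e-10 on the
normal equations, convergence at max |Δβ| < 1e-8, 50 iterations;
non-convergence yields missing statistics.  Median-of-ratios ties: lower
median.  BH: missing p-values propagate and reduce the number of tests.
Zero-SD genes are excluded (and counted) in the variance contrast.
Degenerate Welch inputs (both variances zero) give p = 1 when the means
agree and p = 0 otherwise.  Empty DE results, absent events, and
single-subset resampling boundaries raise informative errors or degrade to
documented degenerate outputs.  All file outputs are text with fixed %.6g
float formatting and LF newlines, so identical configurations and seeds
give byte-identical files; a single pipeline seed expands deterministically
into per-stage seeds.

## Problem sizes used in the shipped checks

Calibration runs use 2000-gene null datasets (10 seeds); parameter-recovery
runs the full 64-sample, 2000-gene design (10 seeds); resampling
diagnostics run at 400 genes with 30–50 iterations per distribution.  These
sizes give stable averages while keeping a complete run of the test suite
and the acceptance script in the minutes range on a single core.
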
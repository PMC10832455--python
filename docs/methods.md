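# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort preparation

Repeated metabolite measurements with a QC warning are removed before
collapsing; the individual's level is the median of the surviving repeats,
missing if none survive. Z-scores use the sample SD (n−1); the population/
sample distinction is negligible at cohort scale but the choice is fixed for
reproducibility. WHR is waist/hip of median-collapsed measurements. Obesity
cutoffs are strict: BMI > 30, WHR > 0.85 (women) / 0.95 (men); a value
exactly at the cutoff is non-obese. Diseases enter analysis only with ≥ 50
cases (inclusive). Missing covariates exclude an individual from the
affected model only (complete-case per model), mirroring a cohort
restriction to complete covariate data without discarding individuals
globally.

Allele-sum polygenic scoring computes `score_i = Σ_j dosage_ij · w_j` with
dosages counting the weight file's effect allele. When a dosage column
counts the other allele, the dosage is converted (`2 − d`), which equals a
weight sign flip plus a constant shared by all individuals; irreconcilable
alleles are dropped with a warning. Additivity over SNPs makes
per-chromosome scoring followed by summation exactly equal to a single
pass, which is tested.

## Association models

Logistic regression by maximum likelihood (statsmodels Newton, tolerance
1e-8, BFGS fallback), Wald standard errors and two-sided p-values, 95% CI as
exp(β ± 1.96·se). Covariates are exactly age, sex (0 = female, 1 = male),
age², and 10 genotype PCs; age is mean-centered before squaring, which
improves conditioning without changing the model space. Separation is
flagged when any fitted probability is within 1e-8 of 0 or 1 — relevant for
rare endpoints near the 50-case floor — and flagged results are marked
rather than suppressed.

Both predictors are standardized over the analysis cohort, so effects are
per SD and comparable across metabolites. Because the generative model sets
`level = √h²·PGS + √(1−h²)·ε`, the genetic-mode log-OR is attenuated by
√h² relative to the level mode; with the default h² = 0.5 this factor is
0.707, and the calibration suite verifies it at n = 100,000 within 2 SE.
This attenuation is the mechanistic reason a genetic scan yields fewer
significant hits than the direct scan at the same threshold.

## Triangulation and enrichment

The PheWAS-wide threshold is α divided by (diseases × metabolites × 2
modes); with 1,254 × 3 × 2 tests at α = 0.05 this is 6.65×10⁻⁶. A pair
passes when both modes are significant and sign(level β) = sign(PGS β).
Direction uses OR vs 1, not CI overlap. Enrichment uses the standard 2×2
count table [significant ∧ group, significant ∧ ¬group; ¬significant ∧
group, ¬significant ∧ ¬group] with a two-sided Fisher exact test (the
conservative choice when sidedness is not pre-specified), and a group-level
threshold of α / (number of groups containing ≥ 1 significant disease) —
data-dependent, with 15 groups as the canonical denominator giving 0.0033.

## Two-sample Mendelian randomization

Instruments: exposure p < 5×10⁻⁸. Harmonization aligns the outcome to the
exposure effect allele, recognizing strand complements, and drops
palindromic SNPs (A/T, C/G) with EAF in [0.42, 0.58], where strand cannot
be resolved from frequency.

- **IVW** is fixed-effect: estimate Σwβxβy/Σwβx², w = se_y⁻², se =
  √(1/Σwβx²), with Cochran's Q reported. Fixed-effect (not multiplicative
  random effects) is coherent here because heterogeneity outliers are
  removed first; the choice is configurable in spirit — the Q statistic is
  always reported so an over-dispersed analysis can be flagged.
- **Outlier removal** iteratively drops the largest per-SNP Q contribution
  while it exceeds the χ²(1) upper-α quantile, refitting each round, never
  below 3 instruments. Default α = 0.05/n per round (Bonferroni), which
  prevents over-pruning of mildly heterogeneous sets.
- **Weighted median**: ratio estimates βy/βx weighted by (βx/se_y)²
  (the leading-order inverse ratio variance), interpolated at cumulative
  weight 0.5; SE by seeded parametric bootstrap (default 1,000 draws), so
  results are deterministic under a fixed seed.
- **Egger**: se_y⁻²-weighted regression with intercept after orienting all
  βx ≥ 0; the intercept estimates directional pleiotropy. Standard errors
  use multiplicative over-dispersion floored at 1.

The method registry covers the estimators that drive inference here (IVW
primary, weighted median as robustness, Egger as pleiotropy check) and is
trivially extensible. Support flags: *MR-supported* = IVW p < 0.05 and
OR < 1 (the analysis considers protective candidates only); *dual-support*
adds weighted-median p < 0.05.

## Canalization

Percentile binning uses stable ranks (ties broken by input order), bin
sizes differing by at most 1. The 2% tails are the extreme 2 of 100 bins,
case-weighted within the tail (equivalent to per-individual tails up to
rounding). Delta expected fits, per stratum, a binomial GLM of per-bin
cases on the bin index with a logit link (a linear-in-percentile
alternative is available), then redraws each bin's cases as
Binomial(n_b, fitted_b) — the "equal variance given bin sizes" assumption —
and recomputes the contrast; 10 iterations by default to match the
original design, with ≥ 1,000 recommended when a stable SD matters (the
10-draw SD makes individual departures noisy by construction; the
calibration suite therefore interprets departures across many seeds).
Delta observed is computed signed and its absolute value is compared with
the mean absolute expected delta, scaled by the SD of the absolute expected
deltas; the sign convention (positive = canalization = less deviation than
expected) is fixed by the interpretation of protective associations.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analyses assume:

- metabolite level = √h²·PGS + √(1−h²)·noise on a standardized latent
  scale, shifted to a positive concentration scale (default 1.5 ± 0.3),
  with per-repeat measurement noise (SD 0.05, 2 repeats) and QC warnings at
  2% — so the PGS explains ~h² of the collapsed level (verified at
  n = 50,000 within [0.47, 0.53] for h² = 0.5);
- disease status from a logistic model on the log-odds scale, so the
  generative coefficients are exactly the estimands of the analysis models
  (this is why a logistic rather than probit-threshold liability was
  chosen: parameter-recovery tests are exact, not approximate);
- BMI log-normal with median 27 and σ solved so P(BMI > 30) hits the target
  prevalence (default 25%); WHR normal per sex with means solved from
  sex-specific obesity prevalences (defaults 40% of women, 30% of men —
  more women obese by WHR, as observed in adult cohorts); BMI–WHR latent
  correlation 0.5. Only ranks and cutoffs matter downstream, so marginal
  shape fidelity beyond this is irrelevant;
- GWAS summary statistics with se = 1/√(2·maf·(1−maf)·n), maf ~ U(0.1, 0.5),
  true per-allele exposure effects |N(0.15, 0.03)| with the effect allele
  oriented exposure-increasing — the strong-instrument regime of
  genome-wide-significant metabolite loci (fatty-acid GWAS hits at the
  FADS/ELOVL clusters are of this order). Defaults n_exposure = 250,000 and
  n_outcome = 200,000 reflect current meta-analysis scale; at these sizes
  the regression dilution of IVW from noisy exposure effects (~0.1% of the
  estimate) and the finite-sample ratio-noise shift of the weighted median
  are second-order, so estimator properties are tested in the regime the
  design assumes. Outcome effects are causal·βx plus a direct effect
  N(pleiotropy_mean, pleiotropy_sd) for a configurable invalid fraction.

Not emulated: linkage disequilibrium and real genotypes (instruments are
independent), population structure (PCs are pure noise covariates),
age-dependent incidence, metabolite–metabolite correlation, and selection/
ascertainment. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the assumed structure, not robustness to
confounding, relatedness, or LD-induced instrument correlation in real
biobank data.

## Calibration study designs (problem sizes)

Chosen so the full battery runs in a few minutes on one core while keeping
Monte Carlo error well below the effects being measured: MR recovery and
robustness use 100 replicate pairs of 50 SNPs; association type-I error
uses 200 null cohorts of n = 5,000 (≈ 500 cases each, large enough that
Wald p-values are calibrated); planted-effect recovery uses one cohort of
n = 100,000; null triangulation uses 20 cohorts × 2 metabolites × 3
diseases; delta-departure calibration uses 50 cohorts of n = 40,000 at 20%
prevalence with a strong protective gradient (β = −0.4) — tail bins of the
obese stratum then hold ~200 individuals, keeping binomial noise below the
planted interaction signal (γ = −0.5 on PGS × obesity). The end-to-end demo
uses n = 20,000 with 12 diseases and completes in seconds.

## Known limitations

- Weighted-median SE is bootstrap-based; with very few instruments (3–5) it
  can be unstable — the estimate itself is exact.
- The outlier-removal procedure is a Q-contribution heuristic; it is
  deterministic and conservative (Bonferroni per round) but, like all such
  procedures, can keep a coordinated cluster of invalid instruments.
- Delta departure with 10 expected iterations has a heavy-tailed null; single
  comparisons beyond ±2 SD should be read as screening signals, and
  conclusions drawn from averages over many diseases or seeds.
- Rare diseases near the 50-case floor can separate under the full covariate
  set; such fits are flagged, not silently dropped.
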
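# Methods

## The model

The package estimates how genetic and environmental influences on
insomnia symptoms differ between adolescents with short (< 7 h/night)
and normal/long (≥ 7 h/night) self-reported sleep duration, using twin
pairs. The classical ACE decomposition writes the phenotypic variance as

    Var(y) = a² + c² + e²

with `a` the additive-genetic path (the A factor correlates 1.0 across
MZ co-twins and 0.5 across DZ co-twins), `c` the shared-environment path
(C correlates 1.0 within any pair raised together) and `e` the
non-shared-environment path (E is independent across twins and includes
measurement error, so `e > 0` always).

Because sleep duration moderates the decomposition, pairs are split into
six likelihood groups: {MZ, DZ} × {concordant short, concordant
normal/long, discordant}. This is structurally a sex-limitation model
with sleep duration in place of sex — with the important difference that
MZ pairs *can* be discordant for the moderator. Discordant pairs are
ordered so twin 1 is the short sleeper; this is a relabelling, not a
data alteration.

The implied moments per pair are:

* concordant group g: means `(μ_g, μ_g)`, variances `a_g² + c_g² + e_g²`,
  cross-twin covariance `α·a_g² + c_g²` with `α = 1` (MZ) or `0.5` (DZ);
* discordant pairs: means `(μ_s, μ_n)`, each twin's own variance, and
  cross-twin covariance `α·r_A·a_s·a_n + r_C·c_s·c_n`.

The correlations `r_A(MZ)`, `r_A(DZ)`, `r_C` carry the *qualitative*
heterogeneity: values below 1 mean different genetic or shared-
environmental factors operate in the two sleep groups. They act only on
discordant-pair covariances; the cross-twin E covariance is fixed at 0.
This parameterization reproduces the canonical free-parameter counts
(6 paths + 2 means + 3 correlations = 11) without introducing a
non-standard "shared E" notion.

Three nested variants are fitted:

| variant | free parameters | restriction |
|---|---|---|
| full heterogeneity | 11 | none |
| quantitative heterogeneity | 8 | `r_A(MZ) = r_A(DZ) = r_C = 1` |
| homogeneity | 4 | additionally `a_s=a_n, c_s=c_n, e_s=e_n, μ_s=μ_n` |

AE/CE/E submodels (dropping one or both of A and C in *both* groups) are
attached to the quantitative variant, which is where the comparison
sequence tests them. The full model is always fitted as ACE.

## Estimation

The objective is full-information maximum likelihood: complete pairs
contribute a bivariate Gaussian log density at the implied moments of
their group; a twin whose co-twin lacks phenotype data contributes the
univariate marginal of their own sleep group. Because all pairs in a
group share the same implied moments, the likelihood is evaluated from
per-group sufficient statistics (count, sum, cross-product matrix),
making the evaluation cost independent of cohort size.

Age and sex are regressed out of the phenotype and the residuals
z-standardized *before* fitting; covariate slopes are not part of the
likelihood. This keeps the parameter counts at 11/8/4 and is why the
group means are estimated on the residual scale.

Optimization is quasi-Newton (L-BFGS-B) from at least five dispersed
starts: standardized-component configurations drawn from a flat
Dirichlet, mapped to paths scaled by the per-group sample variances.
Paths are estimated unconstrained (sign-indeterminate — only their
squares enter concordant moments) and reported as variance shares; the
C→0 boundary is handled naturally by `c² ≥ 0`. The qualitative
correlations are box-bounded in [−1, 1]. A fit is flagged converged when
the best start terminates successfully and the best two starts agree in
−2LL within 1e-4. Non-positive-definite trial covariances are rejected
with a large objective value.

Model comparison uses the likelihood-ratio chi-square test (difference
in −2LL at the difference in free parameters: 3 for full vs
quantitative, 4 for quantitative vs homogeneity, 2 for component drops)
and the AIC (`−2LL + 2k`). The "best" model is the lowest-AIC variant
whose LRT against its reference is non-significant, ties going to fewer
parameters.

## Profile confidence intervals

Confidence intervals for standardized components are likelihood-based:
the component's variance share t is fixed by reconstructing its path
from the other two (`p_fixed² = t/(1−t)·(p₁²+p₂²)`), the remaining
parameters are re-optimized, and the bounds are the values of t at which
the profiled −2LL exceeds the minimum by 3.841 (χ²₁ at 95%). Bounds are
located by bisection to 1e-4 and clamped to [0, 1] when the profile
never crosses the threshold on a side (the `0 (0, 0.04)` pattern for a
boundary C estimate arises this way). Each inner re-optimization is run
from both the MLE configuration and the previous profile solution;
either start alone can stall far from the optimum, and taking the better
of the two keeps the profile curve clean.

Calibration, measured by the test suite under a homogeneity-truth
generator: profile-CI coverage of the A share is at its nominal 95%
(±3% over 200 replicates) at the reference design size, and the 4-df
quantitative-vs-homogeneity LRT statistic matches χ²₄ by a KS check.
The extreme 5% tail of that LRT is mildly inflated at the reference
size (empirically ≈ 6–7% rejections; the statistic's mean is correct at
≈ 4.07 and the inflation disappears as group sizes grow), so the
nominal-rate check runs at 10× group sizes where asymptotics hold. This
is a known finite-sample property of variance-structure LRTs, not an
implementation artifact — polishing both optima changes nothing.

## Twin-pair and cross-trait correlations

Per-group twin correlations are Pearson correlations with Fisher-z 95%
CIs using the number of pairs. MZ concordant buckets are double-entered
(each pair contributes (y₁,y₂) and (y₂,y₁)) because twin ordering there
is arbitrary; the output flags this. A likelihood-based CI is available
through the pair-correlation model for cross-checks.

The cross-trait analysis estimates the within-person correlation between
insomnia symptoms and a co-trait (anxiety, anxiety sensitivity,
depression, GCSE mean grade, psychotic-like symptoms) per sleep-duration
pair group (concordant-short, concordant-normal, discordant) while
controlling for twin relatedness: the pair vector (X₁, Y₁, X₂, Y₂) is
modelled as 4-variate Gaussian in which the within-person correlation is
the estimand (equated across twins) and the cross-twin same-trait and
cross-trait correlations are zygosity-specific nuisance parameters.
Means and SDs are equated across twins within a bucket — including the
discordant bucket, where the two twins come from different sleep groups;
both traits are age/sex-residualized first, so residual group mean
differences are second-order. Missing entries are handled by FIML over
missingness patterns. Equality of the three group correlations is a
2-df LRT (joint refit with one shared correlation); the five-trait
family uses a Bonferroni threshold of 0.05/5 = 0.01.

## Polygenic-score quadrants

Individuals are classified by the ISI cut-off (insomnia iff total > 8 —
the group-definition convention is strict inequality, so a total of 8 is
"no insomnia") and sleep duration into four quadrants. One polygenic
score per pair (twin 1's, at three LDpred-style p-value thresholds) is
compared across quadrants by a hand-rolled one-way ANOVA, an ANCOVA
realized as covariate-residualized ANOVA with the denominator df reduced
by the number of covariates (an approximation to the general-linear-model
ANCOVA; exact when covariates are balanced across groups), and a pooled-
variance Student t-test of quadrant 1 vs 3 (pooled rather than Welch, to
match the classical ANOVA framework used alongside). Tukey HSD post-hoc
comparisons are attached after a significant omnibus test; no
multiple-testing correction is applied when every test is
non-significant.

## The synthetic cohort generator

Real data of this design are access-restricted, so the generator
reproduces the statistical skeleton the analyses assume. Defaults are
the study conditions:

| quantity | default | source/rationale |
|---|---|---|
| pairs | 4000 | reference design size |
| MZ fraction | 0.354 | reference sample composition |
| male fraction | 0.460 | reference sample composition |
| short-sleep prevalence | 0.215 | chosen with the liability paths so expected six-group counts approximate the reference design |
| sleep-liability ACE | aL²=0.33, cL²=0.17, eL²=0.50 | least-squares fit of the MZ/DZ orthant probabilities to the reference six-group proportions at that prevalence |
| phenotype ACE | short: A=.13, C=.19, E=.68 (total var 1.2); normal: A=.35, C=0, E=.65 (var 1.0) | the quantitative-heterogeneity estimates; larger short-group variance mirrors the reported pattern |
| group means | μ_s=0.3, μ_n=0 SD | short sleepers report more symptoms |
| co-trait correlations | anxiety .46/.38, anx. sensitivity .42/.34, depression .47/.44, GCSE −.03/−.02, psychotic .26/.25 (short/normal) | the reported per-group correlation patterns |
| PGS R² | 0.005 | "below 1%" weak-proxy regime |
| singleton pairs | 2% | produces the FIML singleton path |
| age | 16 ± 0.5 (uniform) | cohort assessed at 16; jitter gives the covariate variance |
| covariate effects | +0.5 ISI points (female), +0.3/year (age) | small, removed by residualization |

Sleep duration arises from an ACE-structured liability (MZ/DZ liability
correlations 0.50/0.335) thresholded at the prevalence; continuous hours
are decorative uniform fills (4–6.9 short, 7–10 otherwise) because
downstream analyses use only the < 7 h label. The phenotype uses latent
factors *independent* of the sleep liability by default — the analysis
conditions on observed sleep group, so no cross-loading is needed to
test it; `moderator_phenotype_corr` correlates the two factor sets for
robustness studies. Co-traits load on the standardized phenotype with a
group-specific loading equal to the target correlation, plus unit
noise. The PGS proxy for twin 1 loads on that twin's genetic factor with
loading `sqrt(R²/A-share)`; three threshold columns share the genetic
signal with independent noise.

One master seed drives fixed per-stage substreams (structure, sleep,
phenotype, PGS, missingness, one per co-trait), so adding a co-trait
never perturbs the phenotype draw and the same seed yields byte-identical
cohort CSVs.

What the generator does **not** emulate: the right-skewed marginal of
real ISI totals. Scores are mapped linearly onto questionnaire scales
(ISI: 10 + 3·phenotype, clipped to [0, 28]) with locations chosen so
clipping mass is negligible (≈ 0.1%), because censoring at the floor
would corrupt the Gaussian covariance structure every analysis consumes.
The cost is an unrealistically high insomnia-flag prevalence (≈ 75% vs
≈ 13% in real adolescent data) — quadrant sizes in the PGS stage are
therefore not realistic proportions, and passing tests say nothing about
skew-robustness on real scores. Genotypes, LD structure, ascertainment
and attrition are out of scope.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to finish on a desktop:
parameter recovery uses 25 cohorts at 20× the reference six-group sizes
(mean standardized components within ±0.02 of generating values);
null calibration and CI coverage use 200 replicates; the equality-LRT
type-I check uses 200 cohorts of 800 pairs; power-style checks use a
handful of reference-size cohorts.

## Known limitations

* The ANCOVA is the residualized approximation, not the full GLM; with
  markedly unbalanced covariates across groups the two differ.
* The cross-trait model equates means/SDs across twins within a bucket;
  a fully group-specific mean structure for discordant pairs would add
  two parameters per bucket with negligible effect after
  residualization.
* Opposite-sex DZ pairs are pooled with all DZ pairs; no sex-limitation
  structure is modelled on top of the sleep moderator.
* The phenotype is treated as continuous Gaussian; no ordinal/threshold
  liability fitting, dominance (ADE), or continuous (Purcell-style)
  moderation beyond the two-group split.
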
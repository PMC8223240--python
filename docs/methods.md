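# Methods

This note documents the models, algorithms and design choices behind
`famdep`, in the order the pipeline runs them.

## Questionnaire scoring

The instrument screens with the two core DSM depression symptoms
(depressed mood, loss of interest). Respondents negative on both skip the
remaining symptom section; those blanks are *structural* — the section was
never asked — and are treated as "no", which classifies the respondent as
a control. A **case** must satisfy all of: at least one core symptom, at
least five of the nine DSM criteria (the two core symptoms plus seven
others: loss of energy, sleep problems, guilt/worthlessness,
concentration problems, psychomotor changes, weight/appetite change,
suicidal ideation), and an affirmative answer to the serious-interference
item. A **control** is anyone who fails any of the three conditions.

Respondent-missing items are resolved by completion logic: the scorer
computes the affirmative count and the maximum count attainable if every
missing item were "yes". A respondent is `unknown` only when both a
case-yielding and a control-yielding completion exist; if every completion
agrees, that status is assigned. This maximises the usable sample without
imputation, and reduces to the obvious rules in the complete-data case.

Current (last-year) status gates the lifetime status on the last-year
episode item: `current = case` requires `lifetime = case` **and** an
episode in the last year, so a current case is a lifetime case by
construction. A denied last-year episode makes the respondent a current
control regardless of lifetime ambiguity.

The strict control definition (used for the genetic analyses) excludes
controls reporting diagnosis or treatment of another psychiatric
disorder. A missing answer is treated as "no" — exclusion requires an
affirmative self-report — and flagged.

Covariates: education is harmonised to low/medium/high via a per-cohort
mapping config, with high-without-diploma downgraded to medium; BMI =
weight/(height/100)² banded at 18.5/25/30; age banded 18–39/40–59/60+
(inclusive lower bounds, matching the printed labels). Quality-control
bounds are strict inequalities (exactly 150 cm is kept): age > 110,
height outside (150, 220) cm, weight outside (45, 200) kg, BMI outside
(15, 50), applied in that fixed order with first-hit attribution and the
BMI rule evaluated only on survivors of the height/weight rules. The age
bound is the package's own reading of "typo/outlier" cleaning (the one
documented exclusion was a 120-year-old); it only needs to separate
plausible from impossible ages.

## Prevalence meta-analysis

Cohort prevalences are pooled on the logit scale — proportions are
bounded, and the logit keeps normal-theory weights sensible at low
prevalence — with inverse-variance weights and the DerSimonian–Laird
moment estimator of the between-cohort variance tau². The per-cohort
variance is 1/cases + 1/non-cases, with a 0.5 continuity correction for
zero or full cells. Heterogeneity is reported as Cochran's Q and
I² = max(0, (Q − df)/Q) × 100 with a test-based (Higgins–Thompson)
confidence interval. Subgroup analyses pool each stratum with its own
tau² and compare stratum means by a random-effects between-group Q
against chi² with (#strata − 1) df. Meta-regression uses dummy-coded
study-level moderators (reference level = alphabetically first stratum),
a method-of-moments residual tau² generalised to the design matrix, the
omnibus Wald statistic QM on the moderator block, and reports
heterogeneity explained as 100 × max(0, 1 − tau²_res/tau²_base). Constant
moderators alias the intercept and are dropped (QM = 0) rather than
raising the rank-deficiency error reserved for genuinely collinear
designs. Leave-one-out sensitivity re-pools k times in input order.
The multiple-testing threshold is plain Bonferroni:
alpha / (phenotypes × tests per phenotype).

## Pedigree variance components

Family relationship structure comes from FAM-style pedigree files with a
twin-group and zygosity extension. The additive relationship matrix A is
built by the tabular method (parents before offspring,
a(i,j) = ½·a(father,j) + ½·a(mother,j), founders unrelated, no
inbreeding modelled), after which MZ pairs are collapsed to genetic
identity. The shared-environment matrix C is an indicator for co-twins
only — MZ and DZ alike — reflecting the environment twins share growing
up; ordinary siblings and households are deliberately not given a shared
component.

The phenotype (continuous, or binary 0/1 on the observed scale) is
modelled as multivariate normal per family with covariance
V = sigma²_A·A + sigma²_C·C + sigma²_E·I and fixed effects (intercept,
mean-centred age, sex coded −1/+1 so the sex effect reads as a
half-difference). Estimation is REML: the restricted likelihood is
accumulated family by family, and families sharing an (A, C, missingness)
pattern are batched into single tensor contractions — a twin register
has a handful of family configurations repeated thousands of times, which
makes a fit on ~15,000 individuals take well under a second. Gradients
are analytic (tr(P dV) − y'P dV P y with the block structure exploited);
optimisation is bound-constrained L-BFGS-B with nonnegative variance
components (relative likelihood tolerance 1e-12, gradient tolerance
1e-7, 200 iterations). Components estimated at the zero bound are
flagged: their Wald standard errors are unreliable. Standard errors come
from a central-difference Hessian of the restricted likelihood at the
optimum; the heritability h² = sigma²_A/(sigma²_A+sigma²_C+sigma²_E)
gets a delta-method SE.

The bivariate model stacks two traits per family with per-trait A/C/E
variances, an additive cross-covariance and a unique-environment
cross-covariance (the twin-C cross-covariance is fixed at zero — the C
components themselves are typically indistinguishable from zero for these
traits — but per-trait C remains free). Individuals measured on one
trait contribute their observed rows only. The cross terms are optimised
as correlations in (−1, 1) so the implied 2×2 blocks stay positive
semidefinite, with moment-based starting values (per-trait variances and
the within-person cross-correlation) to select the right likelihood
basin. Degenerate input — a trait regressed on an exact copy of itself —
makes the restricted likelihood unbounded (the within-person difference
has zero variance); any re-measurement with nonzero error is fine and
recovers rg ≈ 1.

Binary traits are analysed on the observed 0/1 scale with this same
linear model. The classical linear bridge to the liability scale
(h²_liab = h²_obs·K(1−K)/z²) is available as an explicit function and is
never applied silently.

## Liability-threshold generator and exact calibration

The synthetic cohorts realise exactly the estimator's assumptions:
founder breeding values N(0, h²_liab), offspring = parental midpoint +
Mendelian deviation N(0, h²_liab/2), MZ co-twins share one breeding
value, co-twins share a common-environment deviate of variance c²_liab,
residuals fill to unit liability variance, and a binary trait is
liability > Φ⁻¹(1−K). An optional sex threshold shift raises female
prevalence. Assortative mating, age effects on liability and
participation bias are deliberately absent. Ages are generated with
family structure (parents older than twins) but do not enter the
liability, so passing recovery tests demonstrates estimator correctness
under the model's own assumptions, not robustness to real-data
violations of them.

The default family mix approximates an extended twin register: every
family has two founders and a twin pair (45% MZ, the register's MZ:DZ
pair ratio), parents are study members in half the families, a quarter
add a full sibling, and a quarter attach a spouse and one child to the
first twin — about 3.75 phenotyped members per family.

Because the observed 0/1 scale is a thresholded liability, targeting an
*observed-scale* quantity requires inverting the threshold model. The
classical linear bridge is a small-correlation approximation that fails
badly at common prevalences (at K = 0.10 an observed-scale 0.34 maps to
liability 0.99, whose exact observed MZ correlation is 0.91, not 0.34).
The generator therefore calibrates exactly: for a candidate liability
parameter it computes each family configuration's exact observed-scale
covariance matrix from bivariate-normal orthant probabilities, locates
the pseudo-true REML estimand on those covariances (the probability limit
of the estimator), and bisects the liability parameter until the estimand
equals the requested observed-scale target. The same machinery calibrates
the generating liability-scale genetic correlation for bivariate targets.
The calibration is deterministic — no simulation is involved — and the
estimators never see it: they recover the target from data alone.

## Polygenic-score prediction

Scoring is the oriented weighted dosage sum: dosage columns are labelled
with the allele they count; a dose is flipped to 2 − dose when that
allele is the weight table's other allele, and variants matching neither
orientation are dropped with a warning. Scores are standardised within
the analysis sample. Prediction is logistic GEE (statsmodels) with an
exchangeable working correlation over families and robust sandwich
standard errors, reported as the odds ratio per SD of score. The decile
plot sorts stably by (score, id) with boundaries at rank·n/10, so the
n-weighted decile mean equals the overall case fraction exactly.

Explained variance is the Nagelkerke pseudo-R² difference between the
full and covariates-only *independence* logistic fits (both against the
intercept-only likelihood); the working correlation does not enter the
likelihood. The liability-scale conversion is the Lee et al. (2012)
ascertainment-corrected transformation with c = [K(1−K)/z²]·[K(1−K)/
(P(1−P))] and theta = a(a−t), a = (z/K)(P−K)/(1−K). The population risk
K defaults to the sample case fraction P (appropriate for
population-based samples) and is configurable.

The PRS cohort generator transmits the true score within sibships like a
breeding value (within-family correlation ½), adds a shared familial
liability component (default variance 0.30, a typical familial
aggregation for depression) and thresholds at the configured case
fraction. Direct-score mode is the default; dosage mode expands the
score into Hardy–Weinberg variants (with half the weight rows
deliberately allele-swapped) to exercise scoring-time orientation
matching.

## Replication experiment sizes

The recovery experiments use 4,000 families (~15,000 individuals) per
replicate for univariate heritability, 5,000 families (~19,000
individuals, both traits observed) for the bivariate genetic correlation,
n = 50,000 in sibships of four for the GEE odds ratio, and 20 replicates
per configuration — sizes chosen so the replicate-mean standard error is
a few thousandths on h² and a couple of hundredths on rg, comfortably
inside the tolerances being checked, while a full recovery study runs in
minutes on one core.

## Known limitations

* The ACE estimator treats binary data as Gaussian on the observed scale;
  it is consistent for the pseudo-true observed-scale decomposition, not
  a threshold-model (tetrachoric) fit.
* Nonnegativity constraints make boundary estimates (typically sigma²_C
  here) slightly bias h² downward in finite samples; the recovery tests
  absorb this within their tolerances.
* The C component is twin-pair-specific; household or sibling shared
  environment, dominance, X-linkage and sex-limitation models are out of
  scope, as are GWAS, LD-aware weight shrinkage and genotype QC.
* The meta-analysis module assumes within-cohort binomial sampling on the
  logit scale; it does not model publication bias. Normal-interval
  DerSimonian–Laird CIs are known to undercover (≈90% instead of 95%)
  when pooling only a handful of studies; the coverage check is run at
  k = 30 cohorts, where the interval is calibrated.
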
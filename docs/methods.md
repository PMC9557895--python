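# Methods

## Model and procedure

The analysis targets interaction between a weighted genetic risk score
(GRS) and a binary exposure on a continuous outcome (BMI).  The working
model is ordinary least squares on the pooled sample,

    y = β₀ + β_G·G + β_E·E + β_int·(G×E) + γ'C + ε,

with y the rank-based inverse-normalized outcome, G the allele-count-scale
GRS, E the exposure, C covariates (age, sex, centre, deprivation index,
five principal components, genotyping array in the default pipeline).
β_int and its Wald P-value are the quantities of interest; stratified fits
(y ~ G + C within E = 0 and E = 1) report the per-allele association in
each group, and covariate-adjusted contrasts of *raw* BMI between exposure
groups within the bottom and top GRS deciles express the interaction in
kg/m².  Two-sided P-values use the normal approximation to the t statistic;
the exact t distribution is used when residual df < 200, where the
approximation is visibly anticonservative.

A significant β_int is necessary but not sufficient evidence of effect
modification: if cases have a higher outcome mean and SD than controls, any
scale-dependence of the genetic effect produces a non-zero β_int without
any exposure-specific biology.  The negative-control experiment quantifies
exactly that pathway.

## GRS construction

Variants with negative discovery weights are recoded to the
trait-increasing allele (weight negated, allele labels swapped, dosage
replaced by 2 − dosage); recoding is idempotent and the score is invariant
to the input orientation.  The weighted score Σ βₙ·SNPₙ is rescaled by
M/Σβ so a score unit reads as one average-weight risk allele and the score
of an individual homozygous for every risk allele is 2M.  The printed
definition of such scores is ambiguous between this and plain division by
Σβ; the two differ by the constant M, cannot change any regression
statistic, and both are available (`rescale="allele_count" | "sum_beta"`).
Missing dosages are mean-imputed at 2·eaf with per-variant missingness
reported; individuals missing every dosage are flagged and excluded.
Decile ties are broken by stable input (id) order for cross-run
determinism.

## Negative-control experiments

Targets are the real groups' sizes, means and SDs of raw BMI.  Per
replicate, two **disjoint** pseudo-groups hitting all four moments within a
tolerance (default 0.05, i.e. one-decimal-place agreement) are selected
from the full analysis pool regardless of true exposure, and the identical
interaction model is refitted with pseudo-exposure = group membership.
With R replicates and c of them giving an interaction P strictly below the
observed one, the empirical P is the plain proportion c/R (no +1
correction; the convention matches reading "67 of 1000" as 0.067).  The
median replicate (lower-middle rule for even R) is reported as the
representative negative analysis.

Selection is a seeded swap-descent optimizer: a density-ratio-tilted random
start (members drawn with probability proportional to the target-normal
density) followed by batched random member/non-member swaps accepted when
they reduce L = Σ_groups (mean − target)² + (sd − target)², stopping at
tolerance.  Only the achieved moments enter the statistics, so the search
path is irrelevant beyond determinism, which a single integer seed
guarantees.  When the two group sizes exhaust the pool — the usual case,
since targets come from a case/control split of the same sample —
selecting one group fixes the other, so the two groups are optimized
jointly as a partition; with slack in the pool they are selected
sequentially, the second excluding the first.  Targets that cannot be
reached within the iteration budget raise an infeasibility error carrying
the best-achieved moments; `run_negative_experiments` aborts if more than
half of the replicate selections fail, reproducing the realistic failure
mode of moment-matching with very large groups.  A strict-R policy (on by
default) redraws failed replicates up to a 2R attempt budget; otherwise
failures are logged and excluded from the denominator.

Replicate models reuse the real model's covariates by default
(`include_covariates=False` drops them); the choice is exposed because
either convention is defensible and the replicate P distribution is what
matters.

The summary-statistics mode replaces matched selection by direct draws:
group BMI from Normal(mean, sd) and genotypes from Hardy–Weinberg at the
panel's frequencies, independent of group — an interaction null given only
another study's printed group sizes and moments.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
chosen to resemble a large population-study depression subset: case
prevalence 0.24, cases +0.6 kg/m² with an SD ratio of 1.16 (27.2 (5.1) vs
26.6 (4.4) kg/m²), 15.5% of cases treated, a 73-variant panel with
frequencies in (0.05, 0.5) and per-allele effects of ~0.02 SD, BMI
26.7 (4.6) kg/m².  Key mechanisms:

- **Case selection conditional on BMI** via P(case | z) =
  expit(a + b₁z + b₂(z² − 1)), with (a, b₁, b₂) solved by Nelder–Mead so
  the expected prevalence, case-minus-control mean and case/control SD
  ratio hit their targets; the quadratic term lets selection favour the
  tails, which is what raises the case SD.  Matching moments is therefore
  a calibration, not a constraint — the same way real selection induces
  distribution differences.
- **Noise models**: `additive_normal` is homoscedastic with marginal SD
  exactly `bmi_sd`; `multiplicative_lognormal` makes log-BMI linear in the
  genetic burden with (μ, s) solved so the *raw* mean and SD match the
  configured values, producing raw-scale variance that grows with the mean.
  Mean–variance coupling appears iff this mode is on or the case SD ratio
  exceeds 1.
- **Planted interactions**: `true_interaction` = γ adds
  γ·(GRS − mean)·E on the latent (inverse-normal) scale after exposure
  assignment, leaving group means unchanged; γ is the per-allele
  coefficient the downstream fit should recover.
- **Severity** (cases only) is Binomial(severity_max, expit(0.6z)), so the
  above-median-severity group is heavier; the treated flag is Bernoulli
  within cases.
- **Covariates** are independent of genotype and exposure unless
  `confound_covariates` links the deprivation index to BMI (r ≈ 0.4) for
  exercising the Keller adjustment.

What the generator does *not* emulate: linkage disequilibrium between
variants, imputation uncertainty, population stratification, secular BMI
trends, or selection into the study.  Passing tests therefore demonstrate
the statistical machinery — calibration, recovery, artefact reproduction
and correction — under the assumed structure, not robustness to those
real-data complications.

## Numerical choices and problem sizes

- INT uses the Blom offset (3/8), average ranks for ties, computed once on
  the full analysis sample; the offset is configurable.
- Rank-deficient designs raise an error naming the offending columns
  (greedy rank-increment scan); categorical covariates enter as indicators
  against the most frequent level.
- Swap descent uses batches of 64 proposals, accepting the best improving
  one; 400 consecutive non-improving batches trigger a fresh tilted
  restart within a 200 000-proposal budget.  Running sums/sums-of-squares
  make each proposal O(1).
- Simulation-based checks run at deliberately modest sizes chosen to keep
  the full suite in minutes while leaving comfortable statistical margins:
  type-I calibration on 1000 cohorts of n = 5000 (20 variants), recovery of
  γ = 0.05 on 200 cohorts of n = 20 000, artefact reproduction on 500
  cohorts of n = 20 000 (73 variants), and 2 × 50 negative-control runs
  (R = 200, n = 5000).  The artefact/correction thresholds (≥ 80% of runs)
  are far from the observed behaviour (≈ 95–100%) at these sizes.
- All randomness flows from integer seeds through `numpy.random.SeedSequence`
  substreams, so adding downstream draws never perturbs upstream ones and
  every table is byte-identical under a fixed config (the pipeline manifest
  records the config hash and seed).

## Known limitations

- Matching covers the first two moments only, by design — the question is
  precisely whether means and SDs explain the interaction; differences in
  shape beyond that (skewness of the case distribution, say) remain in the
  real groups but are only approximately reproduced by the optimizer's
  implicit selection.
- The empirical P has resolution 1/R and, as a plain proportion, can be
  exactly 0; R = 1000 is the sensible default where runtime allows.
- OLS with homoscedastic SEs is used throughout, matching standard
  practice for these analyses; under strong raw-scale heteroscedasticity
  the *naive* raw-scale test's miscalibration is the studied phenomenon,
  not something the package corrects elsewhere.
- The exposure-calibration optimizer matches moments approximately (it is
  itself a calibration); extreme combinations of prevalence, shift and SD
  ratio can be unattainable by a logistic-quadratic tilt, and realized
  moments should be checked on generated cohorts.
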
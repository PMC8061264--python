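# Methods

This note documents the models behind `perchmon`, the choices made where
the design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Data model

Genotypes are biallelic SNP dosages (0/1/2, −1 missing) for individuals ×
loci, with per-locus metadata (sequencing tag, DArT-style reproducibility,
missingness).  One fish can yield several samples (recaptures); identity
analysis collapses them.  The unit of the survival analysis is the
broodstock pair: one dam × one sire mated in a given breeding season, with
an estimated larvae count and a fingerling share of that season's stocking
total.

## SNP quality control

Filter order: one SNP per tag (first listed) → reproducibility ≥ threshold
(default 1.0) → locus missingness ≤ 0.10 → individual missingness ≤ 0.25 →
loci monomorphic within a caller-chosen subset.  Because removing a called
individual can raise another locus's missing fraction, the two missingness
stages are swept to a fixed point; this makes the whole filter exactly
idempotent at an otherwise negligible cost.  The sex-linkage screen flags
loci where, among known-sex broodstock, every called genotype is homozygous
in one sex and heterozygous in the other — the hemizygosity signature that
would violate the codominant-marker assumption; loci with fewer than two
called fish of either sex are reported untestable, never flagged.

## Genotyping-error model

All relatedness likelihoods share one channel: an observed genotype equals
the true genotype with probability 1 − e and is otherwise one of the other
two genotypes uniformly, with e = 10⁻⁴ by default.  This is the simplest
model consistent with a single per-genotype error rate; it is applied to
offspring *and* parent observations (true parental genotypes are
marginalised under Hardy–Weinberg priors).

## Parentage

The LOD of a candidate pair is the summed per-locus log ratio of the
offspring's observed genotype probability under Mendelian transmission from
the pair versus under random draws from population allele frequencies
(computed once from all genotyped candidates and held fixed).  Each
offspring takes its maximum-LOD pair; acceptance requires all of:

1. **confidence > 0.95**, calibrated by simulation: offspring are simulated
   from the candidate pairs' observed genotypes with 70% of true pairs
   sampled and 90% of loci typed; the confidence attached to an observed
   LOD margin m is the fraction of simulated offspring with margin ≥ m that
   landed on their true pair;
2. **positive LOD**;
3. **Mendelian exclusions ≤ 2% of trio-complete loci**.  True trios at
   e = 10⁻⁴ essentially never show exclusions (observed max 1 of ~900
   loci), while the dangerous impostor class — a grandchild of the pair,
   i.e. the offspring of two stocked full sibs — shows ~5%.  Without this
   screen such fish are confidently mis-assigned to their grandparental
   pair; with it, validation precision on the reference simulation is 1.0
   at recall 0.99.

Ties are reported and left unassigned.

## Sibship

Full-sib clustering uses pairwise log likelihood ratios of full-sib versus
unrelated observed-genotype pairs (parents marginalised, error-aware), a
merge threshold calibrated on simulated unrelated and full-sib pairs,
single-linkage merging, and greedy clique splitting of any group whose
internal pairs do not all pass (splits are logged).  Group confidence is
the minimum over internal pairs of the empirical probability that an
unrelated pair scores lower.  At ≥600 informative loci the two simulated
distributions are separated by hundreds of log-units, so the exact
threshold placement is immaterial; this pairwise scheme deliberately
replaces full-pedigree MCMC for determinism and desk-scale runtimes.

## Ancestry

Per-locus Weir–Cockerham θ (two populations, variance components a, b, c;
missing calls excluded locus-wise; monomorphic loci defined as 0) ranks
loci; those with F_ST ≥ 0.02 between the source reference pools form the
informative panel.  Membership in the source-D gene pool is estimated per
fish by maximum likelihood under the standard admixture mixture — each of
the 2L allele copies is drawn from source D with probability q — via EM
plus a bounded 1-D polish (tolerance 10⁻⁶, verified against a grid search).
This supervised estimator replaces unsupervised MCMC clustering: the
references are labelled, the estimand is the same Q-membership, and the
result is deterministic.  Category thresholds are purely empirical: upper =
min q among known-D references, lower = max q among known-Y references;
overlapping references are a hard calibration error.  Within each full-sib
group only the member with the least missing data is classified and its
label propagated — sibs are pseudo-replicates, not independent draws.
Hybrid classes (pure D, pure Y, F1, F2, BC_D, BC_Y) are scored by mixing
the three parental-origin genotype distributions with each class's expected
ancestry-pair weights ((1,0,0), (0,0,1), (0,1,0), (¼,½,¼), (½,½,0),
(0,½,½)); source frequencies carry an add-one pseudo-count so no genotype
has zero likelihood under any class.

## Origin calls and age

Precedence: identity match to a translocated sample → translocated; else an
accepted parent-pair assignment → stocked; else locally born.  A fish with
both lines of evidence is impossible under the release registry and raises
an error.  Stocked fish are aged by date arithmetic from their pair's
season (hatching fixed at 1 December; capture window treated as 1 April, so
age = capture_year − birth_year − 2/3), truncated into six age classes
0–5.  Non-stocked fish are aged by the rounded inverse of the Gompertz
curve fitted to stocked fish; lengths at or above the asymptote are flagged
for review rather than forced.  Locally born fish whose inferred birth
season had unsampled broodstock, and source-D fish age-compatible with
ungenotyped translocation cohorts, carry explicit ambiguity flags.

## Survival model

For each pair, the minimum number alive at age class a is the number of
distinct assigned offspring whose (oldest) capture age class is ≥ a — the
carry-back rule — for every age class observable for the cohort by the
final monitoring year.  Fingerling output N_f is the pair's larvae share of
its season's stocking total with largest-remainder rounding (season totals
conserve exactly).  The GLMM is k_a ~ Binomial(N_f, logit⁻¹(Xβ + u_year)),
u_year ~ N(0, σ²) on stocking year, fitted by maximising the
Laplace-approximated marginal likelihood (inner 1-D Newton per year for the
random-effect mode, outer L-BFGS-B over (β, log σ); Wald SEs from a
finite-difference Hessian).  Validation: the fit collapses to weighted IRLS
as σ → 0 and matches a 41-node adaptive Gauss–Hermite oracle to <10⁻³ on
small fixtures.  Continuous predictors (age class, parental dissimilarity)
are z-scored by default — the survival differences across cross-types are
otherwise absorbed into intercept scale — with a toggle for raw scales.
Candidate models are {cross-type; dissimilarity; both} × {with, without age
interactions}, all with the age main effect and the year intercept; AIC
(from the same ML objective) ranks them.  Fit is summarised by the marginal
latent-scale pseudo-R², var(Xβ)/(var(Xβ) + σ²_year + π²/3).  This
carry-back construction is a deliberate approximation, not a
capture-recapture likelihood: it conditions on captures and understates
true survivor counts; it is used because it is the construction the
downstream comparisons are defined on.

## Growth

Gompertz L(t) = L∞·exp(−exp(−k(t−t0))) fitted by least squares with
multi-start initialisation (L∞₀ = 1.05·max length; k₀ ∈ {0.3, 0.8, 1.5};
t0₀ = median age; best SSE kept) — the standard three-parameter fisheries
form.  Residuals feed Gaussian mixed models (REML coefficients, ML AICs)
with candidate fixed effects {cross-type; PHt; dissimilarity; cross-type +
PHt; cross-type + dissimilarity} and a stocking-year intercept, via
statsmodels MixedLM.  The inverse t(L) = t0 − ln(−ln(L/L∞))/k ages unknown
fish; with the default 9 mm length noise, ≥90% of integer ages round
correctly.

## Synthetic data generator

The generator is first-class code: it emulates the reference study design
(seven breeding seasons with the published pairs-per-cross-type, stocking
totals summing to 94,029, translocation cohorts of 1,801 with 98.3%
genotyped, three monitoring years) with known truth.  Key choices:

- **Differentiation**: Balding–Nichols beta draws around uniform ancestral
  frequencies.  Two independently diverged pools realise a pairwise F_ST of
  ≈ F/(1 − F/2), so the per-pool parameter is pre-adjusted; the realised
  mean Weir–Cockerham F_ST lands within ±0.01 of the 0.05 target and the
  beta tail supplies a few hundred loci above the 0.02 cutoff.
- **Survival**: annual Bernoulli at logit(intercept −0.8 + cross offset
  {DxD 0, DxY +0.6, YxY +1.2} + 0.5·age + u_cohort), u ~ N(0, 0.3²) per
  birth cohort.  Capture probabilities (0.0003 age-0; 0.002 older) are not
  published quantities; together with the survival intercept and a
  recruitment rate of 9 age-0 recruits per mature adult per season they
  were chosen once so the default run reproduces the study's design scale —
  a few hundred monitoring captures, roughly one-third stocked and
  two-thirds locally born, age-0 fish rare in the catch.
- **Recruitment**: random mating among survivors mature at age 3+; a
  recruit's survival cross-type category follows its pedigree ancestry
  fraction (≥0.75 D-like, ≤0.25 Y-like, else mixed).
- **Maturity at 3 for both sexes**, generation overlap allowed.
- **Apportionment**: larvae-proportional fingerling shares with
  largest-remainder rounding, so season totals are exact.
- **One seed** drives every draw through a single generator stream;
  re-running a config is byte-identical.

What the generator does *not* emulate: spatial river structure,
environmental covariates, sex-biased behaviour, linkage between loci, and
within-year mortality timing (a fish dying in its a-th year counts as dead
for fractional ages beyond a).  Passing tests therefore demonstrate that
the pipeline recovers planted truths under these idealisations, not that
any particular field dataset would yield the same estimates.

## Known limitations

- Admixture assumes independent loci and known-ish source frequencies; for
  multi-generation recruits the realised genome share drifts around the
  pedigree expectation, so monitoring-wide mean |q̂ − q| (~0.06) runs above
  the ~0.04–0.05 achieved for first-generation classes.
- The supervised ancestry estimator cannot discover unmodelled structure
  (a third source would be absorbed into the two clusters).
- Minimum-number-alive is a lower bound conditioned on capture effort; the
  GLMM's binomial denominator treats fingerling shares as exact.
- Parent-pair assignment assumes candidate pairs are the only related
  configurations worth ranking; single-parent (dam-only/sire-only)
  assignment is out of scope, and recruits with exactly one stocked parent
  are intended to fall to the exclusion screen rather than be assigned.

## Problem sizes used in validation

The test suite runs the full default design once (≈1,100 loci, ~94k
simulated fates, ~2,200 genotyped samples) and reuses it session-wide;
parameter-recovery studies use 100 replicates of the pair-level survival
process at the published breeding-programme scale, and quadrature/grid
oracles run on deliberately small fixtures where exhaustive computation is
exact.
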
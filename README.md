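# perchmon

Genetic-monitoring analytics for evaluating a two-source fish reintroduction
programme — hatchery stocking plus wild translocations — from reduced-
representation SNP genotypes.

## The problem

When a locally extinct river population is rebuilt from two differentiated
source populations (call them **D** and **Y**), managers need to know, for
every fish later captured during monitoring: was it **stocked** (hatchery
offspring of a known dam × sire broodstock pair), **translocated**
(wild-caught and moved), or **locally born** in the recipient river?  And do
the parental cross-types (DxD, DxY, YxY) differ in post-stocking survival,
growth, and local recruitment?

`perchmon` implements that full analysis as a tested, reusable pipeline:

- **SNP QC** — one SNP per sequencing tag, reproducibility = 1, loci missing
  in >10% of individuals and individuals missing >25% of genotypes removed,
  monomorphic and sex-linked loci dropped.
- **Identity analysis** — fuzzy matching (>99% of allele scores, ≤50
  mismatched loci) to collapse recaptures and detect translocated fish.
- **Parentage** — trio likelihoods with a per-genotype error model
  (e = 10⁻⁴): LOD = Σᵢ log P(gᵒᶠᶠᵢ | gᵈᵃᵐᵢ, gˢⁱʳᵉᵢ, e) − log P(gᵒᶠᶠᵢ | allele
  freqs), Monte-Carlo-calibrated assignment confidence (>95% accepted), and a
  Mendelian-exclusion screen.
- **Sibship** — pairwise full-sib vs unrelated likelihood ratios with
  single-linkage clustering (>98% group confidence).
- **Ancestry** — per-locus Weir–Cockerham F_ST between reference pools,
  supervised maximum-likelihood admixture q_D on the loci with F_ST ≥ 0.02
  (EM on P(allele) = q·p_D + (1−q)·p_Y), empirically calibrated category
  thresholds, and six hybrid-class posteriors (pure D/Y, F1, F2, two
  backcrosses).
- **Survival** — per-pair minimum-number-alive reconstruction over six age
  classes (captures carried back to earlier ages), fingerling output
  apportioned by each pair's larvae share, and a weighted binomial GLMM
  k_a ~ Binomial(N_f, logit⁻¹(Xβ + u_year)) fitted by Laplace maximum
  likelihood, with AIC model selection and the marginal pseudo-R²
  var(Xβ)/(var(Xβ) + σ²_year + π²/3).
- **Growth** — Gompertz length-at-age L(t) = L∞·exp(−exp(−k(t−t0))), its
  inverse for age-from-length, and Gaussian mixed models of growth
  residuals.
- **Synthetic data** — a generator (`perchmon.simdata`) that emulates the
  whole study design (Balding–Nichols source differentiation, multi-season
  breeding, stocking, translocations, cross-type-dependent survival,
  age-biased capture, local recruitment) and carries a truth ledger, so
  every stage is validated against known answers.

## Worked example

```python
from perchmon import simulate_dataset
from perchmon.pipeline import run_pipeline

dataset = simulate_dataset()          # the default reference design
result = run_pipeline(dataset, seed=7)

print(result.summary.origin_percentages().to_dict())
print(result.survival_best.formula)
print(result.survival_best.coefficients[["term", "estimate", "se", "p"]])
```

Output from the run above:

```
{'locally_born': 62.2, 'stocked': 37.8}
age_class + cross_type + (1|stock_year)
         term  estimate        se              p
0   Intercept -8.278028  0.224603  2.318358e-297
1   age_class -0.343388  0.057079   1.787246e-09
2  cross[DxY]  0.680160  0.281320   1.561715e-02
3  cross[YxY]  2.095457  0.165609   1.076333e-36
```

Reading it: of the ~270 unique fish "captured" during synthetic monitoring,
about 38% were assigned broodstock parents (stocked) and the rest inferred
locally born.  Model selection kept parental cross-type, and the planted
survival advantage is recovered with the right ordering — YxY offspring
survive best, then DxY, with DxD as the reference level.

The same stages are scriptable from a shell:

```bash
perchmon simulate --out-dir data/
perchmon report --data-dir data/ --out-dir results/
```

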
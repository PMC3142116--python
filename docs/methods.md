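# Methods

Statistical definitions, numerical choices, and simulator details for
`famjoint`. Notation: families `i = 1..F`, each with father, mother, and
`m_i ≥ 1` children; genotype scores count copies of a designated allele
(`0/1/2`, `nan` missing); traits `y` are quantitative.

## 1. Between-family screening tests

Let `b_i = (x_fa,i + x_mo,i)/2` be family `i`'s **parental-mean** genotype
score at a marker, and let `Ỹ_i = Σ_k y_ik − n_i · ȳ` be the family's trait
sum centered at the overall mean `ȳ` (all members, parents included,
`n_i = 2 + m_i`). The screening statistic is the self-normalized sum

```
U_i = Ỹ_i · (b_i − b̄),      z = Σ U_i / sqrt(Σ U_i²)
```

with `b̄` the mean of the per-family parental-mean scores over the families
included at that marker. Families are independent sampling units, so `z` is
asymptotically N(0, 1) whenever `E[U_i] = 0` — true in a homogeneous
population (the **unadjusted screen**, `b_screen`) and, after adjustment,
in structured ones (the **admixture screen**, `a_screen`, which evaluates
the same form on residualized traits and genotype scores).

The parental-mean summary (rather than a family mean including children) is
what makes the screening statistic a function of founders and traits only,
hence independent of the transmission-based stage-2 statistic conditional
on the founders. This independence is a load-bearing property (it licenses
the joint combination) and is verified empirically by the acceptance suite.

Markers with founder minor-allele frequency below 0.01 are flagged and
excluded; families missing a parental genotype at a marker are dropped at
that marker, with both means recomputed over the included families.

## 2. Admixture adjustment (parental PCA)

1. Sample `l` genomic markers uniformly without replacement (default 800).
2. Fit PCA on the **parents only** at those markers (children of the same
   parents are correlated and would bias the directions): mean-impute
   missing values, center by parental means, take the top `K`
   eigenvectors of the parental covariance (default `K = 10`). Large
   problems use Lanczos (`scipy.sparse.linalg.eigsh` with a fixed start
   vector for determinism); small ones an exact economy SVD. Requesting
   more components than the covariance rank is an error.
3. Project **every member** — parents and children — with the parental
   means and eigenvectors.
4. Regress trait and candidate genotypes on the `K` PC scores with an
   intercept, coefficients estimated **from the parents only**; each
   member's residual subtracts the fit at its own PC scores.

`K = 0` is the degenerate no-PC path (intercept-only residualization), in
which the admixture screen reduces exactly to the unadjusted screen.

## 3. Within-family association test (QPTD)

For each child, the transmission deviation is `x_child − (x_fa + x_mo)/2`.
With child trait deviations `y_ij − ȳ_c` (centered at the mean over
included children),

```
num = Σ_i Σ_j (y_ij − ȳ_c)(x_ij − midparent_i)
var = Σ_i Σ_j (y_ij − ȳ_c)² · (1[fa het] + 1[mo het]) / 4
z   = num / sqrt(var)
```

Conditional on parental genotypes and all traits, the transmissions are the
only randomness under the null: each heterozygous parent contributes
variance 1/4 to the child's deviation and homozygous parents transmit
deterministically, so `var` is the **exact conditional variance** of `num`
and `z` is N(0, 1) regardless of population structure. (An earlier
self-normalized variant — sum of squared per-family contributions — showed
t-like tail inflation in calibration runs and was replaced by this exact
form; the calibration tests define the acceptance surface for the
estimator.) Families with any missing trio genotype at a marker are
dropped there; markers with zero informative (heterozygous-parent)
families are flagged.

## 4. Stage-1 selection, the joint statistic, conditional p-value

Stage 1 keeps the `R` markers (default 10) with the smallest screening
p-values; ties break by marker index. The realized threshold is
`C = |z_screen|` of the R-th selected marker. Stage 2 declares significance
at Bonferroni `α / R`.

The joint statistic combines the two independent N(0, 1) components:

```
z_joint = w·z_screen + sqrt(1 − w²)·z_assoc,       default w = 1/√2
```

Unconditionally `z_joint` is N(0, 1), but selected markers satisfy
`|Z_screen| ≥ C`, so the p-value must condition on selection:

```
p = P(|w·Z_s + s·Z_a| ≥ |z_obs|  |  |Z_s| ≥ C),    s = sqrt(1 − w²)
  = ∫_C^{C+10} [ Φ̄((t − wx)/s) + Φ((−t − wx)/s) ] φ(x) dx / Φ(−C)
```

computed by adaptive quadrature (absolute tolerance 1e-10) with the
negative tail folded by symmetry; mass beyond `C + 10` is below
double-precision relevance. `C = 0` reduces to the unconditional two-sided
p-value; `z_obs = 0` gives 1. The quadrature is validated against a
10⁷-draw truncated-normal Monte-Carlo oracle in the acceptance suite.

## 5. Simulator

Three population models, all built from synthetic haplotype panels of 120
chromosomes per source population on a uniform genetic map (default 2,000
markers over 2.8 Morgans):

* **homogeneous** — one panel, per-site frequency ~ Uniform(0.05, 0.5),
  sites independent by default (an optional block-LD mode shares draws
  within geometric-length blocks).
* **structured** — two panels diverged under the Balding–Nichols model:
  ancestral frequency `p0 ~ Uniform(maf_range)`, population frequency
  `~ Beta(p0(1−Fst)/Fst, (1−p0)(1−Fst)/Fst)` at `Fst = 0.15`; each family
  is drawn wholly from one subpopulation (70%/30%).
* **admixed** — two ancestral panels combined along ancestry tracks laid
  down by the same crossover process with segment origins drawn (0.8, 0.2);
  each member's ancestry proportion (genome fraction from population 1) is
  recorded — parents as the mean of their two haplotypes, children at the
  midparent expectation.

Parental haplotypes are mosaics of panel haplotypes with crossover counts
`Poisson(6 × map length in Morgans)` and uniform breakpoints; children
receive one recombined gamete per parent (Mendelian consistency holds by
construction and is asserted in tests).

**Traits.** Null: parents iid N(0, 1); children from the conditional MVN
implied by unit variances, parent–child and sib–sib correlation `ρ = 0.4`
(child mean `ρ(y_fa + y_mo)`, covariance `(1−ρ)I + (ρ−2ρ²)J`; infeasible
`(ρ, m)` combinations error). Alternative adds `β·X(genotype)` at a disease
locus drawn with population-1 MAF in (0.1, 0.3), where `X` is the
dominant/recessive/additive coding of the risk-allele count (risk allele =
minor for dominant/additive, major for recessive), plus a structure shift:
`μ` added to subpopulation 2 (structured) or `μ ×` ancestry proportion
(admixed). `β = sqrt(h / ((1−h)·Var(X)))` with HWE `Var(X)`, calibrated
per subpopulation from its own risk-allele frequency, so the locus explains
heritability `h` of the unit background variance; the mapping is verified
by a simulation oracle rather than trusted.

**Reproducibility.** One master seed; per-replicate streams derived via
`numpy.random.SeedSequence.spawn`, so experiments are deterministic and
individual replicates independently reproducible. Identical config + seed
⇒ bit-identical cohort.

## 6. What the simulator emulates — and does not

Emulated: frequency divergence between source populations (Balding–Nichols
at Fst 0.15, roughly the CEU–YRI range), family structure, recombination
at 6 crossovers/Morgan, admixture tracks, the `ρ = 0.4` trait correlation,
and heritability-calibrated effect sizes.

Not emulated: real HapMap haplotypes and their LD structure, coalescent
genealogies, phenotype-based ascertainment, genotyping error. Published
full-scale inflation magnitudes for the unadjusted screen depend on the
specific source panels' divergence, so desk-scale runs reproduce the
*pattern* (gross inflation vs nominal calibration), not exact table cells.
One knock-on effect of the default LD-free panel: with independent markers
the family-wise type-I of the two-stage pipelines sits near the theoretical
`1 − (1 − α/R)^R ≈ 4.9%`, whereas large tag-SNP panels with LD (where
selected markers cluster) run slightly more conservative (~3–4%).

## 7. Experiment definitions and problem sizes

* **Type-I (pipelines)** — family-wise: fraction of null replicates in
  which at least one of the `R` selected markers is declared significant at
  `α/R`.
* **Type-I (screens)** — marker-wise: fraction of all unflagged marker
  tests with `p < α`, pooled over replicates.
* **Power** — fraction of replicates in which the disease locus is both
  selected in stage 1 and significant in stage 2; methods evaluated on
  shared replicates so comparisons are paired.

Problem sizes in the acceptance suite are this package's own desk-scale
choices, fixed before any calibration run: 500 replicates × 600 trios ×
2,000 markers (homogeneous calibration); 200 × 400 trios (structured
screens); 2,000 × 200 trios on a 200-marker panel with `l = 150`
(independence diagnostic); 300 paired replicates × 600 trios (power
ordering). Full-scale published experiments use 1,000 replicates and
larger panels; the Monte-Carlo bands in the tests account for the reduced
sizes.

## 8. Known limitations

* Asymptotic normal calibration of the self-normalized screen and the
  bounded-summand QPTD is approximate in extreme tails at small family
  counts; calibration tests pin behavior at the 5% level and moderate tails.
* The PED reader supports biallelic A/C/G/T markers, two-parent nuclear
  families, and complete phenotype records; it recodes genotypes to the
  founder minor allele (so round trips are exact only after
  `recode_to_founder_minor`).
* PCA adjustment assumes structure is low-rank and visible in `l` genomic
  markers; `K` and `l` trade off adjustment quality against noise, with
  defaults (10, 800) matching the standard two-subpopulation setting.
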
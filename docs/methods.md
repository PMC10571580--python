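# Methods

## Models

### Animal models with maternal effects

For records sorted by individual (and trait within individual in the
bivariate case), the most general structure fitted is

    y = X b + Zd a_d + Zm a_m + Wc c + Wme me + e

where `b` are fixed effects (by default: month of slaughter, sex, parity
order as first vs later, measurement method), `a_d` and `a_m` are direct and
maternal breeding values indexed by *pedigree animal* (Zm maps each record
to its dam's maternal column), `c` is a common-litter effect (litter = dam x
parity), `me` a permanent maternal-environment effect (one level per dam)
and `e` the residual.  Five standard structures are exposed as models 1–5
(direct; +maternal; direct+litter; direct+maternal+litter;
direct+maternal+maternal-environment), plus a diagnostic model 0
(intercept + residual only) used to check the sampler against a closed-form
posterior.  Distributions:

    (a_d, a_m) ~ N(0, A ⊗ G0)    c ~ N(0, I ⊗ Cc)
    me ~ N(0, I ⊗ Cme)           e ~ N(0, I ⊗ R0)

`A` is the additive relationship matrix of the full pedigree; `G0` is 2t x 2t
for t traits with (direct, maternal) blocks per trait.  With one litter per
dam the litter and maternal-environment terms coincide; models 4 and 5 then
differ only in bookkeeping, which is why the simulator's default design uses
two parities per dam (see below).

### Sampling scheme

All location parameters are updated single-site (Gauss–Seidel) from their
normal full conditionals, maintaining the residual vector in place; the
genetic updates use the sparse rows of `A⁻¹` and the current `G0⁻¹`, so one
full sweep costs O(records + nnz(A⁻¹) x genetic columns).  The first level
of every fixed factor is constrained to zero and an explicit intercept
column absorbs the mean.

Fixed effects and all covariance blocks carry **flat priors**.  The full
conditional of a p x p covariance block with q levels and effect
cross-product S (for the genetic block, `U'A⁻¹U`) is then inverse-Wishart
with df = q − p − 1, i.e. density ∝ |X|^(−q/2) exp(−tr(S X⁻¹)/2); residual
blocks use q = number of records.  The df convention matters: the
superficially similar choice df = q corresponds to a ∝ 1/σ² prior, and with
one record per animal that prior makes the joint posterior *improper* — the
chain is absorbed at σ²_e → 0 with breeding values interpolating the data
(we verified this empirically from over-dispersed starts).  Under the flat
prior the sampler's marginal posterior matches (to three decimals) a
brute-force grid integration of the exact marginal likelihood on a small
pedigree, and the residual-only model matches its conjugate closed form
σ² | y ~ S/χ²_{n−3} (Kolmogorov–Smirnov check in the test suite).  Draws use
a Bartlett-decomposition inverse-Wishart sampler (scipy's has too much
per-call overhead for 10⁴–10⁵ iteration chains; it is cross-checked against
scipy in the tests).  When a term has so few levels that q − p − 1 ≤ p the
df is clamped to p to keep the draw proper; covariance draws are floored by
1e-12·I so degenerate (zero-variance) data cannot make a conditional
singular.

Chains default to 300,000 iterations, 20,000 burn-in, thinning 200
(1,400 retained draws), the scale of a production run; all validation
experiments in this repository use 20,000–22,000-iteration chains with
burn-in 2,000 and thinning 10, which keeps a full recovery experiment under
half a minute while leaving ~2,000 retained draws.

### Derived parameters

Per retained draw, ratios are taken to the phenotypic variance

    σ²_P = σ²_d + σ²_m + σ_dm + σ²_c + σ²_me + σ²_e

(terms absent from the model contribute zero).  The direct–maternal
covariance enters **once**: each record's maternal effect is carried by its
dam, whose additive relationship to the record is 1/2, so Var(y) contains
2·(1/2)·σ_dm.  This convention also keeps strongly maternal traits
internally consistent — with h²d = 0.45, h²m = 0.46, C² = 0.15 the ratios
exceed 1 under a covariance-free denominator, but fit in exactly when
ρ_dm = −0.39 is included.  Posterior summaries: mean, median, SD; HPD95% as
the shortest interval containing ⌈0.95·N⌉ sorted draws (Chen–Shao),
validated against exhaustive window search; the mode is the midpoint of the
fullest of 50 equal-width histogram bins (presentation only).

### Maternal GWAS (BayesB)

Each offspring record carries its dam's centered additive genotype codes.
Per sweep and locus, δ_j is drawn from its posterior odds with α_j
integrated out given the current per-locus variance σ²_j; α_j | δ_j = 1 from
its normal conditional; σ²_j from a scaled inverse-χ² with df ν + δ_j and
scale (ν σ²_α + δ_j α²_j)/(ν + δ_j), which induces the t_ν(0, σ²_α) effect
prior.  Defaults: ν = 4; π = 1 − n/(3k) rounded to 4 decimals (0.9987 at the
reference scale of n = 349 records and k = 88,512 SNPs);
σ²_α = V_g / ((1 − π) Σ_j 2p_j(1 − p_j)) from a user-supplied trait genetic
variance.  Constant SNP columns are skipped with a warning (their δ is drawn
from the prior, so their inclusion probability is reported at 1 − π).
The sweep works at the dam level (unique dam covariates with per-record
weights), so one iteration costs O(k x dams), not O(k x records).

Bayes factors are posterior odds of inclusion over prior odds.  Window
shares are, per retained draw, Var(window-restricted genomic value) /
Var(total genomic value) across individuals (record-weighted across dams);
the reported percentage is the posterior mean x 100.  Calling uses the
two-tier rule (≥1% primary / ≥0.5% secondary, both requiring a SNP with
BF strictly above 10); SNP counts at BF ≥ 10 are also reported since
summary tables conventionally use the non-strict count.  The 1% and 0.5%
thresholds are 20x and 10x the expected per-window share 100/1973 at the
reference window count.

The printed genotype coding in the source material (0 = heterozygote) is
treated as an erratum; standard additive coding (count of reference allele)
is used, and covariates are column-centered.

## Synthetic data

The generator reproduces the statistical design the estimators assume, not
rabbit biology: a base population of unrelated founders (13 sires, 83 dams),
two lines bred in parallel (8 sires x 40 dams per line per generation by
default, each sire mated with five dams), litters nested in dam x parity,
phenotypes

    y = mean + fixed + a_d(i) + a_m(dam) + c(litter) [+ me(dam)] + e

and optional divergent selection: dams ranked by the mean phenotype of two
scored first-parity full sibs (one male, one female), top 20% retained in
the high line, bottom 20% in the low line, one male per sire from his
best-ranked mating.  Breeding values descend by parent average plus a
Mendelian-sampling deviation with covariance (1/2 − (F_s + F_d)/4)·G0, which
makes the joint covariance exactly A ⊗ G0 (verified by Monte-Carlo moments
against A entries).  Inbreeding is computed by memoized kinship recursion;
the dense tabular A is an independent implementation, so diag(A) − 1 ≡ F is
a genuine cross-check.

Default generating values are the Model-4 decomposition of IMF on a unit
phenotypic-variance scale (σ²_d 0.45, σ²_m 0.09, ρ_dm −0.02, σ²_c 0.14,
residual ≈ 0.32, trait mean 1.08 g/100 g); fixed-effect defaults are small
constants over month (51 levels, per litter), sex, parity and measurement
method, assigned by a shuffled round-robin so every level is observed.
Litter size and parity count are not pinned down by the design this
emulates; the defaults are Poisson(8) truncated at 1, and two parities per
dam.

Genotypes are gene-dropped through the pedigree in linkage equilibrium
(founder alleles Bernoulli(p_j), p_j uniform over the MAF range; one allele
from each parent per locus), which keeps window-variance expectations
analytic (uniform 100/n_windows under the null).  LD, realistic
recombination maps and genotyping error are *not* emulated — power and
calibration results on these data bound what the method does with clean,
independent markers, not with real array LD structure.  A planted dam QTL
adds α x dam-genotype-code to the offspring phenotype and is recorded in the
truth table.

## Validation experiment sizes

* **Model-4 recovery**: two offspring generations, 2 lines x (10 sires x 30
  dams, three dams per sire), two parities, Poisson(8) litters → ~1,900
  phenotyped animals.  The ratio of three dams per sire (rather than the
  husbandry default of five) and two parities are deliberate: sire families
  drive the separation of σ²_d from σ²_e, and repeated litters per dam
  separate σ²_m from σ²_c.  At this information level the h²d posterior is
  intrinsically wide (HPD95 width ≈ 0.4), so the reference script averages
  the posterior mean over a few replicate simulations to report a stable
  recovery value.
* **Misspecification**: one generation (~960 records) generated under
  model 4 and refitted with model 1; ignoring maternal and litter structure
  reliably inflates the direct heritability far above the generating 0.45.
* **Maternal-GWAS power/null**: 100 genotyped founder dams x 5 offspring,
  2,000 SNPs on 21 chromosomes of 5 Mb (105 windows, ~19 SNPs each), one
  planted QTL at ~20% of phenotypic variance (hence ~all genomic variance),
  chain 50k/10k/10.  The null replicates are identical minus the QTL.

## Known limitations

* Single-site Gibbs mixes slowly on the σ²_d–σ²_e ridge typical of
  one-record-per-animal designs; production-length chains (the 300k default)
  are advisable for real analyses.
* Records missing one trait in bivariate runs are dropped (complete case).
* The naive expected-genotype imputation is a labelled stand-in where
  haplotype-based imputation would be used on real array data.
* Maternal GWAS is single-trait; the bivariate structure applies only to the
  animal models.
* With very few levels for a random term the flat-prior posterior is
  improper; the clamped df keeps the sampler defined but such fits should
  not be interpreted.
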
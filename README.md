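# matqg — maternal-effect animal models and maternal GWAS

`matqg` is a quantitative-genetics toolkit for asking how much of an
offspring trait — intramuscular fat (IMF, g/100 g muscle) and intramuscular
fatty-acid percentages in meat rabbits are the motivating case — is shaped by
the *dam's* genotype rather than the animal's own.  It provides, as one
tested stack:

* **Pedigree machinery** — validation, inbreeding coefficients, the additive
  relationship matrix **A** (tabular method) and its sparse inverse
  (Henderson's rules with inbreeding).
* **Bayesian animal models 1–5** fitted by Gibbs sampling, univariate or
  bivariate: direct additive genetic effects (`a_d`), maternal genetic
  effects (`a_m`, carried by the dam), common-litter effects (`c`, dam x
  parity), maternal-environment effects (`me`) and residuals, with
  `(a_d, a_m) ~ N(0, A ⊗ G0)` and flat priors on fixed effects and all
  covariance blocks.  Output: retained MCMC samples plus posterior mean /
  median / mode / SD / HPD95% for the variance ratios h²d, h²m, C², Me² and
  the genetic correlations ρ_dm, ρ_d, ρ_m.
* **A maternal GWAS (BayesB)** — each offspring's phenotype is regressed on
  its dam's SNP genotypes, `y = 1μ + Xb + Σ_j z_j α_j δ_j + e`, with a
  mixture prior (`δ_j = 0` with probability π = 1 − n/3k) and t-distributed
  effects.  Inference uses per-SNP Bayes factors and the posterior share of
  genomic variance per 1-Mb window; a window is associated when it explains
  ≥1% (primary) or ≥0.5% (secondary) of the genomic variance and holds a
  SNP with BF > 10.
* **Genotype QC** (MAF < 0.05, marker missingness > 5%, individual
  missingness > 3%, sex chromosomes), naive expected-genotype imputation,
  1-Mb window construction, and **reporting** (Manhattan tables, merged
  associated regions, GFF3 gene annotation).
* **A generational simulator** that reproduces the divergent-selection
  design the estimators assume (base population of 13 sires / 83 dams, two
  lines, five dams per sire, top-20% dam selection on two scored offspring,
  full-sib litters, gene-dropped SNPs), with every generating value recorded
  in truth tables — so every stage is testable against known truth.

## Worked example

Simulate a Model-4 world at roughly study scale (two offspring generations,
~1,900 phenotyped rabbits, unit phenotypic variance, generating ratios
h²d = 0.45, h²m = 0.09, C² = 0.14) and refit Model 4:

```python
from matqg.experiments import imf_model4_config, recovery_posterior_means

out = recovery_posterior_means(imf_model4_config(seed=1), seed=1,
                               iterations=22_000, burn_in=2_000, thin=10)
print(out["n_records"], out["h2d"], out["h2m"], out["c2"])
```

prints (seed 1):

```
1899 0.3685 0.068 0.1683
```

i.e. from ~1,900 records the chain recovers the generating direct
heritability (0.45), maternal heritability (0.09) and litter-effect ratio
(0.14) to within ±0.10 — about the intrinsic posterior spread at this
design size — and the HPD95% intervals (via `out["result"].summaries()`)
cover all three generating values.

The same models are available from a shell:

```bash
matqg simulate --config sim.yaml --seed 1 --out-dir data/
matqg fit --model 4 --traits IMF --pedigree data/pedigree.csv \
          --phenos data/phenotypes.tsv --iters 300000 --burnin 20000 \
          --thin 200 --seed 1 --out-dir fit/
matqg mgwa --phenos data/phenotypes.tsv --genos data/genotypes \
           --trait IMF --genetic-variance 0.3 --out-dir gwas/
```

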
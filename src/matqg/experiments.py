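"""Reference experiment configurations for recovery and power studies.

These bundle the generating values and breeding designs used by the
package's validation experiments so that scripts and tests run the same
conditions:

* Model-4 recovery experiments generate ~1,900 phenotyped animals over two
  offspring generations (two lines, 10 sires x 30 dams per line, three dams
  per sire, two parities, Poisson(8) litters) on a unit phenotypic-variance
  scale.  The mating ratio and parity count were chosen so that direct,
  maternal and litter components are all identifiable at this scale: sire
  families separate the direct variance, repeated litters per dam separate
  the maternal genetic from the common litter variance.
* Generating variance ratios are the Model-4 posterior means for
  intramuscular fat (h2d 0.45, h2m 0.09, rho_dm -0.02, C2 0.14) and for
  palmitoleic acid C16:1n7 (h2d 0.45, h2m 0.46, rho_dm -0.39, C2 0.15); the
  residual completes the unit total, which includes the direct-maternal
  covariance once.
* The maternal-QTL power experiment plants a single dam QTL explaining
  ~20% of the offspring phenotypic variance among 2,000 linkage-equilibrium
  SNPs on 21 chromosomes (5 Mb each -> 105 one-Mb windows), with 500
  offspring from 100 genotyped dams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .animal_models import ModelSpec, run_gibbs
from .geno_qc import build_windows
from .mgwa import (
    MGWAConfig,
    assign_dam_genotypes,
    call_associated_windows,
    run_bayesb,
    window_variance,
)
from .simulate import (
    FixedEffectSpec,
    LitterSizeSpec,
    SimulationConfig,
    inject_dam_qtl,
    simulate_dataset,
    simulate_genotypes,
)


def _model4_config(seed, s2d, s2m, rho_dm, c2, trait, trait_mean):
    sdm = rho_dm * np.sqrt(s2d * s2m)
    s2e = 1.0 - (s2d + s2m + sdm + c2)
    if s2e <= 0:
        raise ValueError("variance budget exceeds the unit total")
    return SimulationConfig(
        n_generations=2,
        base_sires=13,
        base_dams=83,
        n_lines=2,
        sires_per_gen=10,
        dams_per_gen=30,
        dams_per_sire=3,
        n_parities=2,
        traits=(trait,),
        trait_means=[trait_mean],
        G0_true=[[s2d, sdm], [sdm, s2m]],
        c2=c2,
        me2=0.0,
        R0_true=s2e,
        seed=seed,
    )


def imf_model4_config(seed: int = 0) -> SimulationConfig:
    """Generating values: the Model-4 decomposition of intramuscular fat."""
    return _model4_config(seed, 0.45, 0.09, -0.02, 0.14, "IMF", 1.08)


def palmitoleic_model4_config(seed: int = 0) -> SimulationConfig:
    """Generating values: the Model-4 decomposition of palmitoleic acid
    (strong maternal component, clearly negative direct-maternal
    correlation)."""
    return _model4_config(seed, 0.45, 0.46, -0.39, 0.15, "C16:1n7", 1.40)


def fit_model4(
    dataset,
    seed: int = 0,
    iterations: int = 22_000,
    burn_in: int = 2_000,
    thin: int = 10,
    model_id: int = 4,
):
    """Fit the given animal model to a simulated dataset (short chain)."""
    return run_gibbs(
        dataset.phenotypes,
        dataset.pedigree,
        ModelSpec(model_id=model_id),
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        seed=seed + 101,
    )


def recovery_posterior_means(config, seed: int, **fit_kw) -> dict:
    """Simulate under Model 4 and return posterior means of the ratios."""
    ds = simulate_dataset(config)
    res = fit_model4(ds, seed=seed, **fit_kw)
    trait = config.traits[0]
    s = res.samples
    return {
        "h2d": float(s[f"h2d.{trait}"].mean()),
        "h2m": float(s[f"h2m.{trait}"].mean()),
        "c2": float(s[f"c2.{trait}"].mean()),
        "n_records": ds.phenotypes.n,
        "result": res,
        "dataset": ds,
    }


# ----------------------------------------------------------- maternal QTL


@dataclass
class PowerRun:
    called_primary: bool
    qtl_p_hat: float
    qtl_window_pct: float
    n_false_windows: int
    n_windows: int
    calls: object


def maternal_qtl_dataset(
    seed: int,
    n_dams: int = 100,
    offspring_per_dam: int = 5,
    n_snps: int = 2_000,
    n_chrom: int = 21,
    chrom_length_bp: int = 5_000_000,
    qtl_variance: float = 0.2,
    residual_variance: float = 0.8,
):
    """One-generation maternal-QTL dataset: 100 genotyped founder dams, 500
    phenotyped offspring, linkage-equilibrium SNPs, one planted dam QTL
    (or none when ``qtl_variance`` is 0)."""
    n_sires = max(2, n_dams // 5)
    cfg = SimulationConfig(
        n_generations=1,
        base_sires=n_sires,
        base_dams=n_dams,
        n_lines=1,
        sires_per_gen=n_sires,
        dams_per_gen=n_dams,
        dams_per_sire=5,
        n_parities=1,
        litter_size=LitterSizeSpec(offspring_per_dam, offspring_per_dam, fixed=True),
        G0_true=np.zeros((2, 2)),
        c2=1e-9,
        me2=0.0,
        R0_true=residual_variance,
        fixed_effects=[
            FixedEffectSpec("sex", 2, np.array([0.0, 0.1])),
            FixedEffectSpec("parity", 2, np.array([0.0, 0.1])),
            FixedEffectSpec("month", 5, per="litter"),
        ],
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    gm, mm = simulate_genotypes(
        ds.pedigree, n_snps, n_chrom, maf_range=(0.1, 0.5), seed=seed + 7,
        chrom_length_bp=chrom_length_bp,
    )
    ds.genotypes, ds.marker_map = gm, mm
    windows = build_windows(mm)
    qtl_marker = None
    if qtl_variance > 0:
        rng = np.random.default_rng(seed + 13)
        win = windows[int(rng.integers(len(windows)))]
        probe = inject_dam_qtl(ds, (win.chrom, win.mb_index), 1.0, 1)
        qtl_marker = probe.truth.qtl["marker"].iloc[0]
        col = gm.markers.index(qtl_marker)
        rows = {a: i for i, a in enumerate(gm.individuals)}
        z = np.array(
            [gm.codes[rows[d], col] for d in ds.phenotypes.data["dam"]], dtype=float
        )
        alpha = np.sqrt(qtl_variance / z.var())
        ds = inject_dam_qtl(ds, (win.chrom, win.mb_index), alpha, 1)
    return ds, windows, qtl_marker


def mgwa_power_run(
    seed: int,
    qtl_variance: float = 0.2,
    iterations: int = 50_000,
    burn_in: int = 10_000,
    thin: int = 10,
) -> PowerRun:
    """Run the full maternal-GWAS pipeline on one planted-QTL (or null)
    replicate and report the window calls."""
    ds, windows, qtl_marker = maternal_qtl_dataset(seed, qtl_variance=qtl_variance)
    data = assign_dam_genotypes(
        ds.phenotypes, ds.genotypes, "IMF", fixed=("sex", "parity", "month")
    )
    cfg = MGWAConfig(
        iterations=iterations, burn_in=burn_in, thin=thin, seed=seed + 23,
        genetic_variance=max(qtl_variance, 0.2),
    )
    res = run_bayesb(data, ds.genotypes, cfg)
    snp = res.snp_table(ds.marker_map)
    wv = window_variance(res, windows)
    calls = call_associated_windows(wv, snp, windows)
    if qtl_marker is None:
        return PowerRun(
            called_primary=False,
            qtl_p_hat=np.nan,
            qtl_window_pct=np.nan,
            n_false_windows=int((calls["tier"] == "primary").sum()),
            n_windows=len(windows),
            calls=calls,
        )
    pos = ds.truth.qtl["pos"].iloc[0]
    chrom = str(ds.truth.qtl["chrom"].iloc[0])
    mb = (pos - 1) // 1_000_000
    row = calls[(calls["chrom"] == chrom) & (calls["mb_index"] == mb)].iloc[0]
    col = ds.genotypes.markers.index(qtl_marker)
    return PowerRun(
        called_primary=row["tier"] == "primary",
        qtl_p_hat=float(res.inclusion_prob[col]),
        qtl_window_pct=float(row["pct_var"]),
        n_false_windows=int(
            ((calls["tier"] == "primary") & ~((calls["chrom"] == chrom) & (calls["mb_index"] == mb))).sum()
        ),
        n_windows=len(windows),
        calls=calls,
    )
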
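"""Maternal genome-wide association by BayesB marker regression.

The dam's genotype is assigned to each of her offspring's phenotypes and the
model ``y = 1 mu + X b + sum_j z_j alpha_j delta_j + e`` is sampled by MCMC:
``delta_j`` is 1 with prior probability ``1 - pi`` and the allele
substitution effect ``alpha_j`` carries a t_nu(0, sigma2_alpha) prior,
implemented as a normal with a per-locus scaled inverse-chi-square variance.
``pi`` defaults to ``1 - n/(3k)`` (records over three times the marker
count).  Inference is per-SNP Bayes factors (posterior odds of inclusion
over prior odds) and the posterior mean percentage of genomic variance
explained by each 1-Mb window; a window is called associated when it
explains at least 1% (primary) or 0.5% (secondary) of the genomic variance
and contains at least one SNP with BF above 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .animal_models import n_retained
from .geno_qc import MISSING, GenotypeMatrix, Window
from .simulate import PhenotypeTable


class MGWAError(ValueError):
    pass


def compute_pi(n_records: int, n_snps: int) -> float:
    """Prior exclusion probability ``pi = 1 - n/(3k)``, rounded to 4 decimals.

    Raises when the record count is too large relative to the marker count
    for the mixture prior to make sense (pi must land in (0, 1))."""
    if n_records < 1 or n_snps < 1:
        raise MGWAError("need n_records >= 1 and n_snps >= 1")
    pi = 1.0 - n_records / (3.0 * n_snps)
    if not (0.0 < pi < 1.0):
        raise MGWAError(
            f"pi = {pi:.4f} outside (0, 1); too few SNPs for {n_records} records"
        )
    return round(pi, 4)


def derive_effect_variance(
    genetic_variance: float, pi: float, allele_freqs: np.ndarray
) -> float:
    """Per-locus effect-variance scale ``sigma2_alpha``.

    Standard BayesB partition of the trait's genetic variance over the
    markers expected in the model:
    ``sigma2_alpha = V_g / ((1 - pi) * sum_j 2 p_j (1 - p_j))``.
    """
    p = np.asarray(allele_freqs, dtype=float)
    het = float(np.sum(2.0 * p * (1.0 - p)))
    if het <= 0:
        raise MGWAError("all allele frequencies fixed (0/1); cannot scale effects")
    return float(genetic_variance) / ((1.0 - pi) * het)


def compute_bayes_factor(p_hat, pi: float):
    """Bayes factor of inclusion: posterior odds over prior odds.

    ``BF = [p/(1-p)] / [(1-pi)/pi]``; a posterior probability of 1 returns
    +inf.  Vectorised over ``p_hat``.
    """
    p = np.asarray(p_hat, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise MGWAError("posterior inclusion probabilities must be in [0, 1]")
    prior_odds = (1.0 - pi) / pi
    with np.errstate(divide="ignore"):
        bf = np.where(p < 1.0, p / (1.0 - p) / prior_odds, np.inf)
    if np.isscalar(p_hat):
        return float(bf)
    return bf


@dataclass
class MGWAConfig:
    """Chain settings and prior scales for one BayesB run."""

    pi: float | str = "auto"
    nu: float = 4.0
    sigma2_alpha: float | None = None
    genetic_variance: float | None = None
    iterations: int = 500_000
    burn_in: int = 100_000
    thin: int = 10
    seed: int = 0
    store_samples: bool = True

    def __post_init__(self):
        if self.nu <= 2:
            raise MGWAError("nu must exceed 2 for a finite prior variance")
        if self.burn_in >= self.iterations:
            raise MGWAError("burn_in must be smaller than iterations")
        if self.pi != "auto" and not (0.0 < float(self.pi) < 1.0):
            raise MGWAError("pi must lie in (0, 1)")


@dataclass
class DamAssignedData:
    """Offspring phenotypes carrying their dam's genotype row.

    ``dam_row[r]`` indexes the genotype matrix for record ``r``; dams repeat
    across their offspring.
    """

    y: np.ndarray  # (n_rec,)
    dam_row: np.ndarray  # (n_rec,) into the genotype matrix
    factor_codes: np.ndarray  # (n_rec, nf) incl. intercept column 0
    factor_n_levels: list
    factor_names: list
    offspring_ids: list
    trait: str

    @property
    def n_records(self) -> int:
        return len(self.y)


def assign_dam_genotypes(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    trait: str,
    fixed: tuple = ("sex", "parity"),
) -> DamAssignedData:
    """Build the record table for one trait: each offspring's phenotype is
    paired with its dam's genotype-matrix row.  Raises when a dam is not
    genotyped; records with a missing trait value are dropped."""
    df = phenotypes.data
    keep = ~df[trait].isna()
    df = df.loc[keep].reset_index(drop=True)
    row_of = {a: i for i, a in enumerate(genotypes.individuals)}
    missing = sorted(set(df["dam"]) - set(row_of))
    if missing:
        raise MGWAError(f"dams not genotyped: {missing[:5]}")
    dam_row = df["dam"].map(row_of).to_numpy(dtype=np.int64)
    names = ["(intercept)"]
    codes = [np.zeros(len(df), dtype=np.int64)]
    n_levels = [1]
    for f in fixed:
        if f not in df.columns:
            raise MGWAError(f"fixed factor {f!r} not in phenotype table")
        vals, uniq = pd.factorize(df[f], sort=True)
        names.append(f)
        codes.append(vals.astype(np.int64))
        n_levels.append(len(uniq))
    return DamAssignedData(
        y=df[trait].to_numpy(dtype=float),
        dam_row=dam_row,
        factor_codes=np.column_stack(codes),
        factor_n_levels=n_levels,
        factor_names=names,
        offspring_ids=list(df["animal"]),
        trait=trait,
    )


@dataclass
class BayesBResult:
    """Chain output: per-SNP posteriors plus retained effect samples."""

    inclusion_prob: np.ndarray  # (k,) posterior P(delta_j = 1)
    effect_mean: np.ndarray  # (k,) posterior mean of alpha_j * delta_j
    alpha_samples: np.ndarray | None  # (n_ret, k) float32, alpha*delta
    sigma2_e: np.ndarray  # (n_ret,)
    mu: np.ndarray  # (n_ret,)
    pi: float
    sigma2_alpha: float
    markers: list
    skipped: np.ndarray  # (k,) bool, constant columns
    settings: dict
    # dam-level covariates needed for window variance
    Z_dam: np.ndarray = field(repr=False, default=None)  # (k, n_dams) centered
    dam_weights: np.ndarray = field(repr=False, default=None)  # records per dam

    def bayes_factors(self) -> np.ndarray:
        return compute_bayes_factor(self.inclusion_prob, self.pi)

    def snp_table(self, marker_map=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker": self.markers,
                "p_hat": self.inclusion_prob,
                "alpha_mean": self.effect_mean,
                "bf": self.bayes_factors(),
            }
        )
        if marker_map is not None:
            df = marker_map.frame.merge(df, on="marker", how="right")
        return df


def run_bayesb(
    data: DamAssignedData, genotypes: GenotypeMatrix, config: MGWAConfig
) -> BayesBResult:
    """Sample the BayesB mixture over dam genotypes.

    Covariates are column-centered (record-weighted) additive codes of the
    dam.  Constant SNP columns carry no information and are skipped with a
    warning (their delta is drawn from the prior, so their inclusion
    probability is reported at its prior value ``1 - pi``).
    """
    if np.any(genotypes.codes == MISSING):
        raise MGWAError("genotypes contain missing codes; run impute_naive first")
    n = data.n_records
    k = genotypes.n_markers
    pi = compute_pi(n, k) if config.pi == "auto" else float(config.pi)
    if config.sigma2_alpha is not None:
        s2a = float(config.sigma2_alpha)
    elif config.genetic_variance is not None:
        p = genotypes.allele_freq()
        s2a = derive_effect_variance(config.genetic_variance, pi, p)
    else:
        raise MGWAError("config needs sigma2_alpha or genetic_variance")
    if s2a <= 0:
        raise MGWAError("sigma2_alpha must be positive")

    # dam-level layout: unique dam rows, per-record weights
    dam_rows, rec_dam = np.unique(data.dam_row, return_inverse=True)
    n_dams = len(dam_rows)
    n_d = np.bincount(rec_dam, minlength=n_dams).astype(np.float64)
    Zd = genotypes.codes[dam_rows].T.astype(np.float64)  # (k, n_dams)
    wmean = (Zd * n_d).sum(axis=1) / n
    Zd -= wmean[:, None]
    czz = (Zd * Zd * n_d).sum(axis=1)
    active = czz > 1e-9
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} constant SNP column(s) skipped", stacklevel=2
        )

    # fixed-effect CSR
    offsets = np.concatenate(([0], np.cumsum(data.factor_n_levels)))
    total_levels = int(offsets[-1])
    flat = np.concatenate(
        [data.factor_codes[:, f] + offsets[f] for f in range(len(data.factor_names))]
    )
    recs = np.tile(np.arange(n, dtype=np.int64), len(data.factor_names))
    order = np.argsort(flat, kind="stable")
    lvl_indptr = np.concatenate(
        ([0], np.cumsum(np.bincount(flat, minlength=total_levels)))
    ).astype(np.int64)
    lvl_rec = recs[order]
    lvl_free = np.zeros(total_levels, dtype=np.bool_)
    lvl_free[0] = True
    for f in range(1, len(data.factor_names)):
        lvl_free[offsets[f] + 1 : offsets[f + 1]] = True

    dam_indptr, dam_rec = _invert_dam(rec_dam, n_dams)

    rng = np.random.default_rng([config.seed, 0xB0B])
    _kernels.set_seed(config.seed % (2**31 - 1))
    e = data.y.copy()
    b = np.zeros(total_levels)
    alpha = np.zeros(k)
    delta = np.zeros(k, dtype=np.int64)
    sig2snp = config.nu * s2a / rng.chisquare(config.nu, size=k)
    sig2e = float(np.var(data.y)) / 2.0 or 1.0
    edam = np.zeros(n_dams)

    n_ret = n_retained(config.iterations, config.burn_in, config.thin)
    alpha_out = (
        np.zeros((n_ret, k), dtype=np.float32) if config.store_samples else None
    )
    sig2e_out = np.zeros(n_ret)
    mu_out = np.zeros(n_ret)
    incl = np.zeros(k, dtype=np.int64)
    eff_sum = np.zeros(k)
    row = 0
    for it in range(1, config.iterations + 1):
        sig2e = _kernels.bayesb_sweep(
            e, b, lvl_indptr, lvl_rec, lvl_free, edam, rec_dam.astype(np.int64),
            dam_indptr, dam_rec, n_d, Zd, czz, active, alpha, delta, sig2snp,
            config.nu, s2a, pi, sig2e,
        )
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            ad = alpha * delta
            if alpha_out is not None:
                alpha_out[row] = ad
            incl += delta
            eff_sum += ad
            sig2e_out[row] = sig2e
            mu_out[row] = b[0]
            row += 1
    return BayesBResult(
        inclusion_prob=incl / n_ret,
        effect_mean=eff_sum / n_ret,
        alpha_samples=alpha_out,
        sigma2_e=sig2e_out,
        mu=mu_out,
        pi=pi,
        sigma2_alpha=s2a,
        markers=list(genotypes.markers),
        skipped=~active,
        settings=dict(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed,
            nu=config.nu,
        ),
        Z_dam=Zd,
        dam_weights=n_d,
    )


def _invert_dam(rec_dam, n_dams):
    order = np.argsort(rec_dam, kind="stable")
    counts = np.bincount(rec_dam, minlength=n_dams)
    return (
        np.concatenate(([0], np.cumsum(counts))).astype(np.int64),
        order.astype(np.int64),
    )


def expected_window_share_pct(n_windows: int) -> float:
    """Expected % of genomic variance per window when no window is special."""
    if n_windows < 1:
        raise MGWAError("need at least one window")
    return 100.0 / n_windows


def window_variance(
    result: BayesBResult, windows: list[Window]
) -> pd.DataFrame:
    """Posterior mean % of the genomic variance explained by each window.

    Per retained draw, the genomic value of an individual is
    ``g_i = sum_j z_ij alpha_j delta_j``; a window's share is the variance
    (across individuals, offspring weighted by their dam's record count) of
    the window-restricted genomic value over the variance of ``g``.  Draws
    with zero total genomic variance contribute zero shares.
    """
    if result.alpha_samples is None:
        raise MGWAError("run_bayesb was called with store_samples=False")
    A = result.alpha_samples.astype(np.float64)  # (n_ret, k)
    Z = result.Z_dam  # (k, n_dams)
    w = result.dam_weights
    wsum = w.sum()
    col_of = {m: j for j, m in enumerate(result.markers)}

    def _wvar(G):  # weighted variance across dams, per draw
        mean = (G * w).sum(axis=1) / wsum
        cent = G - mean[:, None]
        return (cent * cent * w).sum(axis=1) / wsum

    total = _wvar(A @ Z)
    ok = total > 0
    shares = np.zeros((A.shape[0], len(windows)))
    for wi, win in enumerate(windows):
        idx = np.array([col_of[m] for m in win.marker_ids], dtype=int)
        v = _wvar(A[:, idx] @ Z[idx])
        shares[ok, wi] = v[ok] / total[ok]
    return pd.DataFrame(
        {
            "chrom": [w_.chrom for w_ in windows],
            "mb_index": [w_.mb_index for w_ in windows],
            "start_bp": [w_.start_bp for w_ in windows],
            "end_bp": [w_.end_bp for w_ in windows],
            "n_snps": [len(w_.marker_ids) for w_ in windows],
            "pct_var": 100.0 * shares.mean(axis=0),
        }
    )


def call_associated_windows(
    window_pct: pd.DataFrame,
    snp_table: pd.DataFrame,
    windows: list[Window],
    primary: float = 1.0,
    secondary: float = 0.5,
    bf_threshold: float = 10.0,
) -> pd.DataFrame:
    """Flag associated windows by the two-tier rule.

    Primary: window explains >= 1% of the genomic variance AND holds at
    least one SNP with BF strictly above the threshold; secondary: likewise
    at >= 0.5%.  Both the strict (>) SNP count used for calling and the
    non-strict (>=) count used in table-style reporting are emitted.
    """
    bf_of = dict(zip(snp_table["marker"], snp_table["bf"]))
    out = window_pct.copy()
    n_gt, n_ge, max_bf = [], [], []
    for win in windows:
        bfs = np.array([bf_of[m] for m in win.marker_ids])
        n_gt.append(int((bfs > bf_threshold).sum()))
        n_ge.append(int((bfs >= bf_threshold).sum()))
        max_bf.append(float(bfs.max()) if len(bfs) else 0.0)
    out["n_snps_bf_gt"] = n_gt
    out["n_snps_bf_ge"] = n_ge
    out["max_bf"] = max_bf
    has_snp = out["n_snps_bf_gt"] > 0
    tier = np.where(
        (out["pct_var"] >= primary) & has_snp,
        "primary",
        np.where((out["pct_var"] >= secondary) & has_snp, "secondary", ""),
    )
    out["tier"] = tier
    out["associated"] = out["tier"] != ""
    return out
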
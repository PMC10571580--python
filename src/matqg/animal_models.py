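"""Bayesian animal models with maternal effects, fitted by Gibbs sampling.

Five model structures of increasing complexity are supported, univariate or
bivariate (records sorted by individual, complete-case across traits):

=====  ==========================================================
model  random terms besides the residual
=====  ==========================================================
0      none (intercept + residual; diagnostic, conjugate limit)
1      direct additive genetic
2      direct + maternal genetic
3      direct + common litter
4      direct + maternal + common litter
5      direct + maternal + maternal environment
=====  ==========================================================

Direct and maternal breeding values are jointly ``N(0, A kron G0)`` where A
is the pedigree relationship matrix and G0 the (co)variance of the genetic
effects (2t x 2t with maternal effects, t traits); litter, maternal
environment and residual effects are iid with covariances Cc, Cme, R0.
Fixed effects and all covariance matrices carry flat priors; a p x p
covariance block with q levels is therefore drawn from an inverse-Wishart
full conditional with df = q - p - 1 and scale the effect cross-products
(for the genetic block, ``U' A^-1 U``).  Location parameters are updated
single-site
(Gauss-Seidel) which keeps the sweep linear in the data.

The phenotypic variance used for ratios includes the direct-maternal
covariance once (``sigma_P = s2d + s2m + s_dm + s2c + s2me + s2e``): each
record's maternal effect is carried by its dam, whose additive relationship
with the record is 1/2, so the variance of a phenotype picks up
``2*(1/2)*s_dm``.  This also makes reported ratios internally consistent
when the direct-maternal correlation is substantially negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from . import _kernels
from .pedigree import Pedigree, build_A_inverse
from .simulate import PhenotypeTable

_RANDOM_TERMS = {
    0: (),
    1: ("direct",),
    2: ("direct", "maternal"),
    3: ("direct", "litter"),
    4: ("direct", "maternal", "litter"),
    5: ("direct", "maternal", "maternal_env"),
}


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """One of the standard animal-model structures."""

    model_id: int
    n_traits: int = 1
    fixed_terms: list | None = None  # None = every fixed factor in the data

    def __post_init__(self):
        if self.model_id not in _RANDOM_TERMS:
            raise ModelError(f"model_id must be one of {sorted(_RANDOM_TERMS)}")
        if self.n_traits not in (1, 2):
            raise ModelError("n_traits must be 1 or 2")

    @property
    def random_terms(self) -> tuple:
        return _RANDOM_TERMS[self.model_id]

    @property
    def has_direct(self) -> bool:
        return "direct" in self.random_terms

    @property
    def has_maternal(self) -> bool:
        return "maternal" in self.random_terms

    @property
    def has_litter(self) -> bool:
        return "litter" in self.random_terms

    @property
    def has_me(self) -> bool:
        return "maternal_env" in self.random_terms

    @property
    def n_genetic(self) -> int:
        """Genetic-effect columns per animal: t directs, plus t maternals."""
        if not self.has_direct:
            return 0
        return self.n_traits * (2 if self.has_maternal else 1)


def n_retained(iterations: int, burn_in: int, thin: int) -> int:
    """Retained draws of a chain: floor((iterations - burn_in)/thin)."""
    if burn_in >= iterations:
        raise ModelError("burn_in must be smaller than iterations")
    return (iterations - burn_in) // thin


# ------------------------------------------------------------------ design


def _invert_groups(codes: np.ndarray, n_groups: int):
    """CSR-style map group -> record indices."""
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=n_groups)
    indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return indptr, order.astype(np.int64)


@dataclass
class DesignMatrices:
    """Indicator structures linking records to effect levels.

    Index arrays are the working representation; the sparse incidence
    matrices X, Zd, Zm, Wc, Wme are materialised on demand (absent terms are
    None).
    """

    model: ModelSpec
    traits: list
    y: np.ndarray  # (n_rec, t)
    factor_names: list
    factor_codes: np.ndarray  # (n_rec, n_factors) incl. leading intercept
    factor_n_levels: list
    factor_level_values: list
    record_animal: np.ndarray
    record_dam: np.ndarray | None
    litter_codes: np.ndarray | None
    litter_ids: list | None
    me_codes: np.ndarray | None
    me_ids: list | None
    n_animals: int
    animal_ids: list

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    def _indicator(self, codes, n_cols):
        n = len(codes)
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, n_cols)
        )

    @property
    def X(self):
        blocks = [
            self._indicator(self.factor_codes[:, f], self.factor_n_levels[f])
            for f in range(len(self.factor_names))
        ]
        return sparse.hstack(blocks, format="csr")

    @property
    def Zd(self):
        if not self.model.has_direct:
            return None
        return self._indicator(self.record_animal, self.n_animals)

    @property
    def Zm(self):
        if not self.model.has_maternal:
            return None
        return self._indicator(self.record_dam, self.n_animals)

    @property
    def Wc(self):
        if not self.model.has_litter:
            return None
        return self._indicator(self.litter_codes, len(self.litter_ids))

    @property
    def Wme(self):
        if not self.model.has_me:
            return None
        return self._indicator(self.me_codes, len(self.me_ids))


def build_design(
    phenotypes: PhenotypeTable,
    pedigree: Pedigree,
    model: ModelSpec,
    traits: list | None = None,
) -> DesignMatrices:
    """Factorise fixed effects and resolve animal/dam/litter columns.

    Complete-case: records missing any selected trait are dropped.  Raises
    when a maternal-model record has a dam absent from the pedigree.
    """
    traits = list(traits or phenotypes.traits[: model.n_traits])
    if len(traits) != model.n_traits:
        raise ModelError(
            f"model expects {model.n_traits} trait(s), got {traits}"
        )
    df = phenotypes.data
    keep = ~df[traits].isna().any(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    y = df[traits].to_numpy(dtype=float)

    fixed = list(model.fixed_terms or phenotypes.fixed)
    names = ["(intercept)"]
    codes_cols = [np.zeros(len(df), dtype=np.int64)]
    n_levels = [1]
    level_values = [["(mean)"]]
    for f in fixed:
        if f not in df.columns:
            raise ModelError(f"fixed factor {f!r} not in phenotype table")
        vals, uniq = pd.factorize(df[f], sort=True)
        if len(uniq) == 1:
            warnings.warn(
                f"fixed factor {f!r} has a single level; aliased with the mean",
                stacklevel=2,
            )
        names.append(f)
        codes_cols.append(vals.astype(np.int64))
        n_levels.append(len(uniq))
        level_values.append(list(uniq))

    record_animal = np.array(
        [pedigree.index_of(a) for a in df["animal"]], dtype=np.int64
    )
    record_dam = None
    if model.has_maternal or model.has_me:
        dams = []
        for a, d in zip(df["animal"], df["dam"]):
            try:
                dams.append(pedigree.index_of(d))
            except Exception:
                raise ModelError(
                    f"record for animal {a!r}: dam {d!r} absent from pedigree"
                ) from None
        record_dam = np.array(dams, dtype=np.int64)

    litter_codes = litter_ids = None
    if model.has_litter:
        if "litter" not in df.columns:
            raise ModelError("litter column required for litter-effect models")
        lc, lids = pd.factorize(df["litter"], sort=True)
        litter_codes, litter_ids = lc.astype(np.int64), list(lids)

    me_codes = me_ids = None
    if model.has_me:
        mc, mids = pd.factorize(df["dam"], sort=True)
        me_codes, me_ids = mc.astype(np.int64), list(mids)

    return DesignMatrices(
        model=model,
        traits=traits,
        y=y,
        factor_names=names,
        factor_codes=np.column_stack(codes_cols),
        factor_n_levels=n_levels,
        factor_level_values=level_values,
        record_animal=record_animal,
        record_dam=record_dam,
        litter_codes=litter_codes,
        litter_ids=litter_ids,
        me_codes=me_codes,
        me_ids=me_ids,
        n_animals=pedigree.n,
        animal_ids=pedigree.ids,
    )


# ----------------------------------------------------------- variance draws


def sample_invwishart(rng, df: float, S: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw, density |X|^{-(df+p+1)/2} exp(-tr(S X^-1)/2).

    Bartlett decomposition; the 1x1 case reduces to S/chi2(df).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    p = S.shape[0]
    if df <= p - 1:
        raise ModelError(f"inverse-Wishart needs df > p-1 (df={df}, p={p})")
    if p == 1:
        return S / rng.chisquare(df)
    S = S + np.eye(p) * 1e-12 * max(np.trace(S), 1.0)
    C = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = C @ A @ A.T @ C.T  # Wishart(df, S^-1)
    return np.linalg.inv(W)


# ----------------------------------------------------------------- results


@dataclass
class VarianceComponents:
    """One draw (or summary) of the model covariance blocks."""

    G0: np.ndarray | None  # (g, g) genetic; per-trait (direct, maternal) blocks
    Cc: np.ndarray | None  # (t, t) litter
    Cme: np.ndarray | None  # (t, t) maternal environment
    R0: np.ndarray  # (t, t) residual
    traits: list = field(default_factory=lambda: ["trait1"])
    has_maternal: bool = True


@dataclass
class GeneticParameters:
    """Variance ratios and genetic correlations derived from one draw."""

    h2d: np.ndarray
    h2m: np.ndarray
    c2: np.ndarray
    me2: np.ndarray
    rho_dm: np.ndarray
    rho_d: float | None = None  # cross-trait direct correlation (bivariate)
    rho_m: float | None = None


def derive_parameters(vc: VarianceComponents) -> GeneticParameters:
    """Ratios to the phenotypic variance and genetic correlations.

    ``sigma_P = s2d + s2m + s_dm + s2c + s2me + s2e`` per trait (terms absent
    from the model contribute zero).  Correlations with a zero variance in
    the denominator are returned as NaN.
    """
    t = len(vc.traits)
    h2d = np.zeros(t)
    h2m = np.zeros(t)
    c2 = np.zeros(t)
    me2 = np.zeros(t)
    rho_dm = np.full(t, np.nan)
    for tt in range(t):
        if vc.G0 is None:
            s2d = s2m = sdm = 0.0
        elif vc.has_maternal:
            di, mi = 2 * tt, 2 * tt + 1
            s2d, s2m, sdm = vc.G0[di, di], vc.G0[mi, mi], vc.G0[di, mi]
        else:
            s2d, s2m, sdm = vc.G0[tt, tt], 0.0, 0.0
        s2c = vc.Cc[tt, tt] if vc.Cc is not None else 0.0
        s2me = vc.Cme[tt, tt] if vc.Cme is not None else 0.0
        s2e = vc.R0[tt, tt]
        sigP = s2d + s2m + sdm + s2c + s2me + s2e
        h2d[tt] = s2d / sigP
        h2m[tt] = s2m / sigP
        c2[tt] = s2c / sigP
        me2[tt] = s2me / sigP
        if s2d > 0 and s2m > 0:
            rho_dm[tt] = sdm / math.sqrt(s2d * s2m)
    rho_d = rho_m = None
    if t == 2 and vc.G0 is not None:
        if vc.has_maternal:
            d1, m1, d2, m2 = 0, 1, 2, 3
            if vc.G0[d1, d1] > 0 and vc.G0[d2, d2] > 0:
                rho_d = vc.G0[d1, d2] / math.sqrt(vc.G0[d1, d1] * vc.G0[d2, d2])
            if vc.G0[m1, m1] > 0 and vc.G0[m2, m2] > 0:
                rho_m = vc.G0[m1, m2] / math.sqrt(vc.G0[m1, m1] * vc.G0[m2, m2])
        else:
            if vc.G0[0, 0] > 0 and vc.G0[1, 1] > 0:
                rho_d = vc.G0[0, 1] / math.sqrt(vc.G0[0, 0] * vc.G0[1, 1])
    return GeneticParameters(
        h2d=h2d, h2m=h2m, c2=c2, me2=me2, rho_dm=rho_dm, rho_d=rho_d, rho_m=rho_m
    )


# ------------------------------------------------------------------- state


@dataclass
class GibbsState:
    """Mutable sampler state: current locations, residuals, covariances."""

    design: DesignMatrices
    e: np.ndarray
    b: np.ndarray
    u: np.ndarray
    c: np.ndarray
    me: np.ndarray
    G0: np.ndarray | None
    Cc: np.ndarray | None
    Cme: np.ndarray | None
    R0: np.ndarray
    rng: np.random.Generator
    iteration: int = 0
    # frozen index arrays for the kernel
    _arrays: dict = field(default_factory=dict, repr=False)


def _empty_csr(n_groups):
    return np.zeros(n_groups + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)


def prepare_state(
    design: DesignMatrices, A_inverse, seed: int = 0
) -> GibbsState:
    """Initial state: zero locations, residuals equal to y, covariance blocks
    initialised from a crude split of the phenotypic variance."""
    model = design.model
    t = model.n_traits
    n_rec = design.n_records
    g = model.n_genetic
    var_y = np.maximum(np.var(design.y, axis=0), 1e-8)

    # flattened fixed-effect levels
    offsets = np.concatenate(([0], np.cumsum(design.factor_n_levels)))
    total_levels = int(offsets[-1])
    lvl_free = np.zeros(total_levels, dtype=np.bool_)
    lvl_all = []
    for f in range(len(design.factor_names)):
        gl = design.factor_codes[:, f] + offsets[f]
        lvl_all.append(gl)
        first = offsets[f]
        lvl_free[first + 1 : offsets[f + 1]] = True
    lvl_free[0] = True  # intercept
    # build one CSR over all levels
    flat = np.concatenate(lvl_all)
    recs = np.tile(np.arange(n_rec, dtype=np.int64), len(design.factor_names))
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=total_levels)
    lvl_indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    lvl_rec = recs[order]

    n_anim = design.n_animals
    if g:
        dir_indptr, dir_rec = _invert_groups(design.record_animal, n_anim)
        if model.has_maternal:
            mat_indptr, mat_rec = _invert_groups(design.record_dam, n_anim)
        else:
            mat_indptr, mat_rec = _empty_csr(n_anim)
        if model.has_maternal:
            eff_trait = np.repeat(np.arange(t), 2).astype(np.int64)
            eff_role = np.tile([0, 1], t).astype(np.int64)
        else:
            eff_trait = np.arange(t, dtype=np.int64)
            eff_role = np.zeros(t, dtype=np.int64)
    else:
        dir_indptr, dir_rec = _empty_csr(n_anim)
        mat_indptr, mat_rec = _empty_csr(n_anim)
        eff_trait = np.zeros(0, dtype=np.int64)
        eff_role = np.zeros(0, dtype=np.int64)

    Ainv = A_inverse.values if hasattr(A_inverse, "values") else A_inverse
    Ainv = sparse.csr_matrix(Ainv)

    if model.has_litter:
        lit_indptr, lit_rec = _invert_groups(
            design.litter_codes, len(design.litter_ids)
        )
        n_lit = len(design.litter_ids)
    else:
        (lit_indptr, lit_rec), n_lit = _empty_csr(0), 0
    if model.has_me:
        me_indptr, me_rec = _invert_groups(design.me_codes, len(design.me_ids))
        n_me = len(design.me_ids)
    else:
        (me_indptr, me_rec), n_me = _empty_csr(0), 0

    G0 = None
    if g:
        G0 = np.zeros((g, g))
        for k in range(g):
            share = 0.3 if eff_role[k] == 0 else 0.1
            G0[k, k] = share * var_y[eff_trait[k]]
    Cc = np.diag(0.1 * var_y) if model.has_litter else None
    Cme = np.diag(0.1 * var_y) if model.has_me else None
    R0 = np.diag(0.5 * var_y)

    state = GibbsState(
        design=design,
        e=design.y.copy(),
        b=np.zeros((total_levels, t)),
        u=np.zeros((n_anim, g)),
        c=np.zeros((n_lit, t)),
        me=np.zeros((n_me, t)),
        G0=G0,
        Cc=Cc,
        Cme=Cme,
        R0=R0,
        rng=np.random.default_rng([seed, 0x5151]),
    )
    state._arrays = dict(
        lvl_indptr=lvl_indptr,
        lvl_rec=lvl_rec,
        lvl_free=lvl_free,
        eff_trait=eff_trait,
        eff_role=eff_role,
        dir_indptr=dir_indptr,
        dir_rec=dir_rec,
        mat_indptr=mat_indptr,
        mat_rec=mat_rec,
        ai_indptr=Ainv.indptr.astype(np.int64),
        ai_idx=Ainv.indices.astype(np.int64),
        ai_val=Ainv.data.astype(np.float64),
        Ainv_sp=Ainv,
        lit_indptr=lit_indptr,
        lit_rec=lit_rec,
        me_indptr=me_indptr,
        me_rec=me_rec,
    )
    _kernels.set_seed(seed % (2**31 - 1))
    return state


def gibbs_step(state: GibbsState) -> GibbsState:
    """One full scan: every location parameter from its normal full
    conditional, then every covariance block from its inverse-Wishart full
    conditional.  Mutates and returns the state."""
    model = state.design.model
    t = model.n_traits
    a = state._arrays
    g = state.u.shape[1]
    R0inv = np.linalg.inv(state.R0)
    G0inv = np.linalg.inv(state.G0) if g else np.zeros((0, 0))
    Ccinv = np.linalg.inv(state.Cc) if model.has_litter else np.zeros((t, t))
    Cmeinv = np.linalg.inv(state.Cme) if model.has_me else np.zeros((t, t))
    _kernels.location_sweep(
        state.e,
        R0inv,
        state.b,
        a["lvl_indptr"],
        a["lvl_rec"],
        a["lvl_free"],
        state.u,
        a["eff_trait"],
        a["eff_role"],
        a["dir_indptr"],
        a["dir_rec"],
        a["mat_indptr"],
        a["mat_rec"],
        a["ai_indptr"],
        a["ai_idx"],
        a["ai_val"],
        G0inv,
        state.c,
        a["lit_indptr"],
        a["lit_rec"],
        Ccinv,
        state.me,
        a["me_indptr"],
        a["me_rec"],
        Cmeinv,
    )
    # Flat priors on every covariance block: the full conditional of a p x p
    # block with q effect levels and cross-product scale S is inverse-Wishart
    # with df = q - p - 1 (density |X|^{-q/2} exp(-tr(S X^-1)/2)).  A
    # divergent prior such as |X|^{-(p+1)/2} would make the posterior
    # improper here: with one record per animal the residual variance has a
    # non-integrable spike at zero and the chain gets absorbed.
    rng = state.rng

    def floor(M):  # keeps degenerate (zero-variance) draws invertible
        return M + 1e-12 * np.eye(M.shape[0])

    def df_of(q, p):
        # flat-prior conditional; clamped so the draw stays proper when a
        # term has very few levels (there the flat posterior is improper)
        return max(q - p - 1, p)

    if g:
        S = state.u.T @ (a["Ainv_sp"] @ state.u)
        state.G0 = floor(
            sample_invwishart(rng, df_of(state.design.n_animals, g), S)
        )
    if model.has_litter:
        nl = state.c.shape[0]
        state.Cc = floor(sample_invwishart(rng, df_of(nl, t), state.c.T @ state.c))
    if model.has_me:
        nm = state.me.shape[0]
        state.Cme = floor(sample_invwishart(rng, df_of(nm, t), state.me.T @ state.me))
    state.R0 = floor(
        sample_invwishart(
            rng, df_of(state.design.n_records, t), state.e.T @ state.e
        )
    )
    state.iteration += 1
    return state


def _vc_of(state: GibbsState) -> VarianceComponents:
    model = state.design.model
    return VarianceComponents(
        G0=state.G0,
        Cc=state.Cc,
        Cme=state.Cme,
        R0=state.R0,
        traits=state.design.traits,
        has_maternal=model.has_maternal,
    )


def _draw_row(state: GibbsState) -> dict:
    """Flatten the current covariance draw and its derived parameters."""
    model = state.design.model
    traits = state.design.traits
    vc = _vc_of(state)
    gp = derive_parameters(vc)
    row = {}
    for tt, tr in enumerate(traits):
        if model.has_direct:
            if model.has_maternal:
                di, mi = 2 * tt, 2 * tt + 1
                row[f"sigma2_d.{tr}"] = vc.G0[di, di]
                row[f"sigma2_m.{tr}"] = vc.G0[mi, mi]
                row[f"sigma_dm.{tr}"] = vc.G0[di, mi]
            else:
                row[f"sigma2_d.{tr}"] = vc.G0[tt, tt]
        if model.has_litter:
            row[f"sigma2_c.{tr}"] = vc.Cc[tt, tt]
        if model.has_me:
            row[f"sigma2_me.{tr}"] = vc.Cme[tt, tt]
        row[f"sigma2_e.{tr}"] = vc.R0[tt, tt]
        if model.has_direct:
            row[f"h2d.{tr}"] = gp.h2d[tt]
        if model.has_maternal:
            row[f"h2m.{tr}"] = gp.h2m[tt]
            row[f"rho_dm.{tr}"] = gp.rho_dm[tt]
        if model.has_litter:
            row[f"c2.{tr}"] = gp.c2[tt]
        if model.has_me:
            row[f"me2.{tr}"] = gp.me2[tt]
    if len(traits) == 2:
        row["sigma_e12"] = vc.R0[0, 1]
        if gp.rho_d is not None:
            row["rho_d"] = gp.rho_d
        if gp.rho_m is not None:
            row["rho_m"] = gp.rho_m
    return row


@dataclass
class GibbsResult:
    """Retained draws plus chain metadata."""

    samples: pd.DataFrame
    model: ModelSpec
    traits: list
    settings: dict

    def summaries(self) -> pd.DataFrame:
        return summarize_chain(self.samples)


def run_gibbs(
    phenotypes: PhenotypeTable,
    pedigree: Pedigree,
    model: ModelSpec,
    traits: list | None = None,
    iterations: int = 300_000,
    burn_in: int = 20_000,
    thin: int = 200,
    seed: int = 0,
    A_inverse=None,
) -> GibbsResult:
    """Fit one animal model and return the retained-sample matrix.

    Defaults mirror a long production chain (300k iterations, 20k burn-in,
    keep 1 in 200 -> 1,400 retained draws); tests and quick looks should
    pass something far shorter.
    """
    n_keep = n_retained(iterations, burn_in, thin)
    design = build_design(phenotypes, pedigree, model, traits)
    if A_inverse is None:
        A_inverse = build_A_inverse(pedigree)
    state = prepare_state(design, A_inverse, seed=seed)
    rows = []
    for it in range(1, iterations + 1):
        gibbs_step(state)
        if it > burn_in and (it - burn_in) % thin == 0:
            rows.append(_draw_row(state))
    samples = pd.DataFrame(rows)
    assert len(samples) == n_keep
    return GibbsResult(
        samples=samples,
        model=model,
        traits=design.traits,
        settings=dict(
            iterations=iterations, burn_in=burn_in, thin=thin, seed=seed
        ),
    )


# --------------------------------------------------------------- summaries


@dataclass
class PosteriorSummary:
    mean: float
    median: float
    mode: float
    sd: float
    hpd95: tuple
    n: int


def hpd_interval(samples, prob: float = 0.95) -> tuple:
    """Shortest interval containing ceil(prob*n) sorted samples (Chen-Shao)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(samples, prob: float = 0.95, bins: int = 50) -> PosteriorSummary:
    """Posterior mean/median/mode/SD and the HPD interval.

    The mode is the midpoint of the fullest of ``bins`` equal-width
    histogram bins (presentation only).  Requires at least 30 draws.
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 30:
        raise ModelError(f"need >= 30 retained samples, got {len(x)}")
    if np.ptp(x) == 0:
        mode = float(x[0])
    else:
        counts, edges = np.histogram(x, bins=bins)
        i = int(np.argmax(counts))
        mode = float(0.5 * (edges[i] + edges[i + 1]))
    return PosteriorSummary(
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        mode=mode,
        sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        hpd95=hpd_interval(x, prob),
        n=len(x),
    )


def summarize_chain(samples: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in samples.columns:
        s = summarize(samples[col].to_numpy())
        rows.append(
            {
                "parameter": col,
                "mean": s.mean,
                "median": s.median,
                "mode": s.mode,
                "sd": s.sd,
                "hpd95_low": s.hpd95[0],
                "hpd95_high": s.hpd95[1],
                "n": s.n,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def fit_bivariate_battery(
    phenotypes: PhenotypeTable,
    pedigree: Pedigree,
    trait_list: list,
    model_id: int = 4,
    **mcmc,
) -> pd.DataFrame:
    """One bivariate fit per (anchor trait, other trait) pair.

    ``trait_list[0]`` is the anchor (the selection trait, IMF in the design
    this emulates) and is paired with every remaining trait; each row
    reports the pair's genetic-parameter posterior summaries.
    """
    if len(trait_list) < 2:
        raise ModelError("need the anchor trait plus at least one other")
    anchor = trait_list[0]
    out = []
    for other in trait_list[1:]:
        res = run_gibbs(
            phenotypes,
            pedigree,
            ModelSpec(model_id=model_id, n_traits=2),
            traits=[anchor, other],
            **mcmc,
        )
        summ = res.summaries()
        row = {"trait": other}
        for name in (
            f"h2d.{other}",
            f"h2m.{other}",
            f"c2.{other}",
            f"rho_dm.{other}",
        ):
            if name in summ.index:
                short = name.split(".")[0]
                row[f"{short}_mean"] = summ.loc[name, "mean"]
                row[f"{short}_hpd_low"] = summ.loc[name, "hpd95_low"]
                row[f"{short}_hpd_high"] = summ.loc[name, "hpd95_high"]
        for name in ("rho_d", "rho_m"):
            if name in summ.index:
                row[f"{name}_mean"] = summ.loc[name, "mean"]
                row[f"{name}_hpd_low"] = summ.loc[name, "hpd95_low"]
                row[f"{name}_hpd_high"] = summ.loc[name, "hpd95_high"]
        out.append(row)
    return pd.DataFrame(out)
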
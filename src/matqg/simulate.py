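"""Synthetic divergent-selection datasets with known genetic truth.

The generator emulates the statistical design the estimators assume: a base
population of unrelated founders (13 sires, 83 dams by default), two lines
bred with a fixed mating ratio (each sire mated with five dams), full-sib
litters nested in dam x parity, and per-animal direct and maternal breeding
values drawn so that the joint covariance is exactly ``A kron G0``.  Optional
divergent selection ranks dams on the mean phenotype of two scored first-parity
offspring and retains the top 20% (high line) or bottom 20% (low line).

Default generating variances are the Model-4 decomposition of intramuscular
fat (IMF, g/100 g muscle) on a unit phenotypic-variance scale: direct 0.45,
maternal 0.09, litter 0.14, residual ~0.32, with a direct-maternal
correlation of -0.02 and a trait mean of 1.08.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geno_qc import MISSING, GenotypeMatrix, MarkerMap
from .pedigree import Pedigree, kinship, sort_and_validate


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


# ---------------------------------------------------------------- config


@dataclass
class LitterSizeSpec:
    """Litter-size distribution: Poisson(mean) truncated below at ``minimum``,
    or the rounded mean when ``fixed``."""

    mean: float = 8.0
    minimum: int = 1
    fixed: bool = False

    def draw(self, rng) -> int:
        if self.fixed:
            return int(round(self.mean))
        return max(self.minimum, int(rng.poisson(self.mean)))


@dataclass
class FixedEffectSpec:
    """A fixed factor: name, level count and per-level effect values.

    ``values`` has shape (n_levels,) or (n_levels, n_traits); level 0 is the
    reference.  ``per`` controls assignment granularity ("animal" or
    "litter"); the reserved names "sex" and "parity" are assigned
    structurally from the breeding design.
    """

    name: str
    n_levels: int
    values: np.ndarray | None = None
    per: str = "animal"

    def resolved_values(self, n_traits: int) -> np.ndarray:
        if self.values is None:
            v = np.linspace(-0.1, 0.1, self.n_levels)
        else:
            v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = np.tile(v[:, None], (1, n_traits))
        if v.shape != (self.n_levels, n_traits):
            raise ConfigError(
                f"fixed effect {self.name!r}: values shape {v.shape} "
                f"!= ({self.n_levels}, {n_traits})"
            )
        return v


def default_fixed_effects() -> list[FixedEffectSpec]:
    """Month of slaughtering (51 levels, per litter), sex (2), parity order
    (2: first vs later) and measurement method (2), with small effects."""
    return [
        FixedEffectSpec("month", 51, per="litter"),
        FixedEffectSpec("sex", 2, np.array([0.0, 0.05])),
        FixedEffectSpec("parity", 2, np.array([0.0, 0.05])),
        FixedEffectSpec("method", 2, np.array([0.0, 0.05])),
    ]


def _as_cov(x, t: int, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim == 0:
        m = np.eye(t) * float(m)
    elif m.ndim == 1:
        m = np.diag(m)
    if m.shape != (t, t):
        raise ConfigError(f"{name} must be {t}x{t}, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ConfigError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(m)) < -1e-10:
        raise ConfigError(f"{name} must be positive semi-definite")
    return m


def _default_G0(t: int) -> np.ndarray:
    # per-trait blocks [[s2d, s_dm], [s_dm, s2m]] for the Model-4 IMF values
    block = np.array([[0.45, -0.02 * np.sqrt(0.45 * 0.09)],
                      [-0.02 * np.sqrt(0.45 * 0.09), 0.09]])
    G0 = np.zeros((2 * t, 2 * t))
    for k in range(t):
        G0[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = block
    return G0


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Genetic effect ordering is (direct, maternal) within trait, so
    ``G0_true`` is ``2t x 2t`` with trait-k block at rows/cols 2k, 2k+1.
    """

    n_generations: int = 2
    base_sires: int = 13
    base_dams: int = 83
    n_lines: int = 2
    sires_per_gen: int = 8
    dams_per_gen: int = 40
    dams_per_sire: int = 5
    n_parities: int = 2
    litter_size: LitterSizeSpec = field(default_factory=LitterSizeSpec)
    traits: tuple = ("IMF",)
    trait_means: np.ndarray | None = None
    G0_true: np.ndarray | None = None
    c2: object = 0.14
    me2: object = 0.0
    R0_true: object = None
    fixed_effects: list = field(default_factory=default_fixed_effects)
    selection: str = "none"  # "none" | "divergent_on_trait1_top20pct"
    n_scored_per_dam: int = 2
    selected_top_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        t = self.n_traits
        if self.litter_size.mean < 1 or self.litter_size.minimum < 1:
            raise ConfigError("litter size must be >= 1")
        if self.dams_per_gen > self.sires_per_gen * self.dams_per_sire:
            raise ConfigError(
                "infeasible mating design: more dams than sire matings "
                f"({self.dams_per_gen} > {self.sires_per_gen} x {self.dams_per_sire})"
            )
        if self.selection not in ("none", "divergent_on_trait1_top20pct"):
            raise ConfigError(f"unknown selection scheme {self.selection!r}")
        self.G0_true = (
            _default_G0(t) if self.G0_true is None
            else _as_cov(self.G0_true, 2 * t, "G0_true")
        )
        self.Cc_true = _as_cov(self.c2, t, "c2")
        self.Cme_true = _as_cov(self.me2, t, "me2")
        self.R0_true = _as_cov(
            0.324 if self.R0_true is None else self.R0_true, t, "R0_true"
        )
        self.trait_means = (
            np.full(t, 1.08) if self.trait_means is None
            else np.asarray(self.trait_means, dtype=float)
        )

    @property
    def n_traits(self) -> int:
        return len(self.traits)


# ---------------------------------------------------------------- containers


@dataclass
class PhenotypeTable:
    """Complete-case phenotype records with their fixed-effect levels.

    ``data`` columns: animal, dam, litter, one column per fixed factor, one
    column per trait.
    """

    data: pd.DataFrame
    traits: list
    fixed: list

    @property
    def n(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path, traits, fixed) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"), list(traits), list(fixed))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedTruth:
    """Per-level generating values recorded alongside the data."""

    breeding_values: pd.DataFrame  # animal + a_d.<trait>, a_m.<trait>
    litter_effects: pd.DataFrame  # litter + c.<trait>
    maternal_env: pd.DataFrame  # dam + me.<trait>
    residuals: pd.DataFrame  # animal + e.<trait>
    dam_scores: pd.DataFrame | None = None  # selection bookkeeping
    qtl: pd.DataFrame | None = None


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    phenotypes: PhenotypeTable
    truth: SimulatedTruth
    genotypes: GenotypeMatrix | None = None
    marker_map: MarkerMap | None = None


# ---------------------------------------------------------------- helpers


def _mendelian_bv(rng, L_G0, bv_s, bv_d, F_s, F_d):
    """One offspring breeding-value vector: parent average plus a
    Mendelian-sampling deviation with covariance ``d * G0`` where
    ``d = 1/2 - (F_s + F_d)/4`` (unknown-parent variants as in Henderson)."""
    g = L_G0.shape[0]
    mean = np.zeros(g)
    if bv_s is None and bv_d is None:
        d = 1.0
    elif bv_s is None or bv_d is None:
        bv, Fp = (bv_d, F_d) if bv_s is None else (bv_s, F_s)
        mean = 0.5 * bv
        d = 0.75 - 0.25 * Fp
    else:
        mean = 0.5 * (bv_s + bv_d)
        d = 0.5 - 0.25 * (F_s + F_d)
    return mean + np.sqrt(d) * (L_G0 @ rng.standard_normal(g))


class _Cycler:
    """Deterministic shuffled round-robin over factor levels; guarantees every
    level is observed once enough assignments are made."""

    def __init__(self, rng, n_levels):
        self.rng = rng
        self.n = n_levels
        self.perm = rng.permutation(n_levels)
        self.i = 0

    def next(self) -> int:
        if self.i == self.n:
            self.perm = self.rng.permutation(self.n)
            self.i = 0
        v = int(self.perm[self.i])
        self.i += 1
        return v


def _chol_or_zero(m: np.ndarray) -> np.ndarray:
    if np.allclose(m, 0):
        return np.zeros_like(m)
    # tiny jitter tolerates semi-definite inputs
    w, V = np.linalg.eigh(m)
    w = np.clip(w, 0, None)
    return V * np.sqrt(w)


# ---------------------------------------------------------------- engine


class _Engine:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        t = config.n_traits
        self.t = t
        self.g = 2 * t
        self.L_G0 = _chol_or_zero(config.G0_true)
        self.L_Cc = _chol_or_zero(config.Cc_true)
        self.L_Cme = _chol_or_zero(config.Cme_true)
        self.L_R0 = _chol_or_zero(config.R0_true)
        self.has_me = not np.allclose(config.Cme_true, 0)
        # pedigree state
        self.ids: list[str] = []
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.gen: list[int] = []
        self.line: list = []
        self.sex: list[str] = []
        self.F: list[float] = []
        self.bv: list[np.ndarray] = []
        self._kin_memo: dict = {}
        # phenotype/truth state
        self.records: list[dict] = []
        self.resid: list[np.ndarray] = []
        self.litter_fx: dict[str, np.ndarray] = {}
        self.me_fx: dict[int, np.ndarray] = {}
        self.dam_scores: list[dict] = []
        self.first_parity_offspring: dict[int, list[int]] = {}
        self.cyclers = {
            f.name: _Cycler(self.rng, f.n_levels)
            for f in config.fixed_effects
            if f.name not in ("sex", "parity")
        }
        self.fx_values = {
            f.name: f.resolved_values(t) for f in config.fixed_effects
        }
        self.fx_per = {f.name: f.per for f in config.fixed_effects}

    # -- kinship over the growing pedigree ------------------------------
    def _phi(self, x: int, y: int) -> float:
        if x < 0 or y < 0:
            return 0.0
        if x > y:
            x, y = y, x
        key = (x, y)
        got = self._kin_memo.get(key)
        if got is not None:
            return got
        if x == y:
            val = 0.5 * (1.0 + self._phi(self.sire[x], self.dam[x]))
        else:
            val = 0.5 * (self._phi(self.sire[y], x) + self._phi(self.dam[y], x))
        self._kin_memo[key] = val
        return val

    def _add_animal(self, aid, s, d, gen, line, sex) -> int:
        i = len(self.ids)
        self.ids.append(aid)
        self.sire.append(s)
        self.dam.append(d)
        self.gen.append(gen)
        self.line.append(line)
        self.sex.append(sex)
        self.F.append(self._phi(s, d) if (s >= 0 and d >= 0) else 0.0)
        if s < 0 and d < 0:
            bv = self.L_G0 @ self.rng.standard_normal(self.g)
        else:
            bv = _mendelian_bv(
                self.rng,
                self.L_G0,
                self.bv[s] if s >= 0 else None,
                self.bv[d] if d >= 0 else None,
                self.F[s] if s >= 0 else 0.0,
                self.F[d] if d >= 0 else 0.0,
            )
        self.bv.append(bv)
        return i

    # -- phenotypes ------------------------------------------------------
    def _phenotype(self, i, dam_i, litter_id, parity, levels):
        cfg = self.cfg
        t = self.t
        a_d = self.bv[i][0::2]
        a_m = self.bv[dam_i][1::2]
        c = self.litter_fx.setdefault(
            litter_id, self.L_Cc @ self.rng.standard_normal(t)
        )
        if self.has_me:
            me = self.me_fx.setdefault(
                dam_i, self.L_Cme @ self.rng.standard_normal(t)
            )
        else:
            me = np.zeros(t)
        e = self.L_R0 @ self.rng.standard_normal(t)
        fixed = np.zeros(t)
        for name, lev in levels.items():
            fixed += self.fx_values[name][lev]
        y = cfg.trait_means + fixed + a_d + a_m + c + me + e
        rec = {
            "animal": self.ids[i],
            "dam": self.ids[dam_i],
            "litter": litter_id,
            **levels,
        }
        for k, trait in enumerate(cfg.traits):
            rec[trait] = y[k]
        self.records.append(rec)
        self.resid.append(e)
        return y

    # -- one generation of one line -------------------------------------
    def _breed(self, gen, line, sires, dams):
        cfg = self.cfg
        litter_levels_cache = {}
        offspring = []
        mating_sire = {}
        for j, dam_i in enumerate(dams):
            mating_sire[dam_i] = sires[j // cfg.dams_per_sire]
        for parity in range(1, cfg.n_parities + 1):
            for dam_i in dams:
                sire_i = mating_sire[dam_i]
                litter_id = f"{line}.G{gen}.{self.ids[dam_i]}.P{parity}"
                size = cfg.litter_size.draw(self.rng)
                lev_litter = {}
                for name, cyc in self.cyclers.items():
                    if self.fx_per[name] == "litter":
                        lev_litter[name] = cyc.next()
                for k in range(size):
                    sex = "M" if k % 2 == 0 else "F"
                    aid = f"{line}G{gen}N{len(self.ids):05d}"
                    i = self._add_animal(aid, sire_i, dam_i, gen, line, sex)
                    levels = dict(lev_litter)
                    for name, cyc in self.cyclers.items():
                        if self.fx_per[name] == "animal":
                            levels[name] = cyc.next()
                    if "sex" in self.fx_values:
                        levels["sex"] = 0 if sex == "M" else 1
                    if "parity" in self.fx_values:
                        levels["parity"] = 0 if parity == 1 else 1
                    self._phenotype(i, dam_i, litter_id, parity, levels)
                    offspring.append(i)
                    if parity == 1:
                        self.first_parity_offspring.setdefault(dam_i, []).append(i)
        return offspring

    # -- parent choice ---------------------------------------------------
    def _score_dam(self, dam_i):
        """Mean trait-1 phenotype of scored first-parity offspring
        (one male, one female when available)."""
        offs = self.first_parity_offspring.get(dam_i, [])
        males = [i for i in offs if self.sex[i] == "M"]
        females = [i for i in offs if self.sex[i] == "F"]
        scored = males[:1] + females[:1]
        scored = scored[: self.cfg.n_scored_per_dam]
        if not scored:
            return None, []
        trait1 = self.cfg.traits[0]
        rec_by_animal = {r["animal"]: r for r in self.records}
        vals = [rec_by_animal[self.ids[i]][trait1] for i in scored]
        return float(np.mean(vals)), [self.ids[i] for i in scored]

    def _select_parents(self, gen, line_k, line, cur_sires, cur_dams, offspring):
        cfg = self.cfg
        males = [i for i in offspring if self.sex[i] == "M"]
        females = [i for i in offspring if self.sex[i] == "F"]
        if cfg.selection == "none":
            if len(females) < cfg.dams_per_gen or len(males) < cfg.sires_per_gen:
                raise ConfigError(
                    f"line {line}: not enough offspring to form generation {gen + 1}"
                )
            dams = list(self.rng.choice(females, cfg.dams_per_gen, replace=False))
            sires = list(self.rng.choice(males, cfg.sires_per_gen, replace=False))
            return sires, dams
        # divergent selection on trait 1: high line (k=0) keeps top dams,
        # low line (k=1) keeps bottom dams
        scores = {}
        for dam_i in cur_dams:
            s, scored_ids = self._score_dam(dam_i)
            if s is None:
                continue
            scores[dam_i] = s
            self.dam_scores.append(
                {
                    "line": line,
                    "generation": gen,
                    "dam": self.ids[dam_i],
                    "score": s,
                    "scored_offspring": ",".join(scored_ids),
                    "selected": False,
                }
            )
        n_keep = max(1, int(np.ceil(cfg.selected_top_fraction * len(scores))))
        descending = line_k == 0
        ranked = sorted(scores, key=scores.get, reverse=descending)
        keep = set(ranked[:n_keep])
        for row in self.dam_scores:
            if row["generation"] == gen and row["line"] == line:
                row["selected"] = self.ids.index(row["dam"]) in keep  # small n
        elig_f = [i for i in females if self.dam[i] in keep]
        if len(elig_f) < cfg.dams_per_gen:
            raise ConfigError(
                f"line {line}: selected dams produced only {len(elig_f)} "
                f"daughters, need {cfg.dams_per_gen}"
            )
        dams = list(self.rng.choice(elig_f, cfg.dams_per_gen, replace=False))
        # one male per sire, from his highest-ranking mating with offspring
        sires = []
        for sire_i in cur_sires:
            cand_dams = sorted(
                (d for d in cur_dams if d in scores),
                key=scores.get,
                reverse=descending,
            )
            for d in cand_dams:
                sons = [
                    i for i in males if self.dam[i] == d and self.sire[i] == sire_i
                ]
                if sons:
                    sires.append(sons[0])
                    break
        pool = [i for i in males if self.dam[i] in keep and i not in sires]
        while len(sires) < cfg.sires_per_gen and pool:
            pick = int(self.rng.choice(pool))
            sires.append(pick)
            pool.remove(pick)
        if len(sires) < cfg.sires_per_gen:
            raise ConfigError(f"line {line}: not enough males for next generation")
        return sires[: cfg.sires_per_gen], dams

    # -- run -------------------------------------------------------------
    def run(self) -> SimulatedDataset:
        cfg = self.cfg
        rng = self.rng
        for k in range(cfg.base_sires):
            self._add_animal(f"BS{k + 1:03d}", -1, -1, 0, None, "M")
        for k in range(cfg.base_dams):
            self._add_animal(f"BD{k + 1:03d}", -1, -1, 0, None, "F")
        if cfg.base_sires < cfg.sires_per_gen or cfg.base_dams < cfg.n_lines * cfg.dams_per_gen:
            raise ConfigError("base population too small for the line design")
        line_names = (
            ["H", "L"] if cfg.n_lines == 2 else [f"L{k + 1}" for k in range(cfg.n_lines)]
        )
        base_sires = np.arange(cfg.base_sires)
        base_dam_pool = cfg.base_sires + rng.permutation(cfg.base_dams)
        parents = {}
        for k, line in enumerate(line_names):
            s = list(rng.choice(base_sires, cfg.sires_per_gen, replace=False))
            d = list(
                base_dam_pool[k * cfg.dams_per_gen : (k + 1) * cfg.dams_per_gen]
            )
            parents[line] = (s, d)
        for gen in range(1, cfg.n_generations + 1):
            for k, line in enumerate(line_names):
                sires, dams = parents[line]
                offspring = self._breed(gen, line, sires, dams)
                if gen < cfg.n_generations:
                    parents[line] = self._select_parents(
                        gen, k, line, sires, dams, offspring
                    )
        return self._finalize()

    def _finalize(self) -> SimulatedDataset:
        cfg = self.cfg
        ped_frame = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [self.ids[s] if s >= 0 else "0" for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else "0" for d in self.dam],
                "generation": self.gen,
                "line": self.line,
            }
        )
        ped = sort_and_validate(ped_frame)
        fixed_names = [f.name for f in cfg.fixed_effects]
        table = PhenotypeTable(
            data=pd.DataFrame(self.records),
            traits=list(cfg.traits),
            fixed=fixed_names,
        )
        bv = np.array(self.bv)
        bv_df = pd.DataFrame({"animal": self.ids})
        for k, trait in enumerate(cfg.traits):
            bv_df[f"a_d.{trait}"] = bv[:, 2 * k]
            bv_df[f"a_m.{trait}"] = bv[:, 2 * k + 1]
        lit_df = pd.DataFrame(
            [
                {"litter": lid, **{f"c.{tr}": v[k] for k, tr in enumerate(cfg.traits)}}
                for lid, v in self.litter_fx.items()
            ]
        )
        me_df = pd.DataFrame(
            [
                {"dam": self.ids[i], **{f"me.{tr}": v[k] for k, tr in enumerate(cfg.traits)}}
                for i, v in self.me_fx.items()
            ]
        )
        res_df = pd.DataFrame(
            [
                {
                    "animal": r["animal"],
                    **{f"e.{tr}": e[k] for k, tr in enumerate(cfg.traits)},
                }
                for r, e in zip(self.records, self.resid)
            ]
        )
        truth = SimulatedTruth(
            breeding_values=bv_df,
            litter_effects=lit_df,
            maternal_env=me_df,
            residuals=res_df,
            dam_scores=pd.DataFrame(self.dam_scores) if self.dam_scores else None,
        )
        return SimulatedDataset(pedigree=ped, phenotypes=table, truth=truth)


# ---------------------------------------------------------------- operations


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generational simulation (pedigree, truth, phenotypes)."""
    return _Engine(config).run()


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Pedigree of the configured breeding design (seed-deterministic)."""
    return simulate_dataset(config).pedigree


def simulate_breeding_values(
    ped: Pedigree, G0_true: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Draw (direct, maternal) breeding values over an arbitrary pedigree.

    Founders are iid ``N(0, G0)``; descendants are the parent average plus a
    Mendelian-sampling deviation scaled by ``1/2 - (F_s + F_d)/4``, giving a
    joint covariance of exactly ``A kron G0``.  Returns an (n, 2t) array in
    pedigree order with columns (direct, maternal) within trait.
    """
    G0 = np.asarray(G0_true, dtype=float)
    if np.min(np.linalg.eigvalsh(G0)) < -1e-10:
        raise ConfigError("G0_true must be positive semi-definite")
    rng = np.random.default_rng(seed)
    L = _chol_or_zero(G0)
    g = G0.shape[0]
    phi = kinship(ped)
    F = np.zeros(ped.n)
    bv = np.zeros((ped.n, g))
    founder = ped.is_founder
    n_f = int(founder.sum())
    bv[founder] = rng.standard_normal((n_f, g)) @ L.T
    for i in np.flatnonzero(~founder):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            F[i] = phi(s, d)
        bv[i] = _mendelian_bv(
            rng,
            L,
            bv[s] if s >= 0 else None,
            bv[d] if d >= 0 else None,
            F[s] if s >= 0 else 0.0,
            F[d] if d >= 0 else 0.0,
        )
    return bv


def simulate_phenotypes(
    ped: Pedigree, breeding_values: np.ndarray, config: SimulationConfig
) -> tuple[PhenotypeTable, SimulatedTruth]:
    """Phenotype every animal with a known dam on a pre-built pedigree.

    ``y_i = mean + fixed + a_d(i) + a_m(dam_i) + c(litter_i) [+ me(dam_i)] + e_i``
    with residual covariance ``R0_true`` across traits.  Litters are defined
    as dam x generation here (the engine tracks true parities itself).
    Raises if an animal has a recorded sire but no dam.
    """
    cfg = config
    t = cfg.n_traits
    rng = np.random.default_rng(cfg.seed + 1)
    L_Cc = _chol_or_zero(cfg.Cc_true)
    L_Cme = _chol_or_zero(cfg.Cme_true)
    L_R0 = _chol_or_zero(cfg.R0_true)
    has_me = not np.allclose(cfg.Cme_true, 0)
    cyclers = {
        f.name: _Cycler(rng, f.n_levels)
        for f in cfg.fixed_effects
        if f.name not in ("sex", "parity")
    }
    fx_values = {f.name: f.resolved_values(t) for f in cfg.fixed_effects}
    litter_fx: dict[str, np.ndarray] = {}
    me_fx: dict[int, np.ndarray] = {}
    records, resid = [], []
    ids = ped.ids
    gens = list(ped.frame["generation"])
    for i in range(ped.n):
        d = ped.dam_idx[i]
        if d < 0:
            if ped.sire_idx[i] >= 0:
                raise ConfigError(f"animal {ids[i]!r} has a sire but no dam in pedigree")
            continue
        litter_id = f"{ids[d]}.G{gens[i]}"
        c = litter_fx.setdefault(litter_id, L_Cc @ rng.standard_normal(t))
        me = (
            me_fx.setdefault(d, L_Cme @ rng.standard_normal(t))
            if has_me
            else np.zeros(t)
        )
        e = L_R0 @ rng.standard_normal(t)
        levels = {}
        fixed = np.zeros(t)
        for name, cyc in cyclers.items():
            levels[name] = cyc.next()
        if "sex" in fx_values:
            levels["sex"] = int(rng.integers(2))
        if "parity" in fx_values:
            levels["parity"] = 0
        for name, lev in levels.items():
            fixed += fx_values[name][lev]
        a_d = breeding_values[i, 0::2]
        a_m = breeding_values[d, 1::2]
        y = cfg.trait_means + fixed + a_d + a_m + c + me + e
        rec = {"animal": ids[i], "dam": ids[d], "litter": litter_id, **levels}
        for k, trait in enumerate(cfg.traits):
            rec[trait] = y[k]
        records.append(rec)
        resid.append(e)
    table = PhenotypeTable(
        data=pd.DataFrame(records),
        traits=list(cfg.traits),
        fixed=[f.name for f in cfg.fixed_effects],
    )
    bv_df = pd.DataFrame({"animal": ids})
    for k, trait in enumerate(cfg.traits):
        bv_df[f"a_d.{trait}"] = breeding_values[:, 2 * k]
        bv_df[f"a_m.{trait}"] = breeding_values[:, 2 * k + 1]
    truth = SimulatedTruth(
        breeding_values=bv_df,
        litter_effects=pd.DataFrame(
            [
                {"litter": lid, **{f"c.{tr}": v[k] for k, tr in enumerate(cfg.traits)}}
                for lid, v in litter_fx.items()
            ]
        ),
        maternal_env=pd.DataFrame(
            [
                {"dam": ids[i], **{f"me.{tr}": v[k] for k, tr in enumerate(cfg.traits)}}
                for i, v in me_fx.items()
            ]
        ),
        residuals=pd.DataFrame(
            [
                {"animal": r["animal"], **{f"e.{tr}": e[k] for k, tr in enumerate(cfg.traits)}}
                for r, e in zip(records, resid)
            ]
        ),
    )
    return table, truth


def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    n_chrom: int,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    chrom_length_bp: int = 100_000_000,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Gene-drop SNP genotypes through the pedigree.

    Founder alleles are Bernoulli(p_j) with p_j uniform in ``maf_range``;
    offspring inherit one allele from each parent independently per locus
    (linkage equilibrium).  Map positions are uniform per chromosome.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if n_chrom < 1:
        raise ConfigError("n_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    if n_snps == 0:
        return (
            GenotypeMatrix(
                codes=np.zeros((ped.n, 0), dtype=np.int8),
                individuals=ped.ids,
                markers=[],
            ),
            MarkerMap(pd.DataFrame(columns=["marker", "chrom", "pos"])),
        )
    p = rng.uniform(lo, hi, n_snps)
    alleles = np.zeros((ped.n, 2, n_snps), dtype=np.int8)
    for i in range(ped.n):
        for slot, parent in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if parent < 0:
                alleles[i, slot] = rng.random(n_snps) < p
            else:
                pick = rng.integers(0, 2, n_snps)
                alleles[i, slot] = alleles[parent, pick, np.arange(n_snps)]
    codes = alleles.sum(axis=1).astype(np.int8)
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_snps))
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        m = chrom == c
        pos[m] = np.sort(rng.integers(1, chrom_length_bp + 1, int(m.sum())))
    markers = [f"snp{c}_{j}" for j, c in enumerate(chrom)]
    mm = MarkerMap(
        pd.DataFrame({"marker": markers, "chrom": chrom.astype(str), "pos": pos})
    )
    gm = GenotypeMatrix(codes=codes, individuals=ped.ids, markers=markers)
    return gm, mm


def inject_dam_qtl(
    dataset: SimulatedDataset,
    window: tuple,
    effect_size: float,
    n_qtl: int = 1,
    trait: str | None = None,
) -> SimulatedDataset:
    """Plant a maternal QTL: offspring phenotypes incremented by
    ``effect_size * dam_genotype_code`` for each of ``n_qtl`` SNPs in the
    given (chrom, 1-Mb index) window.  Returns a new dataset; the truth table
    records the QTL markers and effects."""
    if dataset.genotypes is None or dataset.marker_map is None:
        raise ConfigError("dataset has no genotypes")
    chrom, mb = window
    mm = dataset.marker_map.frame
    in_win = (mm["chrom"].astype(str) == str(chrom)) & (
        (mm["pos"] - 1) // 1_000_000 == mb
    )
    idx = np.flatnonzero(in_win.to_numpy())
    if len(idx) < max(n_qtl, 1):
        raise ConfigError(
            f"window {window} holds {len(idx)} SNPs, need at least {max(n_qtl, 1)}"
        )
    centre = (mb + 0.5) * 1_000_000
    idx = idx[np.argsort(np.abs(mm["pos"].to_numpy()[idx] - centre))][:n_qtl]
    trait = trait or dataset.phenotypes.traits[0]
    gm = dataset.genotypes
    row_of = {a: i for i, a in enumerate(gm.individuals)}
    data = dataset.phenotypes.data.copy()
    dam_rows = data["dam"].map(row_of)
    if dam_rows.isna().any():
        raise ConfigError("some dams are not genotyped")
    shift = np.zeros(len(data))
    for j in idx:
        shift += effect_size * gm.codes[dam_rows.to_numpy(dtype=int), j]
    data[trait] = data[trait] + shift
    qtl = pd.DataFrame(
        {
            "marker": [gm.markers[j] for j in idx],
            "chrom": mm["chrom"].to_numpy()[idx],
            "pos": mm["pos"].to_numpy()[idx],
            "effect": effect_size,
            "trait": trait,
        }
    )
    phen = PhenotypeTable(
        data=data, traits=dataset.phenotypes.traits, fixed=dataset.phenotypes.fixed
    )
    truth = replace(dataset.truth, qtl=qtl)
    return replace(dataset, phenotypes=phen, truth=truth)


# ------------------------------------------------------------ composites

SFA_COMPONENTS = ["C14:0", "C15:0", "C16:0", "C17:0", "C18:0"]
MUFA_COMPONENTS = ["C16:1n7", "C18:1n7", "C18:1n9"]
PUFA_COMPONENTS = [
    "C18:2n6", "C18:3n3", "C20:2n6", "C20:3n6", "C20:4n6",
    "C20:5n3", "C22:4n6", "C22:5n3", "C22:6n3",
]


def derive_composite_traits(table):
    """Append SFA, MUFA, PUFA totals and MUFA/SFA, PUFA/SFA ratios.

    Totals are plain sums of the component fatty-acid percentage columns;
    absent components count as zero (with a warning).  Raises
    ``ZeroDivisionError`` when a ratio is requested and SFA is zero.
    Accepts a :class:`PhenotypeTable` or a bare DataFrame.
    """
    is_pt = isinstance(table, PhenotypeTable)
    df = (table.data if is_pt else table).copy()
    missing = []

    def total(components):
        s = np.zeros(len(df))
        for c in components:
            if c in df.columns:
                s = s + df[c].to_numpy(dtype=float)
            else:
                missing.append(c)
        return s

    df["SFA"] = total(SFA_COMPONENTS)
    df["MUFA"] = total(MUFA_COMPONENTS)
    df["PUFA"] = total(PUFA_COMPONENTS)
    if missing:
        warnings.warn(
            f"composite traits: missing components treated as 0: {sorted(set(missing))}",
            stacklevel=2,
        )
    if np.any(df["SFA"].to_numpy() == 0):
        raise ZeroDivisionError("SFA is zero for some records; ratios undefined")
    df["MUFA/SFA"] = df["MUFA"] / df["SFA"]
    df["PUFA/SFA"] = df["PUFA"] / df["SFA"]
    new_traits = ["SFA", "MUFA", "PUFA", "MUFA/SFA", "PUFA/SFA"]
    if is_pt:
        return PhenotypeTable(
            data=df, traits=table.traits + [t for t in new_traits if t not in table.traits],
            fixed=table.fixed,
        )
    return df
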
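"""Genotype quality control and 1-Mb window construction.

Filters follow the usual array-QC order — minor allele frequency, per-marker
missingness, per-individual missingness, sex chromosomes — with the boundary
conventions MAF strictly below the threshold and missingness strictly above.
Missing genotypes remaining after QC are filled with the marker's rounded
expected code ``2*p_hat`` (a deliberately naive, clearly labelled stand-in
for haplotype-based imputation, which is out of scope here).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype code
MISSING = np.int8(-1)

_ALLOWED = frozenset((-1, 0, 1, 2))
DEFAULT_SEX_CHROMS = ("X", "Y", "XY")


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """0/1/2 additive genotype codes, individuals x markers; -1 = missing."""

    codes: np.ndarray
    individuals: list
    markers: list

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise GenotypeError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = set(np.unique(self.codes)) - _ALLOWED
        if bad:
            raise GenotypeError(f"invalid genotype codes {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per marker, missing set aside."""
        codes = self.codes.astype(float)
        codes[self.codes == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # ---------------------------------------------------------------- io
    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Matrix dialect: first column individual id, one column per marker,
        codes 0/1/2 and NA/-1 for missing."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        codes = df.to_numpy(dtype=float)
        codes = np.where(np.isnan(codes), -1, codes).astype(np.int8)
        return cls(codes=codes, individuals=list(df.index.astype(str)),
                   markers=list(df.columns))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.codes, index=self.individuals, columns=self.markers)
        df.where(df != int(MISSING), other=pd.NA).to_csv(path, sep="\t")


@dataclass
class MarkerMap:
    """Per-marker chromosome label and 1-based bp position, sorted within
    chromosome."""

    frame: pd.DataFrame  # columns marker, chrom, pos

    def __post_init__(self):
        df = self.frame
        required = {"marker", "chrom", "pos"}
        if not required.issubset(df.columns):
            raise GenotypeError(f"marker map needs columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if len(df) and (df["pos"] < 1).any():
            raise GenotypeError("map positions must be >= 1")
        for _, grp in df.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise GenotypeError("map positions must be sorted within chromosome")
        self.frame = df.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def subset(self, marker_ids) -> "MarkerMap":
        keep = self.frame["marker"].isin(set(marker_ids))
        return MarkerMap(self.frame.loc[keep])


@dataclass
class QCReport:
    """Removal counts per filter, in application order."""

    removed: dict = field(default_factory=dict)  # filter name -> count
    initial_markers: int = 0
    initial_individuals: int = 0
    final_markers: int = 0
    final_individuals: int = 0
    imputation: str = "none"
    empty_result: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def apply_qc(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    maf: float = 0.05,
    marker_missing: float = 0.05,
    indiv_missing: float = 0.03,
    sex_chroms: tuple = DEFAULT_SEX_CHROMS,
) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Apply the four QC filters in order and report removal counts.

    Boundary rules: markers with MAF *lower than* ``maf`` are removed (equal
    kept); missingness uses *greater than* (equal kept).  MAF denominators
    use observed alleles only.
    """
    report = QCReport(
        initial_markers=gm.n_markers,
        initial_individuals=gm.n_individuals,
        imputation="naive expected-genotype (2*p_hat, rounded); "
        "haplotype-based imputation not performed",
    )
    order = mm.frame.set_index("marker").loc[gm.markers]
    codes = gm.codes
    marker_ids = np.array(gm.markers, dtype=object)
    indiv_ids = np.array(gm.individuals, dtype=object)

    # 1. minor allele frequency (strict <)
    maf_vals = gm.maf()
    keep = ~(maf_vals < maf)
    keep &= ~np.isnan(maf_vals)
    report.removed["maf"] = int((~keep).sum())
    codes, marker_ids = codes[:, keep], marker_ids[keep]

    # 2. per-marker missing rate (strict >)
    if codes.shape[1]:
        miss_rate = (codes == MISSING).mean(axis=0)
        keep = ~(miss_rate > marker_missing)
    else:
        keep = np.zeros(0, dtype=bool)
    report.removed["marker_missing"] = int((~keep).sum())
    codes, marker_ids = codes[:, keep], marker_ids[keep]

    # 3. per-individual missing rate (strict >)
    if codes.shape[1]:
        ind_rate = (codes == MISSING).mean(axis=1)
        keep_i = ~(ind_rate > indiv_missing)
    else:
        keep_i = np.ones(len(indiv_ids), dtype=bool)
    report.removed["indiv_missing"] = int((~keep_i).sum())
    codes, indiv_ids = codes[keep_i], indiv_ids[keep_i]

    # 4. sex chromosomes
    chrom_of = dict(zip(order.index, order["chrom"]))
    sexset = {str(c).upper() for c in sex_chroms}
    keep = np.array(
        [str(chrom_of[m]).upper() not in sexset for m in marker_ids], dtype=bool
    )
    report.removed["sex_chromosomes"] = int((~keep).sum())
    codes, marker_ids = codes[:, keep], marker_ids[keep]

    report.final_markers = len(marker_ids)
    report.final_individuals = len(indiv_ids)
    if report.final_markers == 0:
        report.empty_result = True
        warnings.warn("QC removed every marker", stacklevel=2)
    out = GenotypeMatrix(
        codes=codes, individuals=list(indiv_ids), markers=list(marker_ids)
    )
    return out, mm.subset(marker_ids), report


def impute_naive(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing code with the marker's rounded expectation
    ``2*p_hat``; observed codes are untouched."""
    codes = gm.codes.copy()
    miss = codes == MISSING
    if not miss.any():
        return GenotypeMatrix(codes=codes, individuals=list(gm.individuals),
                              markers=list(gm.markers))
    p = gm.allele_freq()
    all_missing = np.isnan(p)
    if all_missing.any():
        bad = [gm.markers[j] for j in np.flatnonzero(all_missing)[:5]]
        raise GenotypeError(
            f"markers entirely missing (should have been filtered): {bad}"
        )
    fill = np.rint(2.0 * p).astype(np.int8)
    rows, cols = np.nonzero(miss)
    codes[rows, cols] = fill[cols]
    return GenotypeMatrix(codes=codes, individuals=list(gm.individuals),
                          markers=list(gm.markers))


@dataclass
class Window:
    """One 1-Mb genomic window: markers with equal ``floor((pos-1)/1e6)``."""

    chrom: str
    mb_index: int
    marker_ids: list

    @property
    def start_bp(self) -> int:
        return self.mb_index * 1_000_000 + 1

    @property
    def end_bp(self) -> int:
        return (self.mb_index + 1) * 1_000_000


def build_windows(mm: MarkerMap, sex_chroms: tuple = DEFAULT_SEX_CHROMS) -> list:
    """Group autosomal markers into non-empty 1-Mb windows.

    Bins are half-open 1-based intervals ``[m*1e6 + 1, (m+1)*1e6]``.  Raises
    if the map still carries sex chromosomes.
    """
    df = mm.frame
    sexset = {str(c).upper() for c in sex_chroms}
    if len(df) and df["chrom"].str.upper().isin(sexset).any():
        raise GenotypeError("marker map contains sex chromosomes; filter first")
    windows = []
    if not len(df):
        return windows
    mb = (df["pos"] - 1) // 1_000_000
    for (chrom, mbi), grp in df.groupby(["chrom", mb], sort=False):
        windows.append(
            Window(chrom=str(chrom), mb_index=int(mbi), marker_ids=list(grp["marker"]))
        )
    windows.sort(key=lambda w: (_chrom_key(w.chrom), w.mb_index))
    return windows


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


# ------------------------------------------------------------------- PLINK io


def write_plink(gm: GenotypeMatrix, mm: MarkerMap, prefix: str) -> None:
    """Write text PLINK ped/map.  Dialect: alleles 'A' (reference, counted by
    the 0/1/2 code) and 'B'; missing is '0 0'; family id equals individual id."""
    order = mm.frame.set_index("marker").loc[gm.markers]
    with open(f"{prefix}.map", "w") as fh:
        for m, row in order.iterrows():
            fh.write(f"{row['chrom']}\t{m}\t0\t{row['pos']}\n")
    pair = {0: "B B", 1: "A B", 2: "A A", -1: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in enumerate(gm.individuals):
            geno = " ".join(pair[int(c)] for c in gm.codes[i])
            fh.write(f"{ind} {ind} 0 0 0 -9 {geno}\n")


def read_plink(prefix: str) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read the text PLINK dialect written by :func:`write_plink` (counts of
    allele 'A'; '0' alleles mean missing)."""
    mrows = []
    with open(f"{prefix}.map") as fh:
        for line in fh:
            chrom, marker, _cm, pos = line.split()
            mrows.append({"marker": marker, "chrom": chrom, "pos": int(pos)})
    mm = MarkerMap(pd.DataFrame(mrows))
    individuals, rows = [], []
    k = len(mrows)
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * k:
                raise GenotypeError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'}: "
                    f"expected {6 + 2 * k} fields, got {len(parts)}"
                )
            individuals.append(parts[1])
            alleles = parts[6:]
            codes = np.empty(k, dtype=np.int8)
            for j in range(k):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                codes[j] = -1 if "0" in (a, b) else (a == "A") + (b == "A")
            rows.append(codes)
    gm = GenotypeMatrix(
        codes=np.vstack(rows) if rows else np.zeros((0, k), dtype=np.int8),
        individuals=individuals,
        markers=[r["marker"] for r in mrows],
    )
    return gm, mm
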
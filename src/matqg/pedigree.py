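"""Pedigree validation, inbreeding and additive relationship matrices.

The numerator (additive) relationship matrix ``A`` and its sparse inverse are
the genetic covariance structure shared by every sampler and simulator in the
package: vectors of breeding values are modelled as ``N(0, A kron G0)``.

Unknown parents are treated as unrelated, non-inbred founders.  Animals that
appear only as parents are inserted automatically as founders, which is how
real pedigree files are usually laid out.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: token used for an unknown parent in files and in-memory frames
UNKNOWN = "0"

_DENSE_LIMIT = 6000  # dense A is quadratic in memory; study scale is 3,677


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate or bad reference)."""


def _norm_id(value) -> str:
    """Normalise an id token; empty / NaN / '0' mean unknown."""
    if value is None:
        return UNKNOWN
    if isinstance(value, float) and np.isnan(value):
        return UNKNOWN
    s = str(value).strip()
    if s == "" or s == "0" or s.lower() == "nan":
        return UNKNOWN
    # "12.0" from a float-typed CSV column
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


@dataclass
class Pedigree:
    """Validated, parents-first ordered pedigree.

    Attributes
    ----------
    frame:
        Columns ``animal, sire, dam, generation, line`` in topological
        (parents-first) order.  ``sire``/``dam`` are :data:`UNKNOWN` for
        founders; ``line`` may be ``None``.
    sire_idx, dam_idx:
        Integer positions of the parents in ``frame`` (-1 for unknown).
    """

    frame: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.frame["animal"])}

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list:
        return list(self.frame["animal"])

    def index_of(self, animal_id: str) -> int:
        try:
            return self._index[str(animal_id)]
        except KeyError:
            raise PedigreeError(f"animal {animal_id!r} not in pedigree") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    # ------------------------------------------------------------------ io
    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str)
        return sort_and_validate(df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix ``A`` or its inverse, in pedigree order."""

    values: object  # dense ndarray (A) or scipy sparse (A inverse)
    kind: str  # "A" | "A_inverse"
    ids: list

    def to_coo_tsv(self, path) -> None:
        """Write non-zero entries as coordinate-format TSV (i, j, value)."""
        m = sparse.coo_matrix(self.values)
        pd.DataFrame({"i": m.row, "j": m.col, "value": m.data}).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------- validation


def sort_and_validate(records) -> Pedigree:
    """Normalise, complete and topologically sort raw pedigree records.

    ``records`` may be a DataFrame with columns ``animal, sire, dam``
    (optionally ``generation, line``) or an iterable of tuples in that order.
    Parents that never appear as animals are inserted as founders.  Raises
    :class:`PedigreeError` on duplicate ids or parenthood cycles.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [tuple(r) for r in records]
        width = max((len(r) for r in rows), default=3)
        cols = ["animal", "sire", "dam", "generation", "line"][:width]
        df = pd.DataFrame(rows, columns=cols)
    for col in ("generation", "line"):
        if col not in df.columns:
            df[col] = None

    animals = [_norm_id(a) for a in df["animal"]]
    sires = [_norm_id(s) for s in df["sire"]]
    dams = [_norm_id(d) for d in df["dam"]]

    seen = set()
    for a in animals:
        if a == UNKNOWN:
            raise PedigreeError("animal id missing/unknown in a record")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)

    # auto-insert parents that appear only as parents (founders)
    extra = []
    for p in sires + dams:
        if p != UNKNOWN and p not in seen:
            seen.add(p)
            extra.append(p)

    n_extra = len(extra)
    all_animals = extra + animals
    all_sires = [UNKNOWN] * n_extra + sires
    all_dams = [UNKNOWN] * n_extra + dams
    gens = [0] * n_extra + list(df["generation"])
    lines = [None] * n_extra + list(df["line"])
    pos = {a: i for i, a in enumerate(all_animals)}

    for a, s, d in zip(all_animals, all_sires, all_dams):
        if a in (s, d):
            raise PedigreeError(f"animal {a!r} listed as its own parent")

    # Kahn's algorithm with a heap on the original position: deterministic and
    # order-preserving when the input is already parents-first.
    n = len(all_animals)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(all_sires, all_dams)):
        for p in (s, d):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) != n:
        bad = all_animals[int(np.flatnonzero(indeg > 0)[0])]
        raise PedigreeError(f"pedigree cycle detected involving animal {bad!r}")

    frame = pd.DataFrame(
        {
            "animal": [all_animals[i] for i in order],
            "sire": [all_sires[i] for i in order],
            "dam": [all_dams[i] for i in order],
            "generation": [gens[i] for i in order],
            "line": [lines[i] for i in order],
        }
    )
    index = {a: i for i, a in enumerate(frame["animal"])}
    sire_idx = np.array(
        [index[s] if s != UNKNOWN else -1 for s in frame["sire"]], dtype=np.int64
    )
    dam_idx = np.array(
        [index[d] if d != UNKNOWN else -1 for d in frame["dam"]], dtype=np.int64
    )
    return Pedigree(frame=frame, sire_idx=sire_idx, dam_idx=dam_idx, _index=index)


# ---------------------------------------------------------------- inbreeding


def kinship(ped: Pedigree, memo: dict | None = None):
    """Return a memoized kinship function ``phi(i, j)`` over pedigree positions.

    ``phi(i, i) = (1 + F_i)/2`` and the additive relationship is
    ``a(i, j) = 2 phi(i, j)``.  Unknown parents contribute zero.
    """
    sire, dam = ped.sire_idx, ped.dam_idx
    if memo is None:
        memo = {}

    def phi(x: int, y: int) -> float:
        if x < 0 or y < 0:
            return 0.0
        if x > y:
            x, y = y, x
        key = (x, y)
        got = memo.get(key)
        if got is not None:
            return got
        if x == y:
            val = 0.5 * (1.0 + phi(sire[x], dam[x]))
        else:
            # recurse through the later animal's parents (both earlier)
            val = 0.5 * (phi(sire[y], x) + phi(dam[y], x))
        memo[key] = val
        return val

    return phi


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by memoized kinship recursion.

    Founders (and animals with any unknown parent) have ``F = 0``; otherwise
    ``F_i = a(sire_i, dam_i)/2``, the kinship of the parents.
    """
    phi = kinship(ped)
    F = np.zeros(ped.n)
    for i in range(ped.n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            F[i] = phi(s, d)
    return F


# ------------------------------------------------------------------- build A


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Dense additive relationship matrix by the tabular method.

    ``a(i, j) = (a(j, sire_i) + a(j, dam_i))/2`` for earlier ``j`` and
    ``a(i, i) = 1 + a(sire_i, dam_i)/2``.  Dense storage; intended for
    pedigrees up to a few thousand animals.
    """
    n = ped.n
    if n > _DENSE_LIMIT:
        raise PedigreeError(
            f"dense A limited to {_DENSE_LIMIT} animals (got {n}); "
            "use build_A_inverse/inbreeding for larger pedigrees"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            if i:
                A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            if i:
                A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        if i:
            A[:i, i] = A[i, :i]
    return RelationshipMatrix(values=A, kind="A", ids=ped.ids)


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> RelationshipMatrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal ``i`` is
    ``d_i = 1/2 - (F_s + F_d)/4`` with both parents known,
    ``3/4 - F_p/4`` with one, and ``1`` for founders; its reciprocal is
    spread over the (i, sire, dam) block.
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        parents = [p for p in (s, d) if p >= 0]
        for p in parents:
            for q in parents:
                add(p, q, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(values=Ainv, kind="A_inverse", ids=ped.ids)
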
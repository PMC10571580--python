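"""Shared fixtures: small pedigrees and random-pedigree generation."""

import numpy as np
import pandas as pd
import pytest

from matqg import sort_and_validate


def random_pedigree(rng, n_founders=20, n_extra=80, p_unknown=0.1):
    """Random valid pedigree with loops and inbreeding: each non-founder
    picks its parents among earlier animals (occasionally unknown)."""
    rows = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for i in range(n_extra):
        if rng.random() < p_unknown:
            s = "0"
        else:
            s = ids[int(rng.integers(len(ids)))]
        if rng.random() < p_unknown:
            d = "0"
        else:
            d = ids[int(rng.integers(len(ids)))]
            if d == s:
                d = "0"
        a = f"X{i}"
        rows.append((a, s, d))
        ids.append(a)
    return sort_and_validate(rows)


@pytest.fixture
def trio_pedigree():
    return sort_and_validate([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture
def fullsib_pedigree():
    """Two founders, two full sibs, and their (inbred) offspring."""
    return sort_and_validate(
        [
            ("s", "0", "0"),
            ("d", "0", "0"),
            ("a", "s", "d"),
            ("b", "s", "d"),
            ("o", "a", "b"),
        ]
    )


def naive_relationship(ped):
    """Independent tabular oracle: memoized recursive additive relationship."""
    sire, dam = ped.sire_idx, ped.dam_idx
    memo = {}

    def a(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            val = 1.0 + 0.5 * a(sire[i], dam[i])
        else:
            val = 0.5 * (a(sire[j], i) + a(dam[j], i))
        memo[(i, j)] = val
        return val

    n = ped.n
    A = np.array([[a(i, j) for j in range(n)] for i in range(n)])
    return A
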
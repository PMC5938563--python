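"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: relationship
coefficients come from Wright's path counting over explicitly enumerated
ancestry paths, link counts from a double loop over all pairs, and exact
test p-values from exhaustive enumeration in rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np


# -- Wright path-counting relationship -----------------------------------------


def _ascending_paths(i: str, parents: dict[str, tuple[str | None, str | None]]) -> list[list[str]]:
    """All paths i -> ancestor following parent links (including the trivial [i])."""
    paths = [[i]]
    for p in parents[i]:
        if p is not None:
            paths += [[i] + rest for rest in _ascending_paths(p, parents)]
    return paths


def path_inbreeding(i: str, parents) -> Fraction:
    s, d = parents[i]
    if s is None or d is None:
        return Fraction(0)
    return path_relationship(s, d, parents) / 2


def path_relationship(i: str, j: str, parents) -> Fraction:
    """Numerator relationship A(i, j) by summing (1/2)^links * (1 + F_anc)
    over all pairs of ascending paths that meet only at their common
    ancestor (Wright's rules)."""
    if i == j:
        return 1 + path_inbreeding(i, parents)
    total = Fraction(0)
    for p1 in _ascending_paths(i, parents):
        for p2 in _ascending_paths(j, parents):
            if p1[-1] != p2[-1]:
                continue
            anc = p1[-1]
            if set(p1[:-1]) & set(p2[:-1]):
                continue  # paths must be disjoint apart from the ancestor
            links = (len(p1) - 1) + (len(p2) - 1)
            total += Fraction(1, 2**links) * (1 + path_inbreeding(anc, parents))
    return total


def path_relationship_matrix(ped) -> np.ndarray:
    parents = {}
    for _, row in ped.table.iterrows():
        parents[row["id"]] = (
            row["sire"] if isinstance(row["sire"], str) else None,
            row["dam"] if isinstance(row["dam"], str) else None,
        )
    ids = ped.ids
    A = np.zeros((len(ids), len(ids)))
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            A[a, b] = float(path_relationship(i, j, parents))
    return A


# -- pairwise link classification ----------------------------------------------


def brute_force_links(ped) -> tuple[int, int, int, int]:
    """(mother_offspring, father_offspring, full_sib, half_sib) by looping
    over every individual and unordered pair."""
    t = ped.table
    recs = [
        (row["sire"] if isinstance(row["sire"], str) else None,
         row["dam"] if isinstance(row["dam"], str) else None)
        for _, row in t.iterrows()
    ]
    mo = sum(1 for s, d in recs if d is not None)
    fo = sum(1 for s, d in recs if s is not None)
    full = half = 0
    for (s1, d1), (s2, d2) in itertools.combinations(recs, 2):
        shared = sum(
            1
            for a, b in ((s1, s2), (d1, d2))
            if a is not None and b is not None and a == b
        )
        if shared == 2:
            full += 1
        elif shared == 1:
            half += 1
    return mo, fo, full, half


# -- exact tests in rational arithmetic ----------------------------------------


def multinomial_pmf_fraction(counts, probs: tuple[Fraction, ...]) -> Fraction:
    n = sum(counts)
    coef = factorial(n)
    for c in counts:
        coef //= factorial(c)
    p = Fraction(coef)
    for c, pr in zip(counts, probs):
        if c and pr == 0:
            return Fraction(0)
        p *= pr**c
    return p


def exact_multinomial_p(observed, probs: tuple[Fraction, ...]) -> Fraction:
    """Exhaustive-enumeration exact multinomial p-value (ties included)."""
    n = sum(observed)
    p_obs = multinomial_pmf_fraction(observed, probs)
    if p_obs == 0:
        return Fraction(0)
    total = Fraction(0)
    for a in range(n + 1):
        for b in range(n - a + 1):
            out = (a, b, n - a - b)
            p = multinomial_pmf_fraction(out, probs)
            if p <= p_obs:
                total += p
    return total


def fisher_exact_p(table: np.ndarray) -> Fraction:
    """Two-sided conditional (hypergeometric) p for a 2x2 table, summing all
    tables with the same margins whose probability is <= the observed one."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    return sum(
        (prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(x) <= p_obs),
        Fraction(0),
    )
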
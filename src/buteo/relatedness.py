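"""Additive genetic relationship matrix A and its sparse inverse.

A(i, j) is the expected proportion of alleles shared identical by descent
(parent-offspring 0.5, half sibs 0.25, self 1 + inbreeding coefficient).
A is built by the tabular recurrence over a topological order; its inverse
is assembled directly from pedigree structure by Henderson's rules with
inbreeding-corrected Mendelian-sampling variances, so it stays sparse even
when A itself is dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree

__all__ = ["RelationshipMatrix", "additive_matrix", "inverse_additive"]


@dataclass
class RelationshipMatrix:
    """A (dense) and optionally A^-1 (sparse CSC) over ``order``.

    ``mendelian_variance`` holds the per-individual Mendelian-sampling
    variance d_i (relative to V_A): 1 for founders, 0.75 with one known
    non-inbred parent, 0.5 with two; inbreeding of the parents shrinks it.
    """

    order: list[str]
    A: np.ndarray
    A_inv: sp.csc_matrix | None = None
    mendelian_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0


def _parent_arrays(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    sidx, didx = ped.parent_indices()
    return np.asarray(sidx), np.asarray(didx)


def additive_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method A over the pedigree's topological order.

    For individual i with parents s, d (earlier in the order):
    A(i, j) = (A(s, j) + A(d, j)) / 2 for j < i, A(i, i) = 1 + A(s, d) / 2;
    an unknown parent contributes nothing.
    """
    n = len(ped)
    sidx, didx = _parent_arrays(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            aii = 1.0
        else:
            row = 0.0
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return RelationshipMatrix(order=list(ped.ids), A=A)


def mendelian_sampling_variances(ped: Pedigree, A: np.ndarray) -> np.ndarray:
    """d_i = Var(a_i - parental average)/V_A, corrected for parental inbreeding."""
    sidx, didx = _parent_arrays(ped)
    diag = np.diag(A)
    d = np.ones(len(ped))
    both = (sidx >= 0) & (didx >= 0)
    d[both] = 1.0 - 0.25 * (diag[sidx[both]] + diag[didx[both]])
    one = (sidx >= 0) ^ (didx >= 0)
    pidx = np.where(sidx >= 0, sidx, didx)
    d[one] = 1.0 - 0.25 * diag[pidx[one]]
    return d


def inverse_additive(ped: Pedigree) -> RelationshipMatrix:
    """A with its sparse inverse assembled by Henderson's rules.

    Each individual i with known parents P (|P| in 0..2) contributes
    w = 1/d_i to (i,i), -w/2 to (i,p) and w/4 to (p,q) for p, q in P.
    """
    rel = additive_matrix(ped)
    d = mendelian_sampling_variances(ped, rel.A)
    sidx, didx = _parent_arrays(ped)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(len(ped)):
        w = 1.0 / d[i]
        parents = [p for p in (sidx[i], didx[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(w)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * w, -0.5 * w]
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * w)
    n = len(ped)
    rel.A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    rel.mendelian_variance = d
    return rel
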
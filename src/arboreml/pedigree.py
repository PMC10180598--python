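"""Pedigrees and the numerator relationship matrix A.

Open-pollinated progeny trials record one known parent (the dam) per
offspring; sires are unknown and treated as unrelated, non-inbred
founders, so maternal sibs are half-sibs with expected additive
relatedness 0.25.  ``build_A`` implements the standard tabular
recursion, valid for arbitrary (sorted) pedigrees:

    A[j, i] = 0.5 * (A[i, dam(j)] + A[i, sire(j)])   (i earlier than j)
    A[j, j] = 1 + 0.5 * A[dam(j), sire(j)]

with missing-parent terms zero.  Inbreeding coefficients are
``f_i = A_ii - 1``.  ``KinshipMatrix.a_inverse`` gives the sparse
inverse from the Henderson/Quaas decomposition ``A = T D T'``, which the
mixed-model equations consume directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Pedigree", "KinshipMatrix", "sort_pedigree", "build_A"]

#: tokens accepted as "parent unknown" in pedigree files
UNKNOWN_TOKENS = {"", "0", "NA", ".", "None", "nan"}


def _clean_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """Ordered pedigree: ``ids[i]`` has parents ``dams[i]``/``sires[i]``
    (``None`` for unknown).  After :func:`sort_pedigree` every parent
    precedes its offspring."""

    ids: list
    dams: list
    sires: list

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Series(self.ids).value_counts()
            raise ValueError(f"duplicate individual id(s): {list(dup[dup > 1].index)[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns ``id``, ``dam``, ``sire``
        (empty/0/NA for unknown parents).  Parents named but not listed
        as individuals are prepended as founders."""
        ids = [str(v) for v in frame["id"]]
        dams = [_clean_parent(v) for v in frame["dam"]]
        sires = [_clean_parent(v) for v in frame["sire"]]
        known = set(ids)
        extra = []
        for p in dams + sires:
            if p is not None and p not in known:
                known.add(p)
                extra.append(p)
        if extra:
            ids = extra + ids
            dams = [None] * len(extra) + dams
            sires = [None] * len(extra) + sires
        return cls(ids=ids, dams=dams, sires=sires)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": ["" if d is None else d for d in self.dams],
                "sire": ["" if s is None else s for s in self.sires],
            }
        )


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so parents precede offspring (stable for ties).

    Raises ``ValueError`` naming the offending individuals if the parent
    links contain a cycle (including self-parenting).
    """
    index = {v: i for i, v in enumerate(ped.ids)}
    n = len(ped)
    children: list[list[int]] = [[] for _ in range(n)]
    n_parents = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (ped.dams[i], ped.sires[i]):
            if p is not None:
                j = index[p]
                if j == i:
                    raise ValueError(f"pedigree cycle: {ped.ids[i]} is its own parent")
                children[j].append(i)
                n_parents[i] += 1
    order: list[int] = []
    ready = [i for i in range(n) if n_parents[i] == 0]
    remaining = n_parents.copy()
    while ready:
        nxt: list[int] = []
        for i in ready:
            order.append(i)
            for c in children[i]:
                remaining[c] -= 1
                if remaining[c] == 0:
                    nxt.append(c)
        ready = sorted(nxt)
    if len(order) != n:
        cyc = [ped.ids[i] for i in range(n) if remaining[i] > 0]
        raise ValueError(f"pedigree cycle involving: {cyc}")
    return Pedigree(
        ids=[ped.ids[i] for i in order],
        dams=[ped.dams[i] for i in order],
        sires=[ped.sires[i] for i in order],
    )


@dataclass
class KinshipMatrix:
    """Numerator relationship matrix over a sorted pedigree."""

    ids: list
    A: np.ndarray
    f: np.ndarray  # inbreeding coefficients, A_ii - 1

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[str(v)] for v in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"individual {err} not in pedigree") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.A[np.ix_(idx, idx)]

    def a_inverse(self, ped: Pedigree) -> sp.csr_matrix:
        """Sparse inverse of A via A = T D T' (Henderson/Quaas rules,
        inbreeding-aware through the tabular diagonal)."""
        n = len(self.ids)
        index = {v: i for i, v in enumerate(self.ids)}
        rows, cols, vals = [], [], []
        d = np.empty(n)
        for j in range(n):
            dam = ped.dams[j]
            sire = ped.sires[j]
            di = index[dam] if dam is not None else None
            si = index[sire] if sire is not None else None
            var = 1.0
            if di is not None:
                var -= 0.25 * (1.0 + self.f[di])
            if si is not None:
                var -= 0.25 * (1.0 + self.f[si])
            d[j] = var
            rows.append(j)
            cols.append(j)
            vals.append(1.0)
            for pi in (di, si):
                if pi is not None:
                    rows.append(j)
                    cols.append(pi)
                    vals.append(-0.5)
        Tinv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        Dinv = sp.diags(1.0 / d)
        return (Tinv.T @ Dinv @ Tinv).tocsr()

    def to_coordinate_frame(self, tol: float = 0.0) -> pd.DataFrame:
        """Lower-triangle coordinate export (id_i, id_j, a_ij) for audit."""
        ii, jj = np.tril_indices(len(self.ids))
        vals = self.A[ii, jj]
        keep = np.abs(vals) > tol
        return pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in ii[keep]],
                "id_j": [self.ids[j] for j in jj[keep]],
                "a": vals[keep],
            }
        )


def build_A(ped: Pedigree, *, assume_sorted: bool = False) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    The pedigree is topologically sorted first unless ``assume_sorted``;
    unknown parents contribute nothing (unrelated founders).
    """
    if not assume_sorted:
        ped = sort_pedigree(ped)
    n = len(ped)
    index = {v: i for i, v in enumerate(ped.ids)}
    A = np.zeros((n, n))
    for j in range(n):
        di = index[ped.dams[j]] if ped.dams[j] is not None else None
        si = index[ped.sires[j]] if ped.sires[j] is not None else None
        if j > 0:
            col = np.zeros(j)
            if di is not None:
                col += 0.5 * A[:j, di]
            if si is not None:
                col += 0.5 * A[:j, si]
            A[:j, j] = col
            A[j, :j] = col
        A[j, j] = 1.0 + (0.5 * A[di, si] if di is not None and si is not None else 0.0)
    return KinshipMatrix(ids=list(ped.ids), A=A, f=np.diag(A) - 1.0)
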
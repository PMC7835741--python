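"""Numerator relationship matrix machinery for the single-step model.

The additive (numerator) relationship matrix ``A`` describes expected
identity-by-descent sharing among pedigreed animals.  Single-step GBLUP
needs three derived objects: the sparse inverse ``A``:sup:`-1` (assembled
directly by Henderson's rules, with inbreeding from the Meuwissen & Luo
algorithm), the block ``A22`` of the genotyped animals, and its inverse.

Unknown parents are treated as unrelated, non-inbred founders; no genetic
groups are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

_MISSING_PARENT_TOKENS = {"", "0", "0.0", "NA", "NAN", "NONE", ".", "*"}


def _is_unknown(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip().upper() in _MISSING_PARENT_TOKENS


@dataclass
class Pedigree:
    """A topologically ordered pedigree (parents precede offspring).

    ``sire`` and ``dam`` hold integer positions into ``ids`` or
    :data:`UNKNOWN` (-1) for founders / unknown parents.  ``meta`` carries
    per-animal covariates (sex, birth_year, farm, generation, ...) aligned
    with ``ids``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, animal_ids) -> np.ndarray:
        """Map animal identifiers to row positions in pedigree order."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from exc

    def to_frame(self) -> pd.DataFrame:
        sire_ids = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "0")
        dam_ids = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "0")
        out = pd.DataFrame({"id": self.ids, "sire": sire_ids, "dam": dam_ids})
        for col in self.meta.columns:
            out[col] = np.asarray(self.meta[col])
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        id_col: str = "id",
        sire_col: str = "sire",
        dam_col: str = "dam",
    ) -> "Pedigree":
        """Build a pedigree from a table, reordering parents before offspring.

        Raises on duplicate ids, on a parent id that never appears as an
        animal row, and on pedigree cycles (an animal its own ancestor).
        """
        ids = [str(v).strip() for v in frame[id_col]]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal ids in pedigree")
        idx = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        for arr, col in ((sire, sire_col), (dam, dam_col)):
            for i, raw in enumerate(frame[col]):
                if _is_unknown(raw):
                    continue
                key = str(raw).strip()
                if key not in idx:
                    raise ValueError(
                        f"parent {key!r} of animal {ids[i]!r} has no pedigree record"
                    )
                arr[i] = idx[key]

        order = _topological_order(sire, dam)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = np.arange(n)
        new_sire = np.where(sire[order] >= 0, rank[np.maximum(sire[order], 0)], UNKNOWN)
        new_dam = np.where(dam[order] >= 0, rank[np.maximum(dam[order], 0)], UNKNOWN)
        meta_cols = [c for c in frame.columns if c not in (id_col, sire_col, dam_col)]
        meta = frame.iloc[order][meta_cols].reset_index(drop=True)
        return cls(
            ids=np.asarray(ids, dtype=object)[order],
            sire=new_sire.astype(np.int64),
            dam=new_dam.astype(np.int64),
            meta=meta,
        )


def _topological_order(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn's algorithm over parent->offspring edges; detects cycles."""
    n = len(sire)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                indeg[i] += 1
                children[p].append(i)
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        nxt: list[int] = []
        for i in queue:
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != n:
        raise ValueError("pedigree contains a cycle (animal is its own ancestor)")
    return np.asarray(order, dtype=np.int64)


def mendelian_variances(ped: Pedigree, inbreeding_coef: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variances d_i used by Henderson's rules.

    d_i = 0.5 - 0.25(F_s + F_d) with both parents known, 0.75 - 0.25 F_p with
    one, and 1 with none.
    """
    F = inbreeding(ped) if inbreeding_coef is None else inbreeding_coef
    d = np.ones(ped.n)
    for i in range(ped.n):
        s, m = ped.sire[i], ped.dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0 or m >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, m)]
    return d


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the diagonal a_ii = sum_k L_ik^2 d_k is accumulated by
    propagating path coefficients backwards through its ancestors; F_i is
    then a_ii - 1.  Founders (any unknown parent) get F = 0 by convention.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0 or m >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, m)]
        else:
            d[i] = 1.0
        if s < 0 or m < 0:
            continue  # F stays 0
        coef = np.zeros(i + 1)
        coef[i] = 1.0
        a_ii = 0.0
        for k in range(i, -1, -1):
            lk = coef[k]
            if lk == 0.0:
                continue
            a_ii += lk * lk * d[k]
            if sire[k] >= 0:
                coef[sire[k]] += 0.5 * lk
            if dam[k] >= 0:
                coef[dam[k]] += 0.5 * lk
        F[i] = a_ii - 1.0
    return F


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{s(i)j} + a_{d(i)j}) for j < i; a_ii = 1 + 0.5 a_{s(i)d(i)}.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if m >= 0:
            row += 0.5 * A[m, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, m] if (s >= 0 and m >= 0) else 0.0)
    return A


def build_A_inverse(ped: Pedigree, ignore_inbreeding: bool = False) -> sp.csr_matrix:
    """Sparse A^-1 assembled directly by Henderson's rules.

    Inbreeding enters through the Mendelian sampling variances (Meuwissen &
    Luo F); ``ignore_inbreeding=True`` reproduces the classical rules with
    d in {1, 0.75, 0.5} and exists for testing only.
    """
    n = ped.n
    if ignore_inbreeding:
        F = np.zeros(n)
        d = mendelian_variances(ped, F)
    else:
        d = mendelian_variances(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
            for q in parents:
                add(p, q, 0.25 * alpha)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def subset_A22(A: np.ndarray, genotyped_positions) -> tuple[np.ndarray, np.ndarray]:
    """Principal submatrix of A for the genotyped animals and its inverse.

    ``genotyped_positions`` are row positions in pedigree order, given in the
    genotype-file animal order; the returned block follows that order.
    """
    idx = np.asarray(genotyped_positions, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("no genotyped animals given")
    if idx.min() < 0 or idx.max() >= A.shape[0]:
        raise IndexError("genotyped position outside pedigree")
    A22 = A[np.ix_(idx, idx)]
    A22_inv = np.linalg.inv(A22)
    A22_inv = 0.5 * (A22_inv + A22_inv.T)
    return A22, A22_inv


def write_coo(matrix, path) -> None:
    """Dump a (sparse or dense) relationship matrix in i j value text form."""
    coo = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
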
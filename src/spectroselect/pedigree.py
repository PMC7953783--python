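"""Pedigree handling and the numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` contains the expected
additive-genetic relationships among all animals in a pedigree; its diagonal
is ``1 + F`` where ``F`` is the inbreeding coefficient.  The animal model
assumes breeding values distributed ``u ~ N(0, G ⊗ A)``, so both ``A`` (for
simulation) and its sparse inverse (for the mixed-model equations) are needed.

Unknown parents are treated as unrelated, non-inbred founders; no genetic
groups are fitted.  Identifiers may be arbitrary strings or integers; they are
mapped to dense 0-based indices internally and the mapping is kept on the
:class:`PedigreeTable`.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeTable",
    "RelationshipMatrix",
    "PedigreeCycleError",
    "sort_pedigree",
    "build_A",
    "build_A_inverse",
    "inbreeding_coefficients",
    "kinship",
    "read_pedigree",
    "write_pedigree",
    "write_relationship_coo",
]

#: sentinel strings accepted as "parent unknown" in pedigree files
MISSING_TOKENS = {"", "0", "NA", "na", ".", "None", "nan"}


class PedigreeCycleError(ValueError):
    """Raised when an animal is (transitively) its own ancestor."""


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree: parents always precede offspring.

    Attributes
    ----------
    ids : list
        Animal identifiers in sorted order.
    sire, dam : ndarray of int
        Index of each animal's sire/dam within ``ids``; ``-1`` when unknown.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        sire = [str(ids[s]) if s >= 0 else "0" for s in self.sire]
        dam = [str(ids[d]) if d >= 0 else "0" for d in self.dam]
        return pd.DataFrame({"animal": [str(a) for a in ids], "sire": sire, "dam": dam})


def _normalize(records) -> list[tuple]:
    out = []
    for animal, sire, dam in records:
        sire = None if sire is None or str(sire) in MISSING_TOKENS else sire
        dam = None if dam is None or str(dam) in MISSING_TOKENS else dam
        out.append((animal, sire, dam))
    return out


def sort_pedigree(records) -> PedigreeTable:
    """Topologically sort pedigree records so parents precede offspring.

    Parents appearing only in the sire/dam columns are added as founder
    records.  An already-sorted pedigree passes through with its order intact.
    Raises :class:`PedigreeCycleError` naming an animal on the cycle if the
    parentage graph is cyclic.
    """
    if isinstance(records, PedigreeTable):
        records = records.to_frame()
    if isinstance(records, pd.DataFrame):
        records = list(records.itertuples(index=False, name=None))
    recs = _normalize(records)
    parents: dict = {}
    for animal, sire, dam in recs:
        if animal in parents:
            raise ValueError(f"duplicate pedigree record for animal {animal!r}")
        parents[animal] = (sire, dam)
    for animal in list(parents):
        for p in parents[animal]:
            if p is not None and p not in parents:
                parents[p] = (None, None)

    pos = {a: i for i, a in enumerate(parents)}
    children: dict = {a: [] for a in parents}
    n_unmet = {}
    for a, ps in parents.items():
        known = set(ps) - {None}
        n_unmet[a] = len(known)
        for p in known:
            children[p].append(a)

    # Kahn's algorithm; the heap keeps output order as close to input as possible
    ready = [pos[a] for a, k in n_unmet.items() if k == 0]
    heapq.heapify(ready)
    names = list(parents)
    order: list = []
    while ready:
        a = names[heapq.heappop(ready)]
        order.append(a)
        for c in children[a]:
            n_unmet[c] -= 1
            if n_unmet[c] == 0:
                heapq.heappush(ready, pos[c])
    if len(order) != len(parents):
        stuck = min((a for a, k in n_unmet.items() if k > 0), key=pos.get)
        raise PedigreeCycleError(
            f"pedigree contains a parentage cycle involving animal {stuck!r}"
        )
    idx = {a: i for i, a in enumerate(order)}
    sire = np.array(
        [idx[parents[a][0]] if parents[a][0] is not None else -1 for a in order],
        dtype=np.int64,
    )
    dam = np.array(
        [idx[parents[a][1]] if parents[a][1] is not None else -1 for a in order],
        dtype=np.int64,
    )
    return PedigreeTable(ids=order, sire=sire, dam=dam)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with inbreeding and sparse inverse."""

    ids: list
    A: np.ndarray | None
    F: np.ndarray
    A_inv: sparse.csr_matrix | None = None
    #: log-determinant of A (from A = T D T': log|A| = Σ log d_i)
    logdet: float | None = None


def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Dense A by the tabular method.

    ``a_ij = ½(a_i,s(j) + a_i,d(j))`` for ``i < j`` and
    ``a_jj = 1 + ½ a_s(j),d(j)``; unknown parents contribute zero.
    Quadratic in pedigree size — intended for pedigrees up to a few thousand.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s, d = pedigree.sire, pedigree.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj >= 0:
            row += 0.5 * A[:j, sj]
        if dj >= 0:
            row += 0.5 * A[:j, dj]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if (sj >= 0 and dj >= 0) else 0.0)
    return RelationshipMatrix(ids=list(pedigree.ids), A=A, F=np.diag(A).copy() - 1.0)


def kinship(pedigree: PedigreeTable, i: int, j: int, _memo: dict | None = None) -> float:
    """Kinship (coancestry) coefficient φ between animals ``i`` and ``j``.

    ``a_ij = 2 φ_ij`` and ``F_offspring = φ(sire, dam)``.  Iterative
    evaluation of the standard recurrence with memoization, so arbitrarily
    deep pedigrees do not hit the interpreter recursion limit.
    """
    memo = _memo if _memo is not None else {}
    s, d = pedigree.sire, pedigree.dam

    def key(a, b):
        return (a, b) if a <= b else (b, a)

    stack = [key(i, j)]
    while stack:
        a, b = stack[-1]
        if (a, b) in memo:
            stack.pop()
            continue
        if a < 0 or b < 0:
            memo[(a, b)] = 0.0
            stack.pop()
            continue
        if a == b:
            dep = key(s[a], d[a])
            if dep in memo:
                memo[(a, b)] = 0.5 * (1.0 + memo[dep])
                stack.pop()
            else:
                stack.append(dep)
            continue
        # b is the younger animal (larger index in sorted order)
        deps = [key(a, s[b]), key(a, d[b])]
        missing = [k for k in deps if k not in memo]
        if missing:
            stack.extend(missing)
        else:
            memo[(a, b)] = 0.5 * (memo[deps[0]] + memo[deps[1]])
            stack.pop()
    return memo[key(i, j)]


def inbreeding_coefficients(pedigree: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients: ``F_i = φ(sire_i, dam_i)``, 0 when a parent
    is unknown.  One shared memo across animals keeps the cost near-linear
    for shallow pedigrees."""
    n = len(pedigree)
    F = np.zeros(n)
    memo: dict = {}
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        if s[i] >= 0 and d[i] >= 0:
            F[i] = kinship(pedigree, int(s[i]), int(d[i]), memo)
    return F


def _mendelian_d(pedigree: PedigreeTable, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance coefficients d_i."""
    n = len(pedigree)
    s, d = pedigree.sire, pedigree.dam
    out = np.empty(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            out[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            out[i] = 0.75 - 0.25 * F[max(si, di)]
        else:
            out[i] = 1.0
    return out


def build_A_inverse(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Uses ``A = T D T'`` so that ``A⁻¹ = (T⁻¹)' D⁻¹ T⁻¹`` where ``T⁻¹`` has 1
    on the diagonal and −½ at each animal's known parents; ``d_i`` accounts
    for parental inbreeding.  Also returns ``log|A| = Σ log d_i``, needed by
    the restricted likelihood.
    """
    n = len(pedigree)
    F = inbreeding_coefficients(pedigree)
    dvec = _mendelian_d(pedigree, F)
    rows, cols, vals = [], [], []
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        inv_d = 1.0 / dvec[i]
        entries = [(i, 1.0)]
        for p in (s[i], d[i]):
            if p >= 0:
                entries.append((int(p), -0.5))
        for a, va in entries:
            for b, vb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(inv_d * va * vb)
    A_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(
        ids=list(pedigree.ids),
        A=None,
        F=F,
        A_inv=A_inv,
        logdet=float(np.sum(np.log(dvec))),
    )


def read_pedigree(path) -> PedigreeTable:
    """Read a 3-column TSV (animal, sire, dam; 0/NA = unknown) and sort it."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return sort_pedigree(df[list(df.columns[:3])])


def write_pedigree(pedigree: PedigreeTable, path) -> None:
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


def write_relationship_coo(rel: RelationshipMatrix, matrix_path, idmap_path) -> None:
    """Write A or A⁻¹ as (i, j, value) text plus the id-index mapping."""
    if rel.A_inv is not None:
        coo = rel.A_inv.tocoo()
        rows, cols, vals = coo.row, coo.col, coo.data
    else:
        rows, cols = np.nonzero(rel.A)
        vals = rel.A[rows, cols]
    pd.DataFrame({"i": rows, "j": cols, "value": vals}).to_csv(matrix_path, index=False)
    pd.DataFrame({"index": np.arange(len(rel.ids)), "id": [str(i) for i in rel.ids]}).to_csv(
        idmap_path, index=False
    )
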
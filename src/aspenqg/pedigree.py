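"""Pedigrees and the numerator (additive) relationship matrix.

The additive genetic covariance between trees in a progeny trial is
``A * sigma_A^2`` where ``A`` is the numerator relationship matrix: twice the
kinship matrix, built recursively from the pedigree.  This module builds
validated, topologically ordered pedigrees from (individual, sire, dam)
records, computes ``A`` by the tabular method, and assembles its sparse
inverse directly from pedigree rules (Henderson's rules with the inbreeding
adjustment), which is what the mixed-model equations actually consume.

Polymix (open-pollinated) sires are coded as unknown, so offspring of the
same dam are half sibs with ``a = 0.25``.  Ramets of a clone are a single
genotype here; the tree-to-genotype incidence lives in the model design
matrices, keeping ``A`` non-singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

#: sentinel values accepted for an unknown parent in input records
UNKNOWN_SENTINELS = {None, "", "0", 0, "NA", "na", ".", "unknown"}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle (an individual is its own ancestor)."""


class UnknownParentError(PedigreeError):
    """A parent is referenced but never declared and is not the unknown sentinel."""


def _norm_parent(p) -> Optional[str]:
    if p in UNKNOWN_SENTINELS:
        return None
    if isinstance(p, float) and np.isnan(p):
        return None
    return str(p)


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree.

    ``ids[i]`` is the i-th genotype; ``sire[i]``/``dam[i]`` are indices into
    ``ids`` or -1 for an unknown parent.  Parents always precede offspring.
    """

    ids: Tuple[str, ...]
    sire: np.ndarray  # int64, -1 = unknown
    dam: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, genotype: str) -> int:
        return self._index[genotype]

    @property
    def founders(self) -> List[str]:
        return [g for i, g in enumerate(self.ids) if self.sire[i] < 0 and self.dam[i] < 0]

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient per individual (diagonal of A minus one)."""
        return np.diag(additive_relationship(self)) - 1.0

    def subset_positions(self, genotypes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genotypes], dtype=np.int64)


@dataclass(frozen=True)
class CloneMap:
    """Tree (ramet) to genotype mapping; every tree maps to exactly one genotype."""

    tree_to_genotype: Mapping[str, str]

    def __post_init__(self):
        groups: Dict[str, List[str]] = {}
        for t, g in self.tree_to_genotype.items():
            groups.setdefault(g, []).append(t)
        object.__setattr__(self, "genotype_to_trees", groups)

    def genotype_of(self, tree: str) -> str:
        return self.tree_to_genotype[tree]

    def __len__(self) -> int:
        return len(self.tree_to_genotype)


def build_pedigree(records: Sequence[Tuple[str, object, object]]) -> Pedigree:
    """Build a topologically ordered :class:`Pedigree` from records.

    Parameters
    ----------
    records:
        Iterable of ``(individual, sire, dam)``.  Parents may be listed after
        their offspring; unknown parents use any of the accepted sentinels
        (``None``, empty string, ``"0"``, ``"NA"``).  Parents that are never
        declared as individuals raise :class:`UnknownParentError`; cycles
        (including self-parenting) raise :class:`CycleError`.
    """
    decl: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    order_seen: Dict[str, int] = {}
    for rec in records:
        ind, s, d = str(rec[0]), _norm_parent(rec[1]), _norm_parent(rec[2])
        if not ind or ind in UNKNOWN_SENTINELS:
            raise PedigreeError(f"empty or sentinel individual id: {rec!r}")
        if ind in decl:
            raise PedigreeError(f"duplicate individual id: {ind}")
        decl[ind] = (s, d)
        order_seen[ind] = len(order_seen)
    for ind, (s, d) in decl.items():
        for p in (s, d):
            if p is not None and p not in decl:
                raise UnknownParentError(f"parent {p!r} of {ind!r} is never declared")

    # Kahn topological sort; ties broken by input order for determinism.
    children: Dict[str, List[str]] = {g: [] for g in decl}
    missing_parents: Dict[str, int] = {}
    for ind, (s, d) in decl.items():
        distinct = {p for p in (s, d) if p is not None}
        for p in distinct:
            children[p].append(ind)
        missing_parents[ind] = len(distinct)
    import heapq

    ready = [(order_seen[g], g) for g, n in missing_parents.items() if n == 0]
    heapq.heapify(ready)
    ordered: List[str] = []
    remaining = dict(missing_parents)
    while ready:
        _, g = heapq.heappop(ready)
        ordered.append(g)
        for ch in children[g]:
            remaining[ch] -= 1
            if remaining[ch] == 0:
                heapq.heappush(ready, (order_seen[ch], ch))
    if len(ordered) != len(decl):
        cyclic = sorted(set(decl) - set(ordered))
        raise CycleError(f"pedigree contains a cycle involving: {cyclic[:5]}")

    idx = {g: i for i, g in enumerate(ordered)}
    sire = np.full(len(ordered), -1, dtype=np.int64)
    dam = np.full(len(ordered), -1, dtype=np.int64)
    for g, i in idx.items():
        s, d = decl[g]
        if s is not None:
            sire[i] = idx[s]
        if d is not None:
            dam[i] = idx[d]
    return Pedigree(tuple(ordered), sire, dam)


def additive_relationship(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix ``A`` by the tabular (recursive) method.

    ``a(i,i) = 1 + a(sire_i, dam_i)/2`` and ``a(i,j) = (a(j,sire_i) +
    a(j,dam_i))/2`` for ``j`` preceding ``i``; unknown parents contribute 0.
    Dense, O(n^2) memory; intended for the genotype-level pedigrees of a
    progeny trial (hundreds to a few thousand individuals).
    """
    n = len(pedigree)
    s, d = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s[i] >= 0 and d[i] >= 0:
            aii += 0.5 * A[s[i], d[i]]
        A[i, i] = aii
    return A


def additive_relationship_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse ``A^{-1}`` built directly from pedigree rules.

    Uses the Mendelian-sampling variances ``d_i`` with the inbreeding
    adjustment: ``d_i = 1 - (a(s,s) + a(d,d))/4`` where an unknown parent
    contributes 0, i.e. 1, 3/4 or 1/2 minus a quarter of each known parent's
    inbreeding coefficient.  Satisfies ``A @ A^{-1} = I`` to numerical
    tolerance.
    """
    n = len(pedigree)
    s, d = pedigree.sire, pedigree.dam
    diagA = np.diag(additive_relationship(pedigree))  # 1 + F
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    for i in range(n):
        parents = [p for p in (s[i], d[i]) if p >= 0]
        di = 1.0 - 0.25 * sum(diagA[p] for p in parents)
        if di <= 0:
            raise PedigreeError(f"non-positive Mendelian-sampling variance at {pedigree.ids[i]}")
        alpha = 1.0 / di
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def logdet_A(pedigree: Pedigree) -> float:
    """``log det A`` from the Mendelian-sampling variances (product of d_i)."""
    n = len(pedigree)
    s, d = pedigree.sire, pedigree.dam
    diagA = np.diag(additive_relationship(pedigree))
    out = 0.0
    for i in range(n):
        di = 1.0 - 0.25 * sum(diagA[p] for p in (s[i], d[i]) if p >= 0)
        out += np.log(di)
    return out


def merge_pedigree_records(
    *record_lists: Sequence[Tuple[str, object, object]]
) -> List[Tuple[str, object, object]]:
    """Concatenate pedigree record lists, deduplicating identical records.

    Conflicting duplicate ids (same individual, different parents) raise
    :class:`PedigreeError`.  Used to join per-trial pedigrees that share
    founders for cross-site (type-B) analyses.
    """
    seen: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    out: List[Tuple[str, object, object]] = []
    for records in record_lists:
        for rec in records:
            ind = str(rec[0])
            parents = (_norm_parent(rec[1]), _norm_parent(rec[2]))
            if ind in seen:
                if seen[ind] != parents:
                    raise PedigreeError(f"conflicting duplicate pedigree record for {ind}")
                continue
            seen[ind] = parents
            out.append(rec)
    return out
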
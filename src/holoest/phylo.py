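"""Desk-scale protein phylogeny: progressive alignment, block curation,
p-distances and neighbor joining.

The chain mirrors the classic Clustal/Gblocks/tree workflow at laptop
scale: a UPGMA guide tree from pairwise identities drives profile-profile
dynamic programming with affine gaps (BLOSUM62); curation keeps maximal
runs of low-gap, conserved columns; distances are p-distances over shared
ungapped columns (optionally Poisson-corrected, -ln(1-p)); neighbor joining
(Saitou-Nei) builds the unrooted tree, which is exact on additive matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import clustering


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("all alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class CurationParams:
    max_gap_fraction: float = 0.0
    min_conservation: float = 0.5
    min_block_length: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_gap_fraction <= 1.0 and 0.0 <= self.min_conservation <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")


_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet
_AA_INDEX = {c: i for i, c in enumerate(_ALPHA)}
_GAP_PAIR_SCORE = -1.0  # residue vs existing gap column contribution


def _col_profiles(rows: list[str]) -> np.ndarray:
    """(n_cols, alphabet+1) residue counts per column; last slot = gaps."""
    n = len(_ALPHA)
    prof = np.zeros((len(rows[0]), n + 1))
    for row in rows:
        for j, c in enumerate(row):
            prof[j, _AA_INDEX.get(c, _AA_INDEX["X"]) if c != "-" else n] += 1
    return prof


def _profile_scores(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Mean pairwise substitution score between every column pair."""
    n = len(_ALPHA)
    sub = np.asarray(_BLOSUM)
    ra, rb = pa[:, :n], pb[:, :n]
    ga, gb = pa[:, n], pb[:, n]
    na = ra.sum(axis=1) + ga
    nb = rb.sum(axis=1) + gb
    core = ra @ sub @ rb.T
    gap_pairs = np.outer(ga, rb.sum(axis=1)) + np.outer(ra.sum(axis=1), gb)
    return (core + _GAP_PAIR_SCORE * gap_pairs) / np.outer(na, nb)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Affine-gap (Gotoh) global alignment of two alignment blocks."""
    S = _profile_scores(_col_profiles(rows_a), _col_profiles(rows_b))
    la, lb = S.shape
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - gap_open - gap_extend,
            X[i - 1] - gap_extend,
        )
        # Y has an in-row dependency; fall back to a scalar loop
        for j in range(1, lb + 1):
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append("".join(r[j - 1] for r in rows_b))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append(gap_b)
            open_sc = max(M[i - 1, j], Y[i - 1, j]) - (gap_open + gap_extend)
            ext_sc = X[i - 1, j] - gap_extend
            if ext_sc >= open_sc:
                state = 1
            else:
                state = int(np.argmax([M[i - 1, j], NEG, Y[i - 1, j]]))
            i -= 1
        else:
            out_a.append(gap_a)
            out_b.append("".join(r[j - 1] for r in rows_b))
            open_sc = max(M[i, j - 1], X[i, j - 1]) - (gap_open + gap_extend)
            ext_sc = Y[i, j - 1] - gap_extend
            if ext_sc >= open_sc:
                state = 2
            else:
                state = int(np.argmax([M[i, j - 1], X[i, j - 1], NEG]))
            j -= 1
    cols_a = out_a[::-1]
    cols_b = out_b[::-1]
    new_a = ["".join(col[k] for col in cols_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in cols_b) for k in range(len(rows_b))]
    return new_a, new_b


def progressive_align(
    sequences: Sequence[tuple[str, str]],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Msa:
    """Progressive multiple alignment guided by a UPGMA tree of pairwise
    identity distances.  Deterministic for a fixed input order."""
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [s[0] for s in sequences]
    seqs = [s[1] for s in sequences]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - clustering.identity(seqs[i], seqs[j])
    Z = linkage(squareform(dist, checks=False), method="average")
    # each node: (member indices, gapped rows)
    nodes: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        mem_a, rows_a = nodes.pop(ia)
        mem_b, rows_b = nodes.pop(ib)
        if len(rows_a) == 1 and len(rows_b) == 1 and rows_a[0] == rows_b[0]:
            new_a, new_b = rows_a, rows_b  # identical pair stays gap-free
        else:
            new_a, new_b = _align_profiles(rows_a, rows_b, gap_open, gap_extend)
        nodes[n + k] = (mem_a + mem_b, new_a + new_b)
    members, rows = nodes.popitem()[1]
    ordered = sorted(zip(members, rows))
    return Msa(ids=[ids[m] for m, _ in ordered], rows=[r for _, r in ordered])


def curate_blocks(msa: Msa, params: CurationParams | None = None) -> tuple[Msa, list[int]]:
    """Keep maximal runs of acceptable columns, dropping runs shorter than
    ``min_block_length``.

    A column is acceptable when its gap fraction is <= max_gap_fraction and
    its most frequent non-gap residue covers >= min_conservation of the
    rows.  Returns the curated alignment and the kept column indices.
    """
    params = params or CurationParams()
    n_rows = len(msa.rows)
    ok = []
    for j in range(msa.n_cols):
        col = [r[j] for r in msa.rows]
        gaps = col.count("-")
        residues = [c for c in col if c != "-"]
        conserved = max((residues.count(c) for c in set(residues)), default=0)
        ok.append(
            gaps / n_rows <= params.max_gap_fraction
            and conserved / n_rows >= params.min_conservation
        )
    kept: list[int] = []
    run: list[int] = []
    for j, good in enumerate(ok + [False]):
        if good:
            run.append(j)
        else:
            if len(run) >= params.min_block_length:
                kept.extend(run)
            run = []
    if not kept:
        warnings.warn("no alignment columns survived curation", stacklevel=2)
        return Msa(ids=list(msa.ids), rows=["" for _ in msa.rows]), []
    rows = ["".join(r[j] for j in kept) for r in msa.rows]
    return Msa(ids=list(msa.ids), rows=rows), kept


def protein_distance(row_i: str, row_j: str, poisson: bool = False) -> float:
    """p-distance over columns where neither row is gapped; optional
    Poisson correction -ln(1-p)."""
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal (aligned) length")
    shared = [(a, b) for a, b in zip(row_i, row_j) if a != "-" and b != "-"]
    if not shared:
        raise ValueError("no shared ungapped columns between rows")
    p = sum(1 for a, b in shared if a != b) / len(shared)
    if not poisson:
        return p
    if p >= 1.0:
        raise ValueError("Poisson correction undefined at p = 1")
    return float(-np.log(1.0 - p))


def distance_matrix(msa: Msa, poisson: bool = False) -> DistanceMatrix:
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(msa.rows[i], msa.rows[j], poisson)
    return DistanceMatrix(d, ids=msa.ids)


def nj_tree(dm: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> TreeNode:
    """Neighbor-joining tree (negative branch lengths clamped to zero).

    Accepts a skbio DistanceMatrix or a symmetric array plus ids; raises on
    asymmetric input; needs n >= 3.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr, ids=list(ids) if ids is not None else None)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(dm, neg_as_zero=True)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller-side-agnostic subset of
    leaf names under each internal edge) of an unrooted tree."""
    leaves = frozenset(l.name for l in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=lambda s: (len(s), sorted(s))))
    return splits


def is_monophyletic_unrooted(tree: TreeNode, names: set[str]) -> bool:
    """True when an edge of the unrooted tree separates ``names`` from all
    other leaves (trivial one-leaf and all-leaf sets are monophyletic)."""
    leaves = frozenset(l.name for l in tree.tips())
    group = frozenset(names)
    if not group <= leaves:
        raise ValueError("names must be a subset of the tree's leaves")
    if len(group) in (1, len(leaves)):
        return True
    key = min(group, leaves - group, key=lambda s: (len(s), sorted(s)))
    return key in bipartitions(tree)


def bootstrap_support(
    msa: Msa,
    n_replicates: int = 100,
    seed: int = 0,
    poisson: bool = False,
) -> dict[frozenset[str], float]:
    """Nonparametric bootstrap over alignment columns: fraction of
    replicate NJ trees containing each bipartition of the full-data tree."""
    rng = np.random.default_rng(seed)
    base = bipartitions(nj_tree(distance_matrix(msa, poisson)))
    counts = {b: 0 for b in base}
    n_cols = msa.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(r[j] for j in cols) for r in msa.rows]
        try:
            rep = bipartitions(nj_tree(distance_matrix(Msa(ids=list(msa.ids), rows=rows), poisson)))
        except ValueError:  # a replicate can lose all shared columns
            continue
        for b in base:
            if b in rep:
                counts[b] += 1
    return {b: c / n_replicates for b, c in counts.items()}
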
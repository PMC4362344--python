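"""Greedy identity clustering of six-frame-translated peptides (CD-HIT
semantics) and Venn-overlap accounting across samples.

Identity between two peptides is the number of identical residues divided
by the length of the shorter sequence, counted on the optimal-score
*semi-global* alignment (BLOSUM62, affine gaps, terminal gaps free).  Among
co-optimal alignments the one with the most identities is used, which the
dynamic programme enforces directly by maximising the lexicographic pair
(score, identities) - this makes the measure a deterministic function of
the two sequences rather than of an aligner's tie-breaking.

Two exact upper bounds screen pairs before the affine-gap table is filled:
identities can never exceed the longest common subsequence (LCS), and
LCS <= (m + n - d) / 2 for unit-cost edit distance d (edlib), so most
unrelated pairs are rejected in O(n) or by one cheap LCS row sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
from Bio.Align import substitution_matrices

# lexicographic (score, identities) packing: integer BLOSUM62 scores are
# scaled so one unit of score always outweighs any identity count
_SCALE = 4096
_GAP_OPEN = 10
_GAP_EXT = 1

_BLOSUM = substitution_matrices.load("BLOSUM62")
_LUT = np.full(256, _BLOSUM.alphabet.index("X"), dtype=np.int64)
for _i, _c in enumerate(_BLOSUM.alphabet):
    _LUT[ord(_c)] = _i
_SUB = np.asarray(_BLOSUM).astype(np.int64)


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]


class LcsMasks:
    """Per-character position bitmasks of one sequence, reusable across
    many LCS computations against it (bit-parallel LCS-length)."""

    __slots__ = ("n", "masks", "full")

    def __init__(self, seq: str) -> None:
        self.n = len(seq)
        masks: dict[str, int] = {}
        for j, c in enumerate(seq):
            masks[c] = masks.get(c, 0) | (1 << j)
        self.masks = masks
        self.full = (1 << self.n) - 1

    def lcs(self, other: str) -> int:
        if self.n == 0 or not other:
            return 0
        V = self.full
        get = self.masks.get
        full = self.full
        for c in other:
            U = V & get(c, 0)
            V = ((V + U) | (V - U)) & full
        return self.n - bin(V).count("1")


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence (bit-parallel)."""
    return LcsMasks(b).lcs(a)


def alignment_identities(a: str, b: str) -> int:
    """Identical residues on the best semi-global alignment of a and b
    (max identities among score-co-optimal alignments)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = _encode(a), _encode(b)
    n = len(eb)
    sub_rows = _SUB[ea][:, eb] * _SCALE + (ea[:, None] == eb[None, :])
    open2 = (_GAP_OPEN + _GAP_EXT) * _SCALE
    ext2 = _GAP_EXT * _SCALE
    NEG = np.int64(-(1 << 40))
    j_ramp = np.arange(n + 1, dtype=np.int64) * ext2
    V_prev = np.zeros(n + 1, dtype=np.int64)  # free leading gaps
    X_prev = np.full(n + 1, NEG, dtype=np.int64)
    best_tail = np.int64(0)  # covers alignments ending on the last column
    for i in range(len(ea)):
        M = V_prev[:-1] + sub_rows[i]
        X = np.maximum(V_prev[1:] - open2, X_prev[1:] - ext2)
        W = np.maximum(M, X)
        # Y[j] = max_{j' < j} V'[j'] - open2 - ext2 * (j - j') as a running
        # max, where V'[0] = 0 is the free left boundary of this row
        runmax = np.maximum.accumulate(np.concatenate(([np.int64(0)], W + j_ramp[1:])))
        Y = runmax[:-1] - _GAP_OPEN * _SCALE - j_ramp[1:]
        V = np.maximum(W, Y)
        V_prev = np.concatenate(([np.int64(0)], V))  # free leading gap in b
        X_prev = np.concatenate(([NEG], X))
        best_tail = max(best_tail, V[-1])  # free trailing gap in b
    best = max(best_tail, int(V_prev[1:].max()))  # free trailing gap in a
    return int(best) % _SCALE if best > 0 else 0


def identity(a: str, b: str) -> float:
    """Identical residues over the shorter length (semi-global alignment)."""
    m = min(len(a), len(b))
    if m == 0:
        raise ValueError("identity of an empty sequence")
    return alignment_identities(a, b) / m


def _identity_decision(
    a: str, b: str, threshold: float, a_masks: LcsMasks | None = None
) -> bool:
    """identity(a, b) >= threshold, with exact upper-bound screens."""
    m, n = sorted((len(a), len(b)))
    d = edlib.align(a, b, task="distance")["editDistance"]
    if (m + n - d) / (2 * m) < threshold:  # bounds LCS, hence identities
        return False
    lcs = a_masks.lcs(b) if a_masks is not None else lcs_length(a, b)
    if lcs / m < threshold:
        return False
    return alignment_identities(a, b) / m >= threshold


@dataclass
class Peptide:
    id: str
    sample: str
    seq: str


@dataclass
class Cluster:
    representative: str          # peptide id of the longest member
    rep_seq: str
    members: list[Peptide] = field(default_factory=list)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(p.sample for p in self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)


def greedy_cluster(peptides: Sequence[Peptide], threshold: float = 0.5) -> ClusterSet:
    """CD-HIT-style greedy clustering.

    Sequences are visited by decreasing length (id as tie-break); each joins
    the first existing cluster whose representative matches at >= threshold
    identity, otherwise it founds a new cluster.  Representatives are the
    founding (longest) members by construction.
    """
    if not peptides:
        raise ValueError("no peptides to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(peptides, key=lambda p: (-len(p.seq), p.id))
    clusters: list[Cluster] = []
    for pep in order:
        placed = False
        masks = LcsMasks(pep.seq)
        for cl in clusters:
            if _identity_decision(pep.seq, cl.rep_seq, threshold, masks):
                cl.members.append(pep)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=pep.id, rep_seq=pep.seq, members=[pep]))
    return ClusterSet(clusters=clusters, threshold=threshold)


def venn_counts(
    cluster_set: ClusterSet, samples: Sequence[str] | None = None
) -> tuple[dict[frozenset[str], int], dict[str, float]]:
    """Count clusters per sample-subset, plus per-sample private fractions.

    Each cluster contributes to exactly one subset: the set of samples
    occurring among its members.  The private fraction of a sample is the
    share of clusters containing it that contain no other sample.
    """
    subset_counts: dict[frozenset[str], int] = {}
    for cl in cluster_set.clusters:
        key = cl.samples
        subset_counts[key] = subset_counts.get(key, 0) + 1
    if samples is None:
        samples = sorted({s for key in subset_counts for s in key})
    private: dict[str, float] = {}
    for s in samples:
        containing = sum(n for key, n in subset_counts.items() if s in key)
        alone = subset_counts.get(frozenset({s}), 0)
        private[s] = alone / containing if containing else 0.0
    return subset_counts, private


def six_frame_peptides(
    translations: Mapping[str, Mapping[int, str]],
    sample_of: Mapping[str, str],
) -> list[Peptide]:
    """Flatten per-unigene six-frame translations into clusterable peptides,
    one per (unigene, frame), named ``<unigene>|<frame>``."""
    peptides = []
    for uid, frames in translations.items():
        for frame, pep in frames.items():
            if pep:
                peptides.append(
                    Peptide(id=f"{uid}|{frame:+d}", sample=sample_of[uid], seq=pep)
                )
    return peptides


def collapse_to_unigenes(cluster_set: ClusterSet) -> list[set[str]]:
    """Collapse frame-level clusters to unigene-level member sets (a cluster
    contains a unigene when any of its frames is a member)."""
    return [
        {p.id.rsplit("|", 1)[0] for p in cl.members} for cl in cluster_set.clusters
    ]
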
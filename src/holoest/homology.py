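"""Built-in local similarity search for desk-scale runs.

Replaces an external blastn/tblastn step with exact Smith-Waterman (affine
gaps, via Biopython's ``PairwiseAligner``) in two modes:

* ``nucleotide`` - query and subject are DNA, simple match/mismatch scores;
* ``protein`` - queries are DNA, translated into all six reading frames,
  split at stop codons into ORF segments, and searched as peptides against a
  protein reference set (tblastn-like).

No E-values are computed; raw alignment scores against a ``min_score``
threshold substitute.  The ``bitscore`` field of emitted hits carries the
raw Smith-Waterman score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import SimilarityHit, Unigene, reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class ScoringScheme:
    """Alignment scoring parameters.

    Gap penalties are magnitudes (costs); a gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    mode: str = "protein"  # "nucleotide" | "protein"
    match: float = 2.0
    mismatch: float = -2.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    @classmethod
    def nucleotide(cls, match: float = 2.0, mismatch: float = -2.0,
                   gap_open: float = 5.0, gap_extend: float = 2.0) -> "ScoringScheme":
        return cls(mode="nucleotide", match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def protein(cls, matrix_name: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 1.0) -> "ScoringScheme":
        return cls(mode="protein", matrix_name=matrix_name,
                   gap_open=gap_open, gap_extend=gap_extend)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.mode == "protein":
            try:
                matrix = substitution_matrices.load(self.matrix_name)
            except FileNotFoundError as exc:
                raise ValueError(f"unknown substitution matrix {self.matrix_name!r}") from exc
            # extend the alphabet so '*' and 'X' in translated frames do not crash
            aligner.substitution_matrix = matrix
            aligner.wildcard = "X"
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class SWResult:
    score: float
    aligned_query: str
    aligned_subject: str
    pct_identity: float
    aln_length: int
    # 0-based half-open coordinates in query/subject
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    @property
    def mismatches(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != "-" and b != "-" and a != b
        )

    @property
    def gap_opens(self) -> int:
        opens = 0
        for row in (self.aligned_query, self.aligned_subject):
            in_gap = False
            for c in row:
                if c == "-" and not in_gap:
                    opens += 1
                in_gap = c == "-"
        return opens


def smith_waterman(query: str, subject: str, scheme: ScoringScheme | None = None) -> SWResult:
    """Optimal local alignment of two sequences.

    Returns the empty alignment with score 0 when no positive-scoring cell
    exists.  Ties between co-optimal paths are resolved by the aligner's
    deterministic first path.
    """
    if not query or not subject:
        raise ValueError("smith_waterman requires non-empty sequences")
    scheme = scheme or ScoringScheme.protein()
    aligner = scheme.make_aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return SWResult(0.0, "", "", 0.0, 0)
    aln = aligner.align(query, subject)[0]
    q_aln, s_aln = str(aln[0]), str(aln[1])
    identities = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    length = len(q_aln)
    coords = aln.coordinates
    return SWResult(
        score=float(score),
        aligned_query=q_aln,
        aligned_subject=s_aln,
        pct_identity=100.0 * identities / length,
        aln_length=length,
        q_start=int(coords[0, 0]),
        q_end=int(coords[0, -1]),
        s_start=int(coords[1, 0]),
        s_end=int(coords[1, -1]),
    )


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Standard genetic code; stops are ``*``, ambiguous codons ``X``.  Frame
    -k is the translation of the reverse complement offset by k-1.
    """
    if len(seq) < 3:
        raise ValueError("need at least one codon (3 nt) to translate")
    out: dict[int, str] = {}
    rc = reverse_complement(seq)
    for k in (1, 2, 3):
        for frame, s in ((k, seq), (-k, rc)):
            sub = s[k - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[frame] = str(Seq(sub).translate()) if sub else ""
    return out


def orf_segments(peptide: str, min_len: int = 20) -> list[tuple[int, str]]:
    """Split a frame peptide at stop codons into (offset, segment) pieces of
    length >= min_len."""
    segments: list[tuple[int, str]] = []
    start = 0
    for i, c in enumerate(peptide + "*"):
        if c == "*":
            if i - start >= min_len:
                segments.append((start, peptide[start:i]))
            start = i + 1
    return segments


@dataclass
class Reference:
    """A search subject with its description line and optional taxon."""

    id: str
    seq: str
    description: str = ""
    taxon: str = ""


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _seed_count(q_kmers: set[str], subject: str, k: int) -> int:
    return sum(1 for i in range(len(subject) - k + 1) if subject[i : i + k] in q_kmers)


def search(
    queries: Sequence[Unigene],
    reference_db: Sequence[Reference],
    scheme: ScoringScheme | None = None,
    min_score: float = 40.0,
    min_orf_len: int = 20,
    prescreen: bool = False,
    prescreen_k: int = 11,
    prescreen_min_seeds: int = 2,
) -> list[SimilarityHit]:
    """Search queries against a reference set, emitting blast-tabular hits.

    In protein mode each query is six-frame translated, frames are split at
    stops into ORF segments of >= ``min_orf_len`` aa, and each segment is
    aligned to each reference; the hit records the frame and carries
    aa coordinates within the frame peptide.  In nucleotide mode queries are
    aligned directly (plus strand).

    ``prescreen`` enables an exact shared-k-mer word filter (nucleotide
    mode): subject/query pairs sharing fewer than ``prescreen_min_seeds``
    k-mers are skipped before alignment.  This is an optional speed device
    for larger runs; it can in principle drop a borderline low-identity hit
    and is therefore off by default.

    Hits are sorted by (query, -score, subject) so ties break on subject id.
    """
    if not reference_db:
        raise ValueError("reference_db must be non-empty")
    scheme = scheme or ScoringScheme.protein()
    aligner = scheme.make_aligner()
    hits: list[SimilarityHit] = []

    def align_pair(qid: str, qseq: str, ref: Reference, frame: int | None, offset: int) -> None:
        score = aligner.score(qseq, ref.seq)
        if score < min_score or score <= 0:
            return
        res = smith_waterman(qseq, ref.seq, scheme)
        hits.append(
            SimilarityHit(
                query_id=qid,
                subject_id=ref.id,
                pct_identity=round(res.pct_identity, 2),
                aln_length=res.aln_length,
                mismatches=res.mismatches,
                gap_opens=res.gap_opens,
                q_start=offset + res.q_start + 1,
                q_end=offset + res.q_end,
                s_start=res.s_start + 1,
                s_end=res.s_end,
                evalue=0.0,
                bitscore=float(res.score),
                subject_description=ref.description,
                subject_taxon=ref.taxon,
                frame=frame,
            )
        )

    if scheme.mode == "nucleotide":
        for q in queries:
            q_kmers = _kmer_set(q.seq, prescreen_k) if prescreen else None
            for ref in reference_db:
                if q_kmers is not None and _seed_count(
                    q_kmers, ref.seq, prescreen_k
                ) < prescreen_min_seeds:
                    continue
                align_pair(q.id, q.seq, ref, None, 0)
    else:
        for q in queries:
            if len(q.seq) < 3:
                continue
            for frame, peptide in six_frame_translate(q.seq).items():
                for offset, segment in orf_segments(peptide, min_orf_len):
                    for ref in reference_db:
                        align_pair(q.id, segment, ref, frame, offset)

    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.subject_id))
    return hits


def best_hits(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Top-scoring hit per query (ties already broken by subject id order)."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.query_id] = h
    return best
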
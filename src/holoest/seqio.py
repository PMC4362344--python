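"""Sequence and tabular I/O plus the core record types.

Wire formats are the field's plain-text standards: FASTA for sequences, a
13/14-column blast-tabular dialect for similarity hits (the usual 12 columns
plus the subject description line and an optional subject taxon), and a 2-3
column TSV parent map for the taxonomy.

Coordinate convention: hit coordinates are 1-based inclusive on the wire
(blast tabular); anything computed internally is 0-based half-open and is
converted at the read/write boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_GC_BASES = frozenset("GCSgcs")


def gc_fraction(seq: str) -> float:
    """GC fraction of a nucleotide sequence.

    Counts G, C and the ambiguity code S (G-or-C) in the numerator; every
    base, ambiguous or not, counts in the denominator.  Raises on empty
    input.
    """
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    return sum(1 for b in seq if b in _GC_BASES) / len(seq)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class Unigene:
    """A contig or singleton from an EST assembly (one putative transcript)."""

    id: str
    seq: str
    sample: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"unigene {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


@dataclass
class SimilarityHit:
    """One query-subject local alignment record (blast-tabular dialect).

    ``q_start``/``q_end`` and ``s_start``/``s_end`` are 1-based inclusive,
    as on the wire.  ``frame`` is set by translated searches and is not
    serialised in the 13/14-column table.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_description: str = ""
    subject_taxon: str = ""
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")


def read_fasta(path: str | Path, sample: str = "") -> list[Unigene]:
    """Read a FASTA file into :class:`Unigene` records, order preserved.

    Raises on duplicate IDs (naming the offender) and on empty records.
    """
    records: list[Unigene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(Unigene(id=rec.id, seq=seq, sample=sample, description=desc))
    return records


def write_fasta(records: Iterable[Unigene], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_HIT_NUMERIC = (
    ("pct_identity", float),
    ("aln_length", int),
    ("mismatches", int),
    ("gap_opens", int),
    ("q_start", int),
    ("q_end", int),
    ("s_start", int),
    ("s_end", int),
    ("evalue", float),
    ("bitscore", float),
)


def read_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a 13/14-column hit table (12 blast-tabular columns + subject
    description, optionally + subject taxon).  ``#`` comment lines are
    skipped; a malformed line raises with its line number."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (13, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 13 or 14 tab-separated columns, "
                    f"got {len(fields)}"
                )
            kwargs = {"query_id": fields[0], "subject_id": fields[1]}
            for (name, conv), raw in zip(_HIT_NUMERIC, fields[2:12]):
                try:
                    kwargs[name] = conv(raw)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad value for {name}: {raw!r}") from exc
            kwargs["subject_description"] = fields[12]
            if len(fields) == 14:
                kwargs["subject_taxon"] = fields[13]
            hits.append(SimilarityHit(**kwargs))
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path, with_taxon: bool = False) -> None:
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:.2f}",
                str(h.aln_length),
                str(h.mismatches),
                str(h.gap_opens),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
                h.subject_description,
            ]
            if with_taxon:
                cols.append(h.subject_taxon)
            fh.write("\t".join(cols) + "\n")


@dataclass
class TaxonomyMap:
    """A rooted taxonomy as a child -> parent map (root maps to itself)."""

    parent: dict[str, str]
    rank: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if n == p]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots!r}")
        self.root = roots[0]
        for node in self.parent:
            self.path_to_root(node)  # raises on cycles / missing parents

    def __contains__(self, node: str) -> bool:
        return node in self.parent

    def path_to_root(self, node: str) -> list[str]:
        """Ancestor path [node, ..., root]."""
        path = [node]
        seen = {node}
        while self.parent.get(path[-1]) != path[-1]:
            nxt = self.parent.get(path[-1])
            if nxt is None:
                raise ValueError(f"node {path[-1]!r} has no parent entry")
            if nxt in seen:
                raise ValueError(f"cycle in taxonomy at {nxt!r}")
            seen.add(nxt)
            path.append(nxt)
        return path

    def lca(self, nodes: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of nodes."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca of an empty node set")
        paths = [self.path_to_root(n)[::-1] for n in nodes]  # root-first
        anc = None
        for level in zip(*paths):
            if len(set(level)) == 1:
                anc = level[0]
            else:
                break
        assert anc is not None  # all paths share the root
        return anc


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-3 column TSV: node, parent[, rank]."""
    parent: dict[str, str] = {}
    rank: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            parent[fields[0]] = fields[1]
            if len(fields) > 2 and fields[2]:
                rank[fields[0]] = fields[2]
    return TaxonomyMap(parent=parent, rank=rank)


def write_taxonomy(taxmap: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node, par in taxmap.parent.items():
            fh.write(f"{node}\t{par}\t{taxmap.rank.get(node, '')}\n")
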
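"""C-type lectin domain (CTLD) detection, splitting, deduplication and
sugar-motif classification in six-frame-translated unigenes.

A CTLD is defined operationally by its core architecture: four conserved
cysteines with bounded spacings plus a WIGL-like motif (W, [ILV], G, [ILVF])
between the first and third cysteine.  The tripeptide occupying the long
loop between the second and fourth cysteine carries the sugar-binding
specificity: EPN marks glucose/mannose binding, LND galactose binding;
anything else is recorded as a variant, located - when not found literally -
by anchored alignment to a packaged reference domain, because the motif is
defined by alignment column rather than absolute position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from . import clustering
from .seqio import SimilarityHit

GLUCOSE_MANNOSE = "glucose/mannose"
GALACTOSE = "galactose"
VARIANT = "variant"


@dataclass
class CTLDGrammar:
    """The domain architecture rule.

    ``cys_gap_bounds`` are inclusive bounds on the number of residues
    strictly between consecutive conserved cysteines.
    """

    cys_gap_bounds: tuple[tuple[int, int], ...] = ((5, 60), (20, 90), (5, 40))
    wigl_first: str = "W"
    wigl_second: frozenset[str] = frozenset("ILV")
    wigl_third: str = "G"
    wigl_fourth: frozenset[str] = frozenset("ILVF")
    sugar_motifs: tuple[tuple[str, str], ...] = (("EPN", GLUCOSE_MANNOSE), ("LND", GALACTOSE))

    def __post_init__(self) -> None:
        if len(self.cys_gap_bounds) != 3:
            raise ValueError("need exactly 3 cysteine gap bounds")
        for lo, hi in self.cys_gap_bounds:
            if lo < 0 or hi < lo:
                raise ValueError(f"bad gap bound ({lo}, {hi})")

    def wigl_matches(self, fourmer: str) -> bool:
        return (
            len(fourmer) == 4
            and fourmer[0] == self.wigl_first
            and fourmer[1] in self.wigl_second
            and fourmer[2] == self.wigl_third
            and fourmer[3] in self.wigl_fourth
        )

    def find_wigl(self, peptide: str, start: int, end: int) -> int | None:
        """Leftmost WIGL-like 4-mer fully inside (start, end) exclusive of
        the flanking cysteines; returns its offset or None."""
        for w in range(start + 1, end - 4 + 1):
            if self.wigl_matches(peptide[w : w + 4]):
                return w
        return None


@dataclass
class CTLDomain:
    """A located domain in one reading frame of one unigene.

    ``start``/``end`` are 0-based half-open aa coordinates in the frame
    peptide, spanning the first through the fourth conserved cysteine.
    """

    unigene_id: str
    sample: str
    frame: int
    start: int
    end: int
    cys_positions: tuple[int, int, int, int]
    wigl: str
    sugar_motif: str = ""
    sugar_class: str = VARIANT
    domain_seq: str = ""

    @property
    def id(self) -> str:
        return f"{self.unigene_id}|{self.frame:+d}|{self.start}-{self.end}"


def _scan_window(peptide: str, grammar: CTLDGrammar, begin: int, stop: int) -> list[tuple]:
    """Maximal non-overlapping grammar matches within peptide[begin:stop].

    Candidate cysteine quadruples are enumerated leftmost-compact (c1, then
    c2, c3, c4 each ascending); the first quadruple satisfying all gap
    bounds and holding a WIGL-like motif between c1 and c3 is accepted and
    the scan resumes after its last cysteine.
    """
    cys = [i for i in range(begin, stop) if peptide[i] == "C"]
    (g1lo, g1hi), (g2lo, g2hi), (g3lo, g3hi) = grammar.cys_gap_bounds
    found: list[tuple] = []
    pos = begin
    while True:
        match = None
        for i1, c1 in enumerate(cys):
            if c1 < pos:
                continue
            for i2 in range(i1 + 1, len(cys)):
                c2 = cys[i2]
                g1 = c2 - c1 - 1
                if g1 > g1hi:
                    break
                if g1 < g1lo:
                    continue
                for i3 in range(i2 + 1, len(cys)):
                    c3 = cys[i3]
                    g2 = c3 - c2 - 1
                    if g2 > g2hi:
                        break
                    if g2 < g2lo:
                        continue
                    w = grammar.find_wigl(peptide, c1, c3)
                    if w is None:
                        continue
                    for i4 in range(i3 + 1, len(cys)):
                        c4 = cys[i4]
                        g3 = c4 - c3 - 1
                        if g3 > g3hi:
                            break
                        if g3 < g3lo:
                            continue
                        if c4 >= stop:
                            break
                        match = (c1, c2, c3, c4, w)
                        break
                    if match:
                        break
                if match:
                    break
            if match:
                break
        if match is None:
            return found
        found.append(match)
        pos = match[3] + 1


def scan(
    peptide: str,
    grammar: CTLDGrammar | None = None,
    seed_hits: Sequence[SimilarityHit] | None = None,
    seed_margin: int = 30,
    unigene_id: str = "",
    sample: str = "",
    frame: int = 0,
) -> list[CTLDomain]:
    """Find all maximal non-overlapping CTLDs in one frame peptide.

    ``seed_hits`` (aa coordinates in this peptide, 1-based inclusive as on
    the wire) optionally restrict the scan to the hit regions expanded by
    ``seed_margin``; without seeds the whole peptide is scanned.
    """
    grammar = grammar or CTLDGrammar()
    if seed_hits is None:
        windows = [(0, len(peptide))]
    else:
        intervals = sorted(
            (max(0, h.q_start - 1 - seed_margin), min(len(peptide), h.q_end + seed_margin))
            for h in seed_hits
        )
        windows = []
        for lo, hi in intervals:
            if windows and lo <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(hi, windows[-1][1]))
            else:
                windows.append((lo, hi))
    domains: list[CTLDomain] = []
    for lo, hi in windows:
        for c1, c2, c3, c4, w in _scan_window(peptide, grammar, lo, hi):
            dom = CTLDomain(
                unigene_id=unigene_id,
                sample=sample,
                frame=frame,
                start=c1,
                end=c4 + 1,
                cys_positions=(c1, c2, c3, c4),
                wigl=peptide[w : w + 4],
                domain_seq=peptide[c1 : c4 + 1],
            )
            dom.sugar_motif, dom.sugar_class = classify_sugar(dom, grammar, peptide=peptide)
            domains.append(dom)
    return domains


@lru_cache(maxsize=1)
def _anchor_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _motif_by_anchor(domain_seq: str, reference: tuple[str, int]) -> str:
    """Residues of ``domain_seq`` aligned to the reference motif columns."""
    ref_seq, motif_start = reference
    aln = _anchor_aligner().align(domain_seq, ref_seq)[0]
    q_row, r_row = str(aln[0]), str(aln[1])
    r_pos = 0
    out = []
    for qc, rc in zip(q_row, r_row):
        if rc != "-":
            if motif_start <= r_pos < motif_start + 3 and qc != "-":
                out.append(qc)
            r_pos += 1
    return "".join(out)


def classify_sugar(
    domain: CTLDomain,
    grammar: CTLDGrammar | None = None,
    peptide: str | None = None,
    reference: tuple[str, int] | None = None,
) -> tuple[str, str]:
    """Sugar-binding motif and class of a domain.

    Searches the region between cysteine 2 and cysteine 4 for the known
    motifs; otherwise reports the 3-mer occupying the reference motif
    column (anchored alignment to the packaged reference domain) as a
    variant.
    """
    grammar = grammar or CTLDGrammar()
    pep = peptide if peptide is not None else domain.domain_seq
    if peptide is not None:
        c2, c4 = domain.cys_positions[1], domain.cys_positions[3]
    else:
        c2 = domain.cys_positions[1] - domain.cys_positions[0]
        c4 = domain.cys_positions[3] - domain.cys_positions[0]
    region = pep[c2 + 1 : c4]
    if len(region) < 3:
        return "", VARIANT
    for motif, klass in grammar.sugar_motifs:
        if motif in region:
            return motif, klass
    if reference is None:
        from .datasets import reference_anchor

        reference = reference_anchor()
    motif = _motif_by_anchor(domain.domain_seq, reference)
    return motif, VARIANT


def dedupe(domains: Sequence[CTLDomain], identity_threshold: float = 0.97) -> list[CTLDomain]:
    """Greedy collapse of near-identical domains.

    Domains whose sequences match a kept representative at >= threshold
    identity merge into it; the longest member (first by the length-sorted
    greedy order) is kept.  Output is sorted by unigene id, then frame and
    start.  Idempotent.
    """
    order = sorted(domains, key=lambda d: (-len(d.domain_seq), d.id))
    reps: list[CTLDomain] = []
    for dom in order:
        if not any(
            clustering.identity(dom.domain_seq, r.domain_seq) >= identity_threshold
            for r in reps
        ):
            reps.append(dom)
    return sorted(reps, key=lambda d: (d.unigene_id, d.frame, d.start))


def wigl_variants(domains: Sequence[CTLDomain]) -> dict[str, set[str]]:
    """Per-sample sets of distinct WIGL-like 4-mers."""
    out: dict[str, set[str]] = {}
    for d in domains:
        out.setdefault(d.sample, set()).add(d.wigl)
    return out
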
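"""rRNA / mRNA partitioning of unigenes.

A unigene is called ribosomal when at least one of its similarity hits (i)
has a subject description containing one of the rRNA keywords, (ii) exceeds
the identity threshold and (iii) exceeds the alignment-length threshold.
Everything else - including unigenes with no hits at all - is treated as
putative mRNA.

Keyword matching: all phrases match as case-insensitive substrings except
the short abbreviations ``ITS``, ``LSU`` and ``SSU``, which match
case-sensitively as whole tokens (delimited by non-alphanumerics) so that
ordinary words like "its" or "sites" do not fire.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .seqio import SimilarityHit, Unigene

DEFAULT_KEYWORDS: tuple[str, ...] = (
    "5.8S", "16S", "18S", "23S", "26S", "28S",
    "ITS", "rRNA", "rDNA", "ribosomal DNA", "ribosomal RNA", "LSU", "SSU",
)

_TOKEN_SENSITIVE = frozenset({"ITS", "LSU", "SSU"})


def _token_pattern(word: str) -> re.Pattern:
    return re.compile(rf"(?<![0-9A-Za-z]){re.escape(word)}(?![0-9A-Za-z])")


_TOKEN_RES = {w: _token_pattern(w) for w in _TOKEN_SENSITIVE}


def description_matches(description: str, keywords: Sequence[str] = DEFAULT_KEYWORDS) -> bool:
    """True when the description contains at least one rRNA keyword."""
    lower = description.lower()
    for kw in keywords:
        if kw in _TOKEN_SENSITIVE:
            pat = _TOKEN_RES.get(kw) or _token_pattern(kw)
            if pat.search(description):
                return True
        elif kw.lower() in lower:
            return True
    return False


@dataclass
class PartitionRule:
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    min_identity: float = 80.0   # percent
    min_aln_length: int = 100    # bp
    strict: bool = True          # strict '>' thresholds (inclusive when False)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be non-empty")
        if self.min_identity <= 0 or self.min_aln_length <= 0:
            raise ValueError("thresholds must be positive")


def is_rrna_hit(hit: SimilarityHit, rule: PartitionRule | None = None) -> bool:
    rule = rule or PartitionRule()
    if rule.strict:
        passes = hit.pct_identity > rule.min_identity and hit.aln_length > rule.min_aln_length
    else:
        passes = hit.pct_identity >= rule.min_identity and hit.aln_length >= rule.min_aln_length
    return passes and description_matches(hit.subject_description, rule.keywords)


@dataclass
class PartitionResult:
    labels: dict[str, str]                      # unigene id -> "rRNA" | "mRNA"
    trigger: dict[str, SimilarityHit] = field(default_factory=dict)

    def ids(self, label: str) -> list[str]:
        return [u for u, lab in self.labels.items() if lab == label]

    def per_sample_counts(self, unigenes: Sequence[Unigene]) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {}
        for u in unigenes:
            d = counts.setdefault(u.sample, {"rRNA": 0, "mRNA": 0})
            d[self.labels[u.id]] += 1
        return counts


def partition(
    unigenes: Sequence[Unigene],
    hits: Sequence[SimilarityHit],
    rule: PartitionRule | None = None,
) -> PartitionResult:
    """Label every unigene rRNA or mRNA from its hits (any-hit semantics).

    Hits whose query id is not among the unigenes are ignored with a
    warning.
    """
    rule = rule or PartitionRule()
    known = {u.id for u in unigenes}
    labels = {u.id: "mRNA" for u in unigenes}
    trigger: dict[str, SimilarityHit] = {}
    for hit in hits:
        if hit.query_id not in known:
            warnings.warn(f"hit for unknown query {hit.query_id!r} ignored", stacklevel=2)
            continue
        if labels[hit.query_id] == "rRNA":
            continue
        if is_rrna_hit(hit, rule):
            labels[hit.query_id] = "rRNA"
            trigger[hit.query_id] = hit
    return PartitionResult(labels=labels, trigger=trigger)
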
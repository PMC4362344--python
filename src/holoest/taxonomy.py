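"""Taxonomic assignment of unigenes from similarity hits.

Each unigene is binned at the lowest common ancestor (LCA) of the taxa of
its strong hits: hits scoring within ``top_percent`` of the best score and
at or above ``min_score``.  Unigenes with no hits at all are reported as
"No hits"; unigenes whose hits all fall below ``min_score`` as
"Not assigned".  Count tables mirror the familiar sample x (rRNA|mRNA)
layout with subtree subtotal rows and a percentage row whose formatting
rule (integers at >= 1%, one decimal below) matches how such tables are
printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .seqio import SimilarityHit, TaxonomyMap

NO_HITS = "No hits"
NOT_ASSIGNED = "Not assigned"
TOTAL = "Total"


def lca_assign(
    hits: Sequence[SimilarityHit],
    taxonomy: TaxonomyMap,
    top_percent: float = 10.0,
    min_score: float = 50.0,
) -> str:
    """LCA taxon of the qualifying hits of one unigene.

    Qualifying hits score >= min_score and within top_percent of the best
    hit's score.  Raises when a hit's subject taxon is missing from the
    taxonomy.
    """
    if not hits:
        return NO_HITS
    scored = [h for h in hits if h.bitscore >= min_score]
    if not scored:
        return NOT_ASSIGNED
    best = max(h.bitscore for h in scored)
    cutoff = best * (1.0 - top_percent / 100.0)
    taxa = set()
    for h in scored:
        if h.bitscore >= cutoff:
            if not h.subject_taxon:
                continue
            if h.subject_taxon not in taxonomy:
                raise ValueError(f"subject taxon {h.subject_taxon!r} not in taxonomy")
            taxa.add(h.subject_taxon)
    if not taxa:
        return NOT_ASSIGNED
    return taxonomy.lca(sorted(taxa))


def assign_all(
    hits_by_query: Mapping[str, Sequence[SimilarityHit]],
    query_ids: Sequence[str],
    taxonomy: TaxonomyMap,
    top_percent: float = 10.0,
    min_score: float = 50.0,
) -> dict[str, str]:
    return {
        q: lca_assign(list(hits_by_query.get(q, ())), taxonomy, top_percent, min_score)
        for q in query_ids
    }


@dataclass
class Assignment:
    unigene_id: str
    sample: str
    fraction: str  # "rRNA" | "mRNA"
    taxon: str     # taxon label, NO_HITS or NOT_ASSIGNED


def count_table(
    assignments: Sequence[Assignment],
    taxonomy: TaxonomyMap,
    group_rows: Sequence[str] = (),
) -> pd.DataFrame:
    """Build a taxon x (sample, fraction) count table.

    Rows are the taxa that received assignments plus, for every label in
    ``group_rows`` (internal taxonomy nodes), a ``Total <group>`` subtotal
    over its subtree; reserved rows "No hits", "Not assigned" and "Total"
    close the table.  Every column's leaf + reserved rows sum to the number
    of assignments in that column.
    """
    cols = sorted({(a.sample, a.fraction) for a in assignments})
    index = pd.MultiIndex.from_tuples(cols, names=["sample", "fraction"])
    taxa = sorted({a.taxon for a in assignments if a.taxon not in (NO_HITS, NOT_ASSIGNED)})
    rows = {}
    for taxon in taxa:
        rows[taxon] = [
            sum(1 for a in assignments if a.taxon == taxon and (a.sample, a.fraction) == c)
            for c in cols
        ]
    for group in group_rows:
        members = [t for t in taxa if group in taxonomy.path_to_root(t)]
        rows[f"Total {group}"] = [
            sum(rows[m][i] for m in members) for i in range(len(cols))
        ]
    for reserved in (NO_HITS, NOT_ASSIGNED):
        rows[reserved] = [
            sum(1 for a in assignments if a.taxon == reserved and (a.sample, a.fraction) == c)
            for c in cols
        ]
    rows[TOTAL] = [
        sum(1 for a in assignments if (a.sample, a.fraction) == c) for c in cols
    ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=index)


def format_percent(pct: float) -> float | int:
    """Round a percentage the way summary tables print it: to the nearest
    integer when >= 1, to one decimal below 1 (half away from zero)."""
    if pct >= 1.0:
        return int(math.floor(pct + 0.5))
    return math.floor(pct * 10 + 0.5) / 10


def percent_of_total(
    table: pd.DataFrame, group_row: str, sample: str, fraction: str
) -> float | int:
    """Formatted percentage of a group row relative to the column Total."""
    total = table.loc[TOTAL, (sample, fraction)]
    if total == 0:
        raise ZeroDivisionError(f"zero total for ({sample}, {fraction})")
    return format_percent(100.0 * table.loc[group_row, (sample, fraction)] / total)
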
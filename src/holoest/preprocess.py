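"""Cleaning of raw unigene sets: length filter, adapter/poly-A trimming and
per-sample summary statistics."""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from .seqio import Unigene, gc_fraction


def length_filter(
    unigenes: Sequence[Unigene], min_len: int = 200
) -> tuple[list[Unigene], list[Unigene]]:
    """Partition unigenes into (kept, removed) by length.

    Sequences *shorter than* ``min_len`` are removed; a sequence of exactly
    ``min_len`` bp is kept.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [u for u in unigenes if u.length >= min_len]
    removed = [u for u in unigenes if u.length < min_len]
    return kept, removed


def _tail_cut(seq: str, base: str, min_run: int, mismatch_per: int) -> int:
    """Index of the leftmost valid tail start, or len(seq) if none.

    A valid tail is a suffix of length >= min_run that starts with ``base``
    and contains at most one non-``base`` per ``mismatch_per`` nt (floor).
    Choosing the leftmost valid start makes trimming idempotent.
    """
    n = len(seq)
    best = n
    mismatches = 0
    for j in range(n - 1, -1, -1):
        if seq[j] != base:
            mismatches += 1
        run_len = n - j
        if run_len >= min_run and seq[j] == base and mismatches <= run_len // mismatch_per:
            best = j
    return best


def trim_polyA(seq: str, min_run: int = 10, mismatch_per: int = 10) -> str:
    """Strip a trailing poly-A tail and, symmetrically, a leading poly-T run
    (reverse-strand tails), tolerating one mismatch per ``mismatch_per`` nt.

    Runs shorter than ``min_run`` are untouched.  Idempotent.
    """
    cut = _tail_cut(seq, "A", min_run, mismatch_per)
    seq = seq[:cut]
    lead = _tail_cut(seq[::-1], "T", min_run, mismatch_per)
    return seq[len(seq) - lead :]


def trim_adapters(seq: str, adapters: Sequence[str]) -> str:
    """Remove exact adapter matches at either end (no fuzzy search)."""
    changed = True
    while changed:
        changed = False
        for ad in adapters:
            if ad and seq.startswith(ad):
                seq = seq[len(ad):]
                changed = True
            if ad and seq.endswith(ad):
                seq = seq[: len(seq) - len(ad)]
                changed = True
    return seq


@dataclass
class SampleStats:
    n: int
    total_bp: int
    mean_length: float
    median_length: float
    gc_percent: float


def sample_stats(unigenes: Sequence[Unigene]) -> SampleStats:
    """Count, total bp, mean/median length and overall GC% of a library.

    GC% is base-weighted (GC bases over all bases), matching how the overall
    GC content of an assembly is reported.  Median of an even-sized set is
    the mean of the two central values.
    """
    if not unigenes:
        raise ValueError("sample_stats of an empty unigene set")
    lengths = [u.length for u in unigenes]
    total_bp = sum(lengths)
    gc_bases = sum(round(u.gc * u.length) for u in unigenes)
    return SampleStats(
        n=len(unigenes),
        total_bp=total_bp,
        mean_length=total_bp / len(unigenes),
        median_length=statistics.median(lengths),
        gc_percent=100.0 * gc_bases / total_bp,
    )


def clean(
    unigenes: Sequence[Unigene],
    min_len: int = 200,
    polya_min_run: int = 10,
    adapters: Sequence[str] = (),
) -> tuple[list[Unigene], list[Unigene]]:
    """Full cleaning pass: adapter trim, poly-A/T trim, then length filter.

    Returns (kept, removed); trimmed-to-empty sequences count as removed.
    """
    trimmed: list[Unigene] = []
    removed: list[Unigene] = []
    for u in unigenes:
        s = trim_adapters(u.seq, adapters) if adapters else u.seq
        s = trim_polyA(s, min_run=polya_min_run)
        if not s:
            removed.append(u)
            continue
        trimmed.append(Unigene(id=u.id, seq=s, sample=u.sample, description=u.description))
    kept, short = length_filter(trimmed, min_len=min_len)
    return kept, removed + short
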
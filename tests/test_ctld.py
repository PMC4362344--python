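import numpy as np
import pytest

from holoest import homology
from holoest.ctld import (
    CTLDGrammar,
    CTLDomain,
    classify_sugar,
    dedupe,
    scan,
    wigl_variants,
)
from holoest.datasets import reference_anchor
from holoest.synthio import near_duplicates, random_ctld_peptide

GRAMMAR = CTLDGrammar()
FILLER = "AGSTNQ"  # no C, no W


def _filler(rng, n):
    return "".join(rng.choice(list(FILLER), n))


def _domain(rng, sugar="EPN"):
    return random_ctld_peptide(rng, sugar_motif=sugar)


@pytest.mark.parametrize("variant", ["WIGL", "WLGL", "WVGL", "WIGV", "WLGF"])
def test_observed_wigl_variants_match_the_pattern(variant):
    assert GRAMMAR.wigl_matches(variant)


@pytest.mark.parametrize("bad", ["WAGL", "AIGL", "WIAL", "WIGP", "WIG"])
def test_non_conforming_fourmers_rejected(bad):
    assert not GRAMMAR.wigl_matches(bad)


def test_grammar_validation():
    with pytest.raises(ValueError):
        CTLDGrammar(cys_gap_bounds=((5, 60), (20, 90)))
    with pytest.raises(ValueError):
        CTLDGrammar(cys_gap_bounds=((5, 60), (90, 20), (5, 40)))


def test_scan_hand_constructed_domain_has_exact_coordinates():
    gap1 = "AGS" + "WIGL" + "AGSTNQA"  # 14 residues between C1 and C2
    gap2 = "AGSTNQ" * 4 + "EPN" + "AGS"  # 30 residues between C2 and C3
    gap3 = "AGSTNQAGST"  # 10 residues between C3 and C4
    pep = "NQ" + "C" + gap1 + "C" + gap2 + "C" + gap3 + "C" + "QN"
    (dom,) = scan(pep, GRAMMAR)
    c1 = 2
    c2 = c1 + 1 + len(gap1)
    c3 = c2 + 1 + len(gap2)
    c4 = c3 + 1 + len(gap3)
    assert dom.cys_positions == (c1, c2, c3, c4)
    assert dom.start == c1 and dom.end == c4 + 1
    assert dom.wigl == "WIGL"
    assert dom.sugar_motif == "EPN"
    assert dom.domain_seq == pep[c1 : c4 + 1]


def test_three_cysteines_are_not_a_domain(rng):
    pep = _domain(rng)
    no_last_cys = pep[:-1] + "A"
    assert scan(no_last_cys, GRAMMAR) == []


def test_missing_wigl_is_not_a_domain(rng):
    pep = _domain(rng)
    (dom,) = scan(pep, GRAMMAR)
    w = pep.find(dom.wigl)
    broken = pep[:w] + "A" + pep[w + 1 :]
    assert scan(broken, GRAMMAR) == []


def test_two_domains_split_without_overlap(rng):
    d1, d2 = _domain(rng), _domain(rng, sugar="LND")
    pep = _filler(rng, 6) + d1 + _filler(rng, 20) + d2 + _filler(rng, 6)
    doms = scan(pep, GRAMMAR)
    assert len(doms) == 2
    assert doms[0].end <= doms[1].start
    assert doms[0].sugar_motif == "EPN" and doms[1].sugar_motif == "LND"


def test_scan_restricted_by_seed_hits_is_a_subset(rng):
    d1, d2 = _domain(rng), _domain(rng)
    pep = _filler(rng, 10) + d1 + _filler(rng, 25) + d2 + _filler(rng, 10)
    full = scan(pep, GRAMMAR)
    from holoest.seqio import SimilarityHit

    seed = SimilarityHit(
        query_id="q", subject_id="r", pct_identity=50.0, aln_length=30,
        mismatches=0, gap_opens=0,
        q_start=11, q_end=11 + len(d1), s_start=1, s_end=30,
        evalue=0.0, bitscore=60.0,
    )
    seeded = scan(pep, GRAMMAR, seed_hits=[seed], seed_margin=5)
    assert len(full) == 2
    assert [(d.start, d.end) for d in seeded] == [(full[0].start, full[0].end)]


def test_classify_epn_and_lnd(rng):
    (dom_epn,) = scan(_domain(rng, "EPN"), GRAMMAR)
    assert (dom_epn.sugar_motif, dom_epn.sugar_class) == ("EPN", "glucose/mannose")
    (dom_lnd,) = scan(_domain(rng, "LND"), GRAMMAR)
    assert (dom_lnd.sugar_motif, dom_lnd.sugar_class) == ("LND", "galactose")


@pytest.mark.parametrize("replacement", ["DSS", "WSD", "VND"])
def test_variant_motifs_located_by_anchored_alignment(replacement):
    """Replacing the anchor's EPN by an observed variant tripeptide must be
    reported as that tripeptide with class 'variant'."""
    ref_seq, motif_at = reference_anchor()
    mutated = ref_seq[:motif_at] + replacement + ref_seq[motif_at + 3 :]
    (dom,) = scan(mutated, GRAMMAR)
    assert dom.sugar_class == "variant"
    assert dom.sugar_motif == replacement


def test_classify_short_region_returns_empty_variant():
    dom = CTLDomain(
        unigene_id="u", sample="s", frame=1, start=0, end=10,
        cys_positions=(0, 3, 6, 9), wigl="WIGL", domain_seq="CAACAACAAC",
    )
    assert classify_sugar(dom, GRAMMAR) == ("", "variant")


def test_dedupe_merges_identical_and_keeps_distant(rng):
    base = _domain(rng)
    doms = [
        CTLDomain(
            unigene_id=f"u{i}", sample="s", frame=1, start=0, end=len(base),
            cys_positions=scan(base, GRAMMAR)[0].cys_positions,
            wigl="WIGL", domain_seq=base,
        )
        for i in range(3)
    ]
    assert len(dedupe(doms)) == 1
    other = _domain(rng)
    doms.append(
        CTLDomain(
            unigene_id="u9", sample="s", frame=1, start=0, end=len(other),
            cys_positions=scan(other, GRAMMAR)[0].cys_positions,
            wigl="WIGL", domain_seq=other,
        )
    )
    assert len(dedupe(doms)) == 2


def test_dedupe_idempotent_and_monotone_in_threshold(rng):
    base = _domain(rng)
    copies = near_duplicates(rng, base, 4, GRAMMAR)
    doms = [
        CTLDomain(
            unigene_id=f"u{i}", sample="s", frame=1, start=0, end=len(s),
            cys_positions=scan(s, GRAMMAR)[0].cys_positions,
            wigl="WIGL", domain_seq=s,
        )
        for i, s in enumerate([base] + copies + [_domain(rng)])
    ]
    once = dedupe(doms, 0.97)
    assert dedupe(once, 0.97) == once
    assert len(dedupe(doms, 0.90)) <= len(once) <= len(dedupe(doms, 0.999))


def test_wigl_variants_per_sample():
    def dom(sample, wigl):
        return CTLDomain(
            unigene_id="u", sample=sample, frame=1, start=0, end=5,
            cys_positions=(0, 1, 2, 3), wigl=wigl, domain_seq="CCCCC",
        )

    out = wigl_variants([dom("a", "WIGL"), dom("a", "WIGL"), dom("a", "WVGL"),
                         dom("b", "WLGF")])
    assert out == {"a": {"WIGL", "WVGL"}, "b": {"WLGF"}}
    assert wigl_variants([]) == {}


def test_planted_domains_recovered_coordinate_exact(default_sim):
    """Grammar-only scan of the planted frame recovers every planted domain
    at its exact coordinates (100% recall)."""
    by_read = {u.id: u for u in default_sim.all_unigenes()}
    td = default_sim.truth_domains
    assert len(td) > 0
    for (rid, frame), rows in td.groupby(["read_id", "frame"]):
        pep = homology.six_frame_translate(by_read[rid].seq)[frame]
        found = {(d.start, d.end) for d in scan(pep, GRAMMAR)}
        for _, r in rows.iterrows():
            assert (r.start, r.end) in found


def test_negative_controls_yield_no_domains(default_sim):
    """Planted decoys lacking the four-cysteine architecture must produce
    zero domains in any reading frame (specificity 1.0)."""
    negatives = default_sim.truth_reads.query("category == 'ctld_negative'")
    by_read = {u.id: u for u in default_sim.all_unigenes()}
    assert len(negatives) > 0
    for rid in negatives.read_id:
        for pep in homology.six_frame_translate(by_read[rid].seq).values():
            assert scan(pep, GRAMMAR) == []
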
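"""Synthetic holobiont EST generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: each
sample is a mixture of host, photosymbiont, bacterial and bystander
transcripts with per-taxon GC content, read lengths from a truncated
normal (some below the 200 bp cleaning cutoff), poly-A tails on eukaryotic
mRNA, rRNA reads sampled as windows of mock reference genes whose
description lines carry the rRNA keywords, and planted C-type-lectin-domain
transcripts (single- and multi-domain, with near-duplicate copies) plus
negative-control transcripts lacking the four-cysteine architecture.

Determinism: one RNG stream per run keyed by (seed, sample_id), plus one
for the shared references, so adding a sample never perturbs the others.
Fixed seed => byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ctld as ctld_mod
from .homology import Reference, six_frame_translate
from .seqio import Unigene, reverse_complement, write_fasta


class ConfigurationError(ValueError):
    pass


# fixed reverse-translation codon per residue, for determinism
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}

# residues used for random domain filler and substitutions: no C (would add
# a conserved-cysteine candidate) and no W (would seed a spurious WIGL)
SAFE_AA = "ADEFGHIKLMNPQRSTVY"


@dataclass
class SampleProfile:
    sample_id: str
    taxon_mix: dict[str, float]
    gc_by_taxon: dict[str, float]
    rrna_fraction: float = 0.03
    n_planted_ctld: int = 0       # CTLD-bearing transcripts (one family each)
    n_multidomain: int = 0        # transcripts carrying >= 2 domains
    n_redundant_copies: int = 0   # near-duplicate extra domain copies
    n_negative_controls: int = 3  # decoy transcripts lacking the architecture

    def validate(self) -> None:
        total = sum(self.taxon_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.sample_id}: taxon fractions sum to {total}, not 1"
            )
        for t, f in self.taxon_mix.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{self.sample_id}: bad fraction for {t}")
            if t not in self.gc_by_taxon:
                raise ConfigurationError(f"{self.sample_id}: no GC target for {t}")
        for t, g in self.gc_by_taxon.items():
            if not 0.0 <= g <= 1.0:
                raise ConfigurationError(f"{self.sample_id}: GC for {t} outside [0,1]")
        if not 0.0 <= self.rrna_fraction <= 1.0:
            raise ConfigurationError(f"{self.sample_id}: bad rrna_fraction")
        if self.n_multidomain > self.n_planted_ctld:
            raise ConfigurationError(
                f"{self.sample_id}: n_multidomain exceeds n_planted_ctld"
            )


@dataclass
class SimulationConfig:
    per_sample: list[SampleProfile]
    seed: int = 0
    reads_per_sample: int = 120
    read_length_mean: float = 350.0
    read_length_sd: float = 90.0
    read_length_min: int = 150
    read_length_max: int = 1200
    polyA_len_range: tuple[int, int] = (10, 30)
    mutation_rate: float = 0.02
    novel_fraction: float = 0.2   # mRNA reads with no reference counterpart
    prokaryotic_taxa: tuple[str, ...] = (
        "Gammaproteobacteria", "Alphaproteobacteria", "Bacteroidetes",
    )

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    def validate(self) -> None:
        if not self.per_sample:
            raise ConfigurationError("no sample profiles")
        if self.read_length_min >= self.read_length_mean:
            raise ConfigurationError("read_length_min must be below the mean")
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ConfigurationError("mutation_rate must lie in [0, 0.3]")
        lo, hi = self.polyA_len_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("bad polyA_len_range")
        for p in self.per_sample:
            p.validate()


def _rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def reverse_translate(peptide: str) -> str:
    try:
        return "".join(CODON[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate residue {exc.args[0]!r}") from exc


def plant_ctld(peptide_template: str, frame: int) -> str:
    """Encode a CTLD-bearing peptide in a nucleotide sequence so that the
    stated reading frame recovers the template exactly.

    The template must contain at least one grammar-conformant domain.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in +-1..3, got {frame}")
    if not ctld_mod.scan(peptide_template):
        raise ValueError("peptide template does not match the CTLD grammar")
    nt = reverse_translate(peptide_template)
    k = abs(frame)
    forward = "G" * (k - 1) + nt
    return forward if frame > 0 else reverse_complement(forward)


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SAFE_AA), size=n))


def random_ctld_peptide(
    rng: np.random.Generator,
    sugar_motif: str = "EPN",
    grammar: ctld_mod.CTLDGrammar | None = None,
) -> str:
    """A random domain peptide satisfying the grammar: four cysteines with
    compact spacings, a WIGL-like motif between Cys1 and Cys3 and the given
    sugar motif between Cys2 and Cys4."""
    grammar = grammar or ctld_mod.CTLDGrammar()
    for _ in range(50):
        g1 = int(rng.integers(10, 21))
        g2 = int(rng.integers(30, 46))
        g3 = int(rng.integers(8, 16))
        wigl = (
            "W"
            + str(rng.choice(list(grammar.wigl_second)))
            + "G"
            + str(rng.choice(list(grammar.wigl_fourth)))
        )
        w_at = int(rng.integers(1, g1 - 4))
        gap1 = _random_aa(rng, w_at) + wigl + _random_aa(rng, g1 - w_at - 4)
        m_at = int(rng.integers(1, g2 - len(sugar_motif)))
        gap2 = (
            _random_aa(rng, m_at)
            + sugar_motif
            + _random_aa(rng, g2 - m_at - len(sugar_motif))
        )
        pep = "C" + gap1 + "C" + gap2 + "C" + _random_aa(rng, g3) + "C"
        doms = ctld_mod.scan(pep, grammar)
        if len(doms) == 1 and doms[0].sugar_motif == sugar_motif:
            return pep
    raise RuntimeError("failed to build a grammar-conformant domain")


def _protected_positions(pep: str, grammar: ctld_mod.CTLDGrammar) -> set[int]:
    """Positions whose substitution could change the scan/classification:
    the four cysteines, the WIGL 4-mer and the sugar 3-mer."""
    doms = ctld_mod.scan(pep, grammar)
    protected: set[int] = set()
    for d in doms:
        protected.update(d.cys_positions)
        w = pep.find(d.wigl, d.cys_positions[0], d.cys_positions[2])
        if w >= 0:
            protected.update(range(w, w + 4))
        if d.sugar_motif:
            m = pep.find(d.sugar_motif, d.cys_positions[1], d.cys_positions[3])
            if m >= 0:
                protected.update(range(m, m + 3))
    return protected


def mutate_peptide(
    rng: np.random.Generator,
    pep: str,
    divergence: float,
    grammar: ctld_mod.CTLDGrammar | None = None,
) -> str:
    """Substitute ~divergence of the residues at architecture-safe
    positions, preserving domain count, WIGL and sugar classification."""
    grammar = grammar or ctld_mod.CTLDGrammar()
    reference = ctld_mod.scan(pep, grammar)
    protected = _protected_positions(pep, grammar)
    free = [i for i in range(len(pep)) if i not in protected]
    n_sub = min(len(free), int(round(divergence * len(pep))))
    for _ in range(20):
        sites = rng.choice(len(free), size=n_sub, replace=False) if n_sub else []
        out = list(pep)
        for s in sites:
            i = free[int(s)]
            choices = [a for a in SAFE_AA if a != out[i]]
            out[i] = str(rng.choice(choices))
        mutated = "".join(out)
        doms = ctld_mod.scan(mutated, grammar)
        if len(doms) == len(reference) and all(
            d.cys_positions == r.cys_positions and d.sugar_motif == r.sugar_motif
            for d, r in zip(doms, reference)
        ):
            return mutated
    raise RuntimeError("could not mutate peptide without disturbing the grammar")


def vary_wigl(
    rng: np.random.Generator,
    pep: str,
    grammar: ctld_mod.CTLDGrammar | None = None,
) -> str:
    """Swap the variable WIGL-like positions (2 and 4) within their allowed
    residue classes, emulating the motif variation seen across real CTLDs."""
    grammar = grammar or ctld_mod.CTLDGrammar()
    doms = ctld_mod.scan(pep, grammar)
    out = list(pep)
    for d in doms:
        w = pep.find(d.wigl, d.cys_positions[0], d.cys_positions[2])
        if w >= 0:
            out[w + 1] = str(rng.choice(sorted(grammar.wigl_second)))
            out[w + 3] = str(rng.choice(sorted(grammar.wigl_fourth)))
    return "".join(out)


def near_duplicates(
    rng: np.random.Generator,
    pep: str,
    n: int,
    grammar: ctld_mod.CTLDGrammar | None = None,
) -> list[str]:
    """n near-duplicate copies of a domain, all varying at one shared
    architecture-safe site so every pairwise identity stays >= 1 - 1/len."""
    grammar = grammar or ctld_mod.CTLDGrammar()
    if n == 0:
        return []
    free = [i for i in range(len(pep)) if i not in _protected_positions(pep, grammar)]
    site = free[int(rng.integers(len(free)))]
    copies = []
    for _ in range(n):
        out = list(pep)
        out[site] = str(rng.choice([a for a in SAFE_AA if a != pep[site]]))
        copies.append("".join(out))
    return copies


_MRNA_GENES = (
    "actin mRNA", "heat shock protein 70 mRNA", "elongation factor 1-alpha mRNA",
    "tubulin beta chain mRNA", "ATP synthase subunit beta mRNA",
)


@dataclass
class SimulationResult:
    config: SimulationConfig
    samples: dict[str, list[Unigene]]
    rrna_refs: list[Reference]
    mrna_refs: list[Reference]
    ctld_refs: list[Reference]
    truth_reads: pd.DataFrame
    truth_domains: pd.DataFrame

    def all_unigenes(self) -> list[Unigene]:
        return [u for sample in self.samples.values() for u in sample]

    def nucleotide_refs(self) -> list[Reference]:
        return self.rrna_refs + self.mrna_refs

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in self.samples.items():
            write_fasta(reads, outdir / f"{sample_id}.fasta")
        refs = [
            Unigene(id=r.id, seq=r.seq, description=r.description)
            for r in self.nucleotide_refs()
        ]
        write_fasta(refs, outdir / "references_nt.fasta")
        write_fasta(
            [Unigene(id=r.id, seq=r.seq, description=r.description) for r in self.ctld_refs],
            outdir / "references_ctld.fasta",
        )
        self.truth_reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.truth_domains.to_csv(outdir / "truth_domains.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=list))


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    strong = rng.random(n) < gc
    half = rng.random(n) < 0.5
    bases = np.where(strong, np.where(half, "G", "C"), np.where(half, "A", "T"))
    return "".join(bases)


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        alternatives = [b for b in "ACGT" if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(3))]
    return "".join(arr)


def _truncnorm_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    while True:
        val = rng.normal(cfg.read_length_mean, cfg.read_length_sd)
        if cfg.read_length_min <= val <= cfg.read_length_max:
            return int(round(val))


def _build_references(cfg: SimulationConfig) -> tuple[list[Reference], list[Reference]]:
    """Mock rRNA genes and mRNA transcripts per (taxon, GC) combination."""
    rng = _rng_for(cfg.seed, "references")
    combos: list[tuple[str, float]] = []
    for prof in cfg.per_sample:
        for taxon in sorted(prof.taxon_mix):
            key = (taxon, round(prof.gc_by_taxon[taxon], 4))
            if key not in combos:
                combos.append(key)
    combos.sort()
    rrna_refs: list[Reference] = []
    mrna_refs: list[Reference] = []
    for idx, (taxon, gc) in enumerate(combos):
        tag = f"{taxon}_gc{int(round(gc * 1000)):03d}"
        subunit = "16S" if taxon in cfg.prokaryotic_taxa else "18S"
        rrna_refs.append(
            Reference(
                id=f"{tag}_rrna",
                seq=_random_nt(rng, 1600, gc),
                description=f"{taxon} {subunit} ribosomal RNA gene, partial sequence",
                taxon=taxon,
            )
        )
        for j in range(2):
            gene = _MRNA_GENES[(idx * 2 + j) % len(_MRNA_GENES)]
            mrna_refs.append(
                Reference(
                    id=f"{tag}_mrna{j}",
                    seq=_random_nt(rng, 1200, gc),
                    description=f"{taxon} {gene}, complete cds",
                    taxon=taxon,
                )
            )
    return rrna_refs, mrna_refs


def _frame_offset_of(read: str, transcript_nt: str, frame: int, tail_len: int) -> int:
    """aa offset of the transcript peptide inside the frame peptide of the
    final read (prefix pads consumed by the frame, poly-A tail handled for
    negative frames; tail_len is a multiple of 3 there)."""
    if frame > 0:
        return 0
    return tail_len // 3


def _plant_transcript(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    grammar: ctld_mod.CTLDGrammar,
    domain_peps: Sequence[str],
    read_id: str,
    sample_id: str,
) -> tuple[str, int, list[dict]]:
    """Assemble a read carrying the given domain peptides in one random
    frame; returns (read, frame, truth domain records)."""
    frame = int(rng.choice([1, 2, 3, -1, -2, -3]))
    parts = [_random_aa(rng, int(rng.integers(5, 13)))]
    offsets: list[int] = []
    for i, dom in enumerate(domain_peps):
        if i:
            parts.append(_random_aa(rng, int(rng.integers(15, 26))))
        offsets.append(sum(len(p) for p in parts))
        parts.append(dom)
    parts.append(_random_aa(rng, int(rng.integers(5, 13))))
    transcript_pep = "".join(parts)
    nt = plant_ctld(transcript_pep, frame)
    lo, hi = cfg.polyA_len_range
    tail_len = int(rng.integers(lo, hi + 1))
    if frame < 0:
        tail_len += (-tail_len) % 3  # keep the planted frame's codon phase
    read = nt + "A" * tail_len
    base = _frame_offset_of(read, nt, frame, tail_len)
    frame_pep = six_frame_translate(read)[frame]
    records = []
    for dom, off in zip(domain_peps, offsets):
        start = base + off
        end = start + len(dom)
        assert frame_pep[start:end] == dom, "planted coordinates out of register"
        scanned = ctld_mod.scan(dom, grammar)
        d = scanned[0] if scanned else None
        records.append(
            {
                "read_id": read_id,
                "sample": sample_id,
                "frame": frame,
                "start": start,
                "end": end,
                "cys_positions": (
                    ",".join(str(start + c) for c in d.cys_positions) if d else ""
                ),
                "wigl": d.wigl if d else "",
                "sugar_motif": d.sugar_motif if d else "",
                "sugar_class": d.sugar_class if d else "",
                "domain_seq": dom,
            }
        )
    return read, frame, records


def _negative_domain(rng: np.random.Generator, base: str, grammar: ctld_mod.CTLDGrammar) -> str:
    """Corrupt a domain so it no longer satisfies the grammar: drop the
    last cysteine or destroy the WIGL tryptophan (alternating by rng)."""
    doms = ctld_mod.scan(base, grammar)
    d = doms[0]
    out = list(base)
    if rng.random() < 0.5:
        out[d.cys_positions[3]] = "A"
    else:
        w = base.find(d.wigl, d.cys_positions[0], d.cys_positions[2])
        out[w] = "F"
    neg = "".join(out)
    return neg if not ctld_mod.scan(neg, grammar) else base.replace("C", "A", 2)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate per-sample read sets, shared references and the truth table."""
    config.validate()
    grammar = ctld_mod.CTLDGrammar()
    rrna_refs, mrna_refs = _build_references(config)
    from .datasets import load_reference_ctlds

    ctld_refs = load_reference_ctlds()
    rrna_by_key = {(r.taxon, r.id.split("_gc")[1][:3]): r for r in rrna_refs}
    mrna_by_key: dict[tuple[str, str], list[Reference]] = {}
    for r in mrna_refs:
        key = (r.taxon, r.id.split("_gc")[1][:3])
        mrna_by_key.setdefault(key, []).append(r)

    samples: dict[str, list[Unigene]] = {}
    read_rows: list[dict] = []
    domain_rows: list[dict] = []

    for s_idx, prof in enumerate(config.per_sample):
        rng = _rng_for(config.seed, prof.sample_id)
        reads: list[Unigene] = []
        taxa = sorted(prof.taxon_mix)
        probs = np.array([prof.taxon_mix[t] for t in taxa])
        n = config.reads_per_sample
        n_rrna = int(round(prof.rrna_fraction * n))
        counts_rrna = rng.multinomial(n_rrna, probs)
        counts_mrna = rng.multinomial(n - n_rrna, probs)
        i_read = 0
        for fraction, counts in (("rRNA", counts_rrna), ("mRNA", counts_mrna)):
            for taxon, cnt in zip(taxa, counts):
                gc = prof.gc_by_taxon[taxon]
                gc_key = f"{int(round(gc * 1000)):03d}"
                for _ in range(cnt):
                    rid = f"{prof.sample_id}_r{i_read:05d}"
                    i_read += 1
                    length = _truncnorm_length(rng, config)
                    category = "background"
                    source = ""
                    if fraction == "rRNA":
                        ref = rrna_by_key[(taxon, gc_key)]
                        length = min(length, len(ref.seq))
                        start = int(rng.integers(0, len(ref.seq) - length + 1))
                        seq = _mutate_nt(rng, ref.seq[start : start + length], config.mutation_rate)
                        category, source = "rrna", ref.id
                    elif rng.random() < config.novel_fraction:
                        seq = _random_nt(rng, length, gc)
                        category = "novel"
                    else:
                        ref = rng.choice(mrna_by_key[(taxon, gc_key)])
                        length = min(length, len(ref.seq))
                        start = int(rng.integers(0, len(ref.seq) - length + 1))
                        seq = _mutate_nt(rng, ref.seq[start : start + length], config.mutation_rate)
                        source = ref.id
                    if fraction == "mRNA" and taxon not in config.prokaryotic_taxa:
                        lo, hi = config.polyA_len_range
                        seq = seq + "A" * int(rng.integers(lo, hi + 1))
                    reads.append(Unigene(id=rid, seq=seq, sample=prof.sample_id))
                    read_rows.append(
                        {
                            "read_id": rid, "sample": prof.sample_id,
                            "fraction": fraction, "taxon": taxon,
                            "category": category, "length": len(seq),
                            "source_ref": source, "frame": 0,
                        }
                    )

        # planted CTLD transcripts: one family per transcript, derived from
        # a per-sample base domain so samples separate in the tree
        if prof.n_planted_ctld or prof.n_negative_controls:
            base_ref = ctld_refs[s_idx % len(ctld_refs)].seq
            sample_base = mutate_peptide(rng, base_ref, 0.10, grammar)
            families = [
                vary_wigl(rng, mutate_peptide(rng, sample_base, 0.14, grammar), grammar)
                for _ in range(prof.n_planted_ctld)
            ]
            extra = np.zeros(prof.n_planted_ctld, dtype=int)
            for c in range(prof.n_redundant_copies):
                extra[c % max(prof.n_multidomain, 1)] += 1
            for t, fam in enumerate(families):
                copies = [fam] + near_duplicates(rng, fam, int(extra[t]), grammar)
                rid = f"{prof.sample_id}_ctld{t:02d}"
                read, frame, recs = _plant_transcript(
                    rng, config, grammar, copies, rid, prof.sample_id
                )
                reads.append(Unigene(id=rid, seq=read, sample=prof.sample_id))
                read_rows.append(
                    {
                        "read_id": rid, "sample": prof.sample_id, "fraction": "mRNA",
                        "taxon": taxa[0], "category": "ctld", "length": len(read),
                        "source_ref": "", "frame": frame,
                    }
                )
                for r in recs:
                    r["family"] = t
                domain_rows.extend(recs)
            for t in range(prof.n_negative_controls):
                neg = _negative_domain(rng, mutate_peptide(rng, sample_base, 0.12, grammar), grammar)
                frame = int(rng.choice([1, 2, 3, -1, -2, -3]))
                pep = _random_aa(rng, 8) + neg + _random_aa(rng, 8)
                nt = reverse_translate(pep)
                k = abs(frame)
                forward = "G" * (k - 1) + nt
                read = (forward if frame > 0 else reverse_complement(forward))
                rid = f"{prof.sample_id}_neg{t:02d}"
                reads.append(Unigene(id=rid, seq=read, sample=prof.sample_id))
                read_rows.append(
                    {
                        "read_id": rid, "sample": prof.sample_id, "fraction": "mRNA",
                        "taxon": taxa[0], "category": "ctld_negative",
                        "length": len(read), "source_ref": "", "frame": frame,
                    }
                )
        samples[prof.sample_id] = reads

    truth_reads = pd.DataFrame(
        read_rows,
        columns=[
            "read_id", "sample", "fraction", "taxon", "category",
            "length", "source_ref", "frame",
        ],
    )
    truth_domains = pd.DataFrame(
        domain_rows,
        columns=[
            "read_id", "sample", "family", "frame", "start", "end",
            "cys_positions", "wigl", "sugar_motif", "sugar_class", "domain_seq",
        ],
    )
    return SimulationResult(
        config=config,
        samples=samples,
        rrna_refs=rrna_refs,
        mrna_refs=mrna_refs,
        ctld_refs=ctld_refs,
        truth_reads=truth_reads,
        truth_domains=truth_domains,
    )


def default_config(seed: int = 0, reads_per_sample: int = 120) -> SimulationConfig:
    """The package's standard study design: three photosymbiotic holobionts
    carrying planted CTLDs (the radiolarian-like sample at the 28-domain /
    8-family scale) and one non-symbiotic sample without any."""
    bacteria = {"Gammaproteobacteria": 0.45, "Bacteroidetes": 0.38}
    profiles = [
        SampleProfile(
            sample_id="A_elongata",
            taxon_mix={
                "Acantharea": 0.40, "Haptophyta": 0.18, "Gammaproteobacteria": 0.12,
                "Bacteroidetes": 0.05, "Metazoa": 0.15, "Fungi": 0.10,
            },
            gc_by_taxon={
                "Acantharea": 0.463, "Haptophyta": 0.52, "Metazoa": 0.44,
                "Fungi": 0.48, **bacteria,
            },
            rrna_fraction=0.029,
            n_planted_ctld=2,
        ),
        SampleProfile(
            sample_id="Collozoum_sp",
            taxon_mix={
                "Polycystinea": 0.40, "Dinophyceae": 0.18, "Gammaproteobacteria": 0.10,
                "Bacteroidetes": 0.07, "Metazoa": 0.15, "Fungi": 0.10,
            },
            gc_by_taxon={
                "Polycystinea": 0.44, "Dinophyceae": 0.50, "Metazoa": 0.44,
                "Fungi": 0.48, **bacteria,
            },
            rrna_fraction=0.0034,
            n_planted_ctld=2,
        ),
        SampleProfile(
            sample_id="S_streptacantha",
            taxon_mix={
                "Polycystinea": 0.42, "Dinophyceae": 0.15, "Gammaproteobacteria": 0.12,
                "Bacteroidetes": 0.05, "Metazoa": 0.16, "Fungi": 0.10,
            },
            gc_by_taxon={
                "Polycystinea": 0.509, "Dinophyceae": 0.50, "Metazoa": 0.44,
                "Fungi": 0.48, **bacteria,
            },
            rrna_fraction=0.047,
            n_planted_ctld=8,
            n_multidomain=4,
            n_redundant_copies=20,
        ),
        SampleProfile(
            sample_id="A_scolymantha",
            taxon_mix={
                "Cercozoa": 0.50, "Gammaproteobacteria": 0.12, "Bacteroidetes": 0.08,
                "Metazoa": 0.18, "Fungi": 0.12,
            },
            gc_by_taxon={
                "Cercozoa": 0.406, "Metazoa": 0.44, "Fungi": 0.48, **bacteria,
            },
            rrna_fraction=0.0096,
            n_planted_ctld=0,
        ),
    ]
    return SimulationConfig(per_sample=profiles, seed=seed, reads_per_sample=reads_per_sample)
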
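"""Summary tables, GC-distribution comparison, keyword scans and the
end-to-end pipeline driver.

Keyword matching here is plain case-insensitive substring search: the
annotation descriptions scanned are free-text protein titles, unlike the
token-sensitive rRNA keyword rule in :mod:`holoest.partition`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import clustering, ctld, homology, phylo, preprocess, taxonomy
from .datasets import load_demo_taxonomy
from .partition import PartitionRule, partition
from .seqio import SimilarityHit, Unigene, write_fasta, write_hits
from .synthio import SimulationConfig, SimulationResult, simulate

SYMBIOSIS_KEYWORDS: dict[str, tuple[str, ...]] = {
    "glutamate dehydrogenase": ("glutamate dehydrogenase",),
    "glutathione S-transferase": ("glutathione s-transferase", "glutathione transferase"),
    "lectin": ("lectin",),
    "glutamine synthetase": ("glutamine synthetase",),
    "lipase": ("lipase",),
    "phospholipase": ("phospholipase",),
    "ferritin": ("ferritin",),
}

LECTIN_KEYWORDS: dict[str, tuple[str, ...]] = {
    "c-type lectin": ("c-type lectin",),
    "g-type lectin": ("g-type lectin",),
    "galectin": ("galectin",),
    "fucolectin": ("fucolectin",),
    "mannose binding lectin": ("mannose binding lectin",),
    "rhamnose binding lectin": ("rhamnose binding lectin",),
    "ricin b lectin": ("ricin b lectin",),
    "selectin": ("selectin",),
}


def keyword_scan(
    annotations: Sequence[tuple[str, str, str]],
    keyword_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Count annotated unigenes per category and sample.

    ``annotations`` are (unigene_id, sample, description) triples; a
    unigene counts at most once per category (first matching phrase), and a
    Total row sums the categories.
    """
    samples = sorted({s for _, s, _ in annotations})
    counted: dict[str, set[tuple[str, str]]] = {cat: set() for cat in keyword_sets}
    for uid, sample, desc in annotations:
        lower = desc.lower()
        for cat, phrases in keyword_sets.items():
            if any(p.lower() in lower for p in phrases):
                counted[cat].add((sample, uid))
    table = pd.DataFrame(
        {
            s: [sum(1 for smp, _ in counted[cat] if smp == s) for cat in keyword_sets]
            for s in samples
        },
        index=list(keyword_sets),
        dtype=int,
    )
    total = table.sum(axis=0)
    total.name = "Total"
    return pd.concat([table, total.to_frame().T])


def gc_compare(
    groups: Mapping[str, Sequence[float]], bin_width: float = 0.01
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], dict[tuple[str, str], float]]:
    """Normalised GC histograms per group and the two-sample KS statistic
    for every group pair (statistic only; no p-value is attached)."""
    for label, values in groups.items():
        if len(values) == 0:
            raise ValueError(f"group {label!r} is empty")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hists = {
        label: (edges, np.histogram(values, bins=edges, density=True)[0])
        for label, values in groups.items()
    }
    labels = sorted(groups)
    ks = {
        (a, b): float(sps.ks_2samp(groups[a], groups[b]).statistic)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    return hists, ks


@dataclass
class PipelineParams:
    min_len: int = 200
    polya_min_run: int = 10
    partition_rule: PartitionRule = field(default_factory=PartitionRule)
    nt_min_score: float = 40.0
    protein_min_score: float = 55.0
    lca_top_percent: float = 10.0
    lca_min_score: float = 40.0
    cluster_threshold: float = 0.5
    ctld_identity_threshold: float = 0.97
    curation: phylo.CurationParams = field(
        default_factory=lambda: phylo.CurationParams(max_gap_fraction=0.2, min_conservation=0.3)
    )
    run_clustering: bool = True


@dataclass
class ReportBundle:
    simulation: SimulationResult
    cleaned: dict[str, list[Unigene]]
    nt_hits: list[SimilarityHit]
    partition_labels: dict[str, str]
    count_table: pd.DataFrame
    percent_rhizaria: dict[tuple[str, str], float]
    venn: dict[frozenset[str], int] | None
    private_fraction: dict[str, float] | None
    protein_hits: list[SimilarityHit]
    domains: list[ctld.CTLDomain]
    unique_domains: dict[str, list[ctld.CTLDomain]]
    wigl: dict[str, set[str]]
    lectin_table: pd.DataFrame | None
    gc_ks: dict[tuple[str, str], float]
    tree_newick: str | None
    log: list[str]


def _write_domains_tsv(domains: Sequence[ctld.CTLDomain], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "unigene\tsample\tframe\tstart\tend\tcys_positions\twigl\t"
            "sugar_motif\tsugar_class\tdomain_seq\n"
        )
        for d in domains:
            fh.write(
                f"{d.unigene_id}\t{d.sample}\t{d.frame:+d}\t{d.start}\t{d.end}\t"
                f"{','.join(map(str, d.cys_positions))}\t{d.wigl}\t"
                f"{d.sugar_motif}\t{d.sugar_class}\t{d.domain_seq}\n"
            )


def run_pipeline(
    config_or_sim: SimulationConfig | SimulationResult,
    outdir: str | Path,
    params: PipelineParams | None = None,
) -> ReportBundle:
    """Run the full analysis: simulate (unless given a finished simulation),
    clean, partition, classify, cluster, mine CTLDs, build the tree, and
    write every intermediate plus a JSON manifest into ``outdir``."""
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage: {name}")

    try:
        if isinstance(config_or_sim, SimulationResult):
            sim = config_or_sim
        else:
            stage("simulate")
            sim = simulate(config_or_sim)
            sim.write(outdir / "simulated")
        seed = sim.config.seed

        stage("clean")
        cleaned: dict[str, list[Unigene]] = {}
        for sample_id, reads in sim.samples.items():
            kept, removed = preprocess.clean(
                reads, min_len=params.min_len, polya_min_run=params.polya_min_run
            )
            cleaned[sample_id] = kept
            log.append(f"clean[{sample_id}]: kept {len(kept)}, removed {len(removed)}")
            write_fasta(kept, outdir / f"clean_{sample_id}.fasta")
        all_clean = [u for reads in cleaned.values() for u in reads]

        stage("nucleotide search")
        nt_scheme = homology.ScoringScheme.nucleotide()
        nt_hits = homology.search(
            all_clean, sim.nucleotide_refs(), nt_scheme,
            min_score=params.nt_min_score, prescreen=True,
        )
        write_hits(nt_hits, outdir / "hits_nt.tsv", with_taxon=True)

        stage("partition")
        part = partition(all_clean, nt_hits, params.partition_rule)
        with open(outdir / "partition_labels.tsv", "w") as fh:
            fh.write("unigene\tsample\tlabel\n")
            for u in all_clean:
                fh.write(f"{u.id}\t{u.sample}\t{part.labels[u.id]}\n")
        for label in ("rRNA", "mRNA"):
            write_fasta(
                [u for u in all_clean if part.labels[u.id] == label],
                outdir / f"{label.lower()}_unigenes.fasta",
            )
        mrna = [u for u in all_clean if part.labels[u.id] == "mRNA"]

        stage("taxonomy")
        taxmap = load_demo_taxonomy()
        hits_by_query: dict[str, list[SimilarityHit]] = {}
        for h in nt_hits:
            hits_by_query.setdefault(h.query_id, []).append(h)
        assignments = [
            taxonomy.Assignment(
                unigene_id=u.id,
                sample=u.sample,
                fraction=part.labels[u.id],
                taxon=taxonomy.lca_assign(
                    hits_by_query.get(u.id, []), taxmap,
                    params.lca_top_percent, params.lca_min_score,
                ),
            )
            for u in all_clean
        ]
        table = taxonomy.count_table(
            assignments, taxmap, group_rows=("Bacteria", "Rhizaria", "Eukaryota")
        )
        table.to_csv(outdir / "taxon_counts.tsv", sep="\t")
        percent_rhizaria: dict[tuple[str, str], float] = {}
        if "Total Rhizaria" in table.index:
            for col in table.columns:
                if table.loc[taxonomy.TOTAL, col] > 0:
                    percent_rhizaria[col] = taxonomy.percent_of_total(
                        table, "Total Rhizaria", *col
                    )

        stage("gc comparison")
        gc_groups = {
            s: [u.gc for u in reads] for s, reads in cleaned.items() if reads
        }
        gc_ks = gc_compare(gc_groups)[1] if len(gc_groups) > 1 else {}

        venn = private = None
        if params.run_clustering and mrna:
            stage("clustering")
            translations = {u.id: homology.six_frame_translate(u.seq) for u in mrna}
            sample_of = {u.id: u.sample for u in mrna}
            peptides = clustering.six_frame_peptides(translations, sample_of)
            cluster_set = clustering.greedy_cluster(peptides, params.cluster_threshold)
            venn, private = clustering.venn_counts(cluster_set)
            with open(outdir / "venn_counts.tsv", "w") as fh:
                fh.write("samples\tclusters\n")
                for key in sorted(venn, key=lambda k: (len(k), sorted(k))):
                    fh.write(f"{'+'.join(sorted(key))}\t{venn[key]}\n")
        elif not mrna:
            log.append("clustering skipped: no mRNA unigenes")

        stage("ctld search")
        protein_hits: list[SimilarityHit] = []
        domains: list[ctld.CTLDomain] = []
        unique: dict[str, list[ctld.CTLDomain]] = {}
        lectin_table = None
        tree_newick = None
        if mrna:
            prot_scheme = homology.ScoringScheme.protein()
            protein_hits = homology.search(
                mrna, sim.ctld_refs, prot_scheme, min_score=params.protein_min_score
            )
            write_hits(protein_hits, outdir / "hits_ctld.tsv")
            # hits act as a tblastn-like pre-filter selecting candidate
            # (unigene, frame) pairs; the grammar then scans the whole frame
            # peptide so every domain of a multidomain transcript is split out
            seeds: set[tuple[str, int]] = {
                (h.query_id, h.frame) for h in protein_hits
            }
            sample_of_mrna = {u.id: u.sample for u in mrna}
            seq_of = {u.id: u.seq for u in mrna}
            for uid, frame in sorted(seeds):
                peptide = homology.six_frame_translate(seq_of[uid])[frame]
                domains.extend(
                    ctld.scan(
                        peptide, unigene_id=uid,
                        sample=sample_of_mrna[uid], frame=frame,
                    )
                )
            _write_domains_tsv(domains, outdir / "ctld_domains.tsv")
            stage("ctld dedupe")
            for sample_id in sim.samples:
                sample_domains = [d for d in domains if d.sample == sample_id]
                if sample_domains:
                    unique[sample_id] = ctld.dedupe(
                        sample_domains, params.ctld_identity_threshold
                    )
            all_unique = [d for ds in unique.values() for d in ds]
            write_fasta(
                [Unigene(id=d.id, seq=d.domain_seq, sample=d.sample) for d in all_unique],
                outdir / "ctld_unique.fasta",
            )
            annotations = [
                (h.query_id, sample_of_mrna[h.query_id], h.subject_description)
                for h in protein_hits
            ]
            if annotations:
                lectin_table = keyword_scan(annotations, LECTIN_KEYWORDS)
                lectin_table.to_csv(outdir / "lectin_keyword_counts.tsv", sep="\t")

            if len(all_unique) >= 3:
                stage("phylogeny")
                msa = phylo.progressive_align(
                    [(d.id, d.domain_seq) for d in all_unique]
                )
                curated, kept = phylo.curate_blocks(msa, params.curation)
                use = curated if len(kept) >= 20 else msa
                if len(kept) < 20:
                    log.append(
                        f"curation kept only {len(kept)} columns; tree built on full alignment"
                    )
                tree = phylo.nj_tree(phylo.distance_matrix(use))
                tree_newick = str(tree).strip()
                (outdir / "ctld_tree.nwk").write_text(tree_newick + "\n")
        else:
            log.append("ctld stages skipped: no mRNA unigenes")

        stage("manifest")
        manifest = {
            "seed": seed,
            "n_samples": len(sim.samples),
            "reads_per_sample": sim.config.reads_per_sample,
            "params": {
                "min_len": params.min_len,
                "nt_min_score": params.nt_min_score,
                "protein_min_score": params.protein_min_score,
                "cluster_threshold": params.cluster_threshold,
                "ctld_identity_threshold": params.ctld_identity_threshold,
            },
            "counts": {
                "cleaned": {s: len(r) for s, r in cleaned.items()},
                "rRNA": sum(1 for lab in part.labels.values() if lab == "rRNA"),
                "mRNA": sum(1 for lab in part.labels.values() if lab == "mRNA"),
                "domains": len(domains),
                "unique_domains": {s: len(d) for s, d in unique.items()},
            },
            "versions": {"holoest": __import__("holoest").__version__},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    except Exception as exc:
        current = log[-1] if log else "startup"
        raise RuntimeError(f"pipeline failed at {current!r}: {exc}") from exc

    return ReportBundle(
        simulation=sim,
        cleaned=cleaned,
        nt_hits=nt_hits,
        partition_labels=part.labels,
        count_table=table,
        percent_rhizaria=percent_rhizaria,
        venn=venn,
        private_fraction=private,
        protein_hits=protein_hits,
        domains=domains,
        unique_domains=unique,
        wigl=ctld.wigl_variants([d for ds in unique.values() for d in ds]),
        lectin_table=lectin_table,
        gc_ks=gc_ks,
        tree_newick=tree_newick,
        log=log,
    )
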
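#!/usr/bin/env python
"""Clean the simulated libraries and split them into rRNA and mRNA.

Reads results/simulated/, trims poly-A/poly-T tails, drops sequences under
200 bp, runs the built-in nucleotide similarity search against the packaged
mock references and applies the keyword + >80% identity + >100 bp rule.
Writes cleaned FASTA, the hit table and the partition labels.
"""

import argparse
from pathlib import Path

from holoest import homology, preprocess
from holoest.partition import PartitionRule, partition
from holoest.seqio import read_fasta, write_fasta, write_hits


def load_references(path: Path):
    refs = []
    for rec in read_fasta(path):
        taxon = rec.id.rsplit("_gc", 1)[0]
        refs.append(
            homology.Reference(
                id=rec.id, seq=rec.seq, description=rec.description, taxon=taxon
            )
        )
    return refs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    simdir = args.outdir / "simulated"
    outdir = args.outdir / "partition"
    outdir.mkdir(parents=True, exist_ok=True)

    cleaned = []
    for fasta in sorted(simdir.glob("*.fasta")):
        if fasta.name.startswith("references"):
            continue
        sample = fasta.stem
        reads = read_fasta(fasta, sample=sample)
        kept, removed = preprocess.clean(reads)
        print(f"{sample}: kept {len(kept)} / {len(reads)} after cleaning")
        write_fasta(kept, outdir / f"clean_{sample}.fasta")
        cleaned.extend(kept)

    refs = load_references(simdir / "references_nt.fasta")
    hits = homology.search(
        cleaned, refs, homology.ScoringScheme.nucleotide(), min_score=40, prescreen=True
    )
    write_hits(hits, outdir / "hits_nt.tsv", with_taxon=True)

    result = partition(cleaned, hits, PartitionRule())
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("unigene\tsample\tlabel\n")
        for u in cleaned:
            fh.write(f"{u.id}\t{u.sample}\t{result.labels[u.id]}\n")
    counts = result.per_sample_counts(cleaned)
    for sample, c in sorted(counts.items()):
        print(f"{sample}: {c['rRNA']} rRNA, {c['mRNA']} putative mRNA")
    print(f"wrote {outdir}/")


if __name__ == "__main__":
    main()
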
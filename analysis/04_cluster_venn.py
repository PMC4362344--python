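#!/usr/bin/env python
"""Cross-sample protein clustering and Venn accounting.

Translates every putative-mRNA unigene into its six reading frames,
clusters the frame peptides greedily at 50% identity (CD-HIT semantics)
and counts how many clusters are private to one sample versus shared.
"""

import argparse
from pathlib import Path

import pandas as pd

from holoest import clustering, homology
from holoest.seqio import read_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=0.5)
    args = ap.parse_args()
    part = args.outdir / "partition"
    outdir = args.outdir / "clustering"
    outdir.mkdir(parents=True, exist_ok=True)

    labels = pd.read_csv(part / "labels.tsv", sep="\t")
    mrna_ids = set(labels.query("label == 'mRNA'").unigene)
    unigenes = []
    for fasta in sorted(part.glob("clean_*.fasta")):
        sample = fasta.stem.removeprefix("clean_")
        unigenes.extend(u for u in read_fasta(fasta, sample=sample) if u.id in mrna_ids)

    translations = {u.id: homology.six_frame_translate(u.seq) for u in unigenes}
    sample_of = {u.id: u.sample for u in unigenes}
    peptides = clustering.six_frame_peptides(translations, sample_of)
    print(f"clustering {len(peptides)} frame peptides from {len(unigenes)} unigenes ...")
    cs = clustering.greedy_cluster(peptides, args.threshold)
    venn, private = clustering.venn_counts(cs)

    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster\tmember\tsample\trepresentative\n")
        for i, cl in enumerate(cs.clusters):
            for p in cl.members:
                fh.write(f"{i}\t{p.id}\t{p.sample}\t{int(p.id == cl.representative)}\n")
    with open(outdir / "venn.tsv", "w") as fh:
        fh.write("samples\tclusters\n")
        for key in sorted(venn, key=lambda k: (len(k), sorted(k))):
            fh.write(f"{'+'.join(sorted(key))}\t{venn[key]}\n")

    print(f"{len(cs)} clusters at {args.threshold:.0%} identity")
    all_samples = sorted(private)
    shared_all = venn.get(frozenset(all_samples), 0)
    print(f"shared by all {len(all_samples)} samples: {shared_all}")
    for s in all_samples:
        print(f"  {s}: {private[s]:.0%} of its clusters are private")
    print(f"wrote {outdir}/")


if __name__ == "__main__":
    main()
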
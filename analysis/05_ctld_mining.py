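#!/usr/bin/env python
"""Mine C-type lectin domains from the putative mRNA.

A tblastn-like translated search against the packaged reference CTLD
peptides pre-selects candidate (unigene, frame) pairs; the cysteine/WIGL
grammar then scans those frame peptides, splits multidomain transcripts,
deduplicates near-identical copies per sample (>= 97% identity) and
tabulates the WIGL-like variants and sugar-binding motifs.
"""

import argparse
from pathlib import Path

import pandas as pd

from holoest import ctld, homology
from holoest.seqio import read_fasta, write_hits


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--min-score", type=float, default=55.0)
    args = ap.parse_args()
    part = args.outdir / "partition"
    simdir = args.outdir / "simulated"
    outdir = args.outdir / "ctld"
    outdir.mkdir(parents=True, exist_ok=True)

    labels = pd.read_csv(part / "labels.tsv", sep="\t")
    mrna_ids = set(labels.query("label == 'mRNA'").unigene)
    unigenes = []
    for fasta in sorted(part.glob("clean_*.fasta")):
        sample = fasta.stem.removeprefix("clean_")
        unigenes.extend(u for u in read_fasta(fasta, sample=sample) if u.id in mrna_ids)
    refs = [
        homology.Reference(id=r.id, seq=r.seq, description=r.description)
        for r in read_fasta(simdir / "references_ctld.fasta")
    ]

    hits = homology.search(
        unigenes, refs, homology.ScoringScheme.protein(), min_score=args.min_score
    )
    write_hits(hits, outdir / "hits_ctld.tsv")
    sample_of = {u.id: u.sample for u in unigenes}
    seq_of = {u.id: u.seq for u in unigenes}
    domains = []
    for uid, frame in sorted({(h.query_id, h.frame) for h in hits}):
        pep = homology.six_frame_translate(seq_of[uid])[frame]
        domains.extend(
            ctld.scan(pep, unigene_id=uid, sample=sample_of[uid], frame=frame)
        )
    print(f"{len({h.query_id for h in hits})} unigenes with CTLD similarity; "
          f"{len(domains)} domains after splitting")

    rows = []
    for sample in sorted({d.sample for d in domains}):
        sample_domains = [d for d in domains if d.sample == sample]
        unique = ctld.dedupe(sample_domains, 0.97)
        wigls = sorted({d.wigl for d in unique})
        sugars = sorted({f"{d.sugar_motif}({d.sugar_class})" for d in unique})
        print(f"  {sample}: {len(sample_domains)} domains -> {len(unique)} unique; "
              f"WIGL-like {','.join(wigls)}; sugar motifs {','.join(sugars)}")
        for d in unique:
            rows.append({
                "id": d.id, "sample": d.sample, "unigene": d.unigene_id,
                "frame": d.frame, "start": d.start, "end": d.end,
                "wigl": d.wigl, "sugar_motif": d.sugar_motif,
                "sugar_class": d.sugar_class, "domain_seq": d.domain_seq,
            })
    pd.DataFrame(rows).to_csv(outdir / "unique_domains.tsv", sep="\t", index=False)
    print(f"wrote {outdir}/")


if __name__ == "__main__":
    main()
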
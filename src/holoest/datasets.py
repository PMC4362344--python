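"""Packaged demonstration data.

* a small hand-built taxonomy covering the groups that occur in rhizarian
  holobiont libraries (host lineages, common photosymbionts, dominant
  bacterial classes, bystander eukaryotes);
* published per-library summary counts for the four holobiont EST
  libraries (A. elongata, Collozoum sp., S. streptacantha,
  A. scolymantha), used as inputs for the table arithmetic;
* a constructed ("synthetic", see the FASTA headers) reference set of
  C-type lectin domain peptides that seeds the translated search and
  anchors sugar-motif localisation.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from .homology import Reference
from .seqio import TaxonomyMap, read_fasta, read_taxonomy


def data_path(name: str) -> Path:
    return Path(str(resources.files("holoest").joinpath("data", name)))


@lru_cache(maxsize=1)
def load_demo_taxonomy() -> TaxonomyMap:
    return read_taxonomy(data_path("demo_taxonomy.tsv"))


@lru_cache(maxsize=1)
def load_reference_ctlds() -> list[Reference]:
    records = read_fasta(data_path("reference_ctld_synthetic.fasta"))
    return [
        Reference(id=r.id, seq=r.seq, description=r.description) for r in records
    ]


@lru_cache(maxsize=1)
def reference_anchor() -> tuple[str, int]:
    """The anchor domain for sugar-motif localisation: the first packaged
    reference carrying EPN, as (domain sequence, motif offset)."""
    from . import ctld as ctld_mod

    for ref in load_reference_ctlds():
        domains = ctld_mod.scan(ref.seq)
        for d in domains:
            if d.sugar_motif == "EPN":
                motif_at = d.domain_seq.find(
                    "EPN", d.cys_positions[1] - d.cys_positions[0] + 1
                )
                if motif_at >= 0:
                    return d.domain_seq, motif_at
    raise RuntimeError("no EPN-bearing reference domain packaged")


@lru_cache(maxsize=1)
def load_published_taxon_counts() -> pd.DataFrame:
    """Published taxonomic summary counts, rows x (sample, fraction)."""
    long = pd.read_csv(data_path("published_taxon_counts.tsv"), sep="\t")
    table = long.pivot_table(
        index="row", columns=["sample", "fraction"], values="count",
        aggfunc="first", sort=False,
    )
    return table


@lru_cache(maxsize=1)
def load_published_assembly_stats() -> pd.DataFrame:
    """Published per-library sequencing/assembly statistics (metric rows,
    sample columns)."""
    long = pd.read_csv(data_path("published_assembly_stats.tsv"), sep="\t")
    return long.pivot_table(
        index="metric", columns="sample", values="value", aggfunc="first", sort=False
    )
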
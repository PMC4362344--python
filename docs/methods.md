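# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
design decisions taken where the workflow left genuine freedom.

## Cleaning

Poly-A tails (and, symmetrically, leading poly-T runs from reverse-strand
priming) are trimmed by a declared rule: the longest suffix that starts
with A, is at least `min_run = 10` nt long and contains at most one
non-A per 10 nt (floor) is removed, taking the *leftmost* valid start so
that trimming is idempotent.  Seqclean-style quality heuristics are out of
scope; adapter removal is exact prefix/suffix matching only.  The length
filter removes sequences *shorter than* 200 bp — a 200 bp sequence is
kept.  Medians of even-sized sets are the mean of the two central values.

## Similarity search

`homology` is an exact local aligner standing in for a BLAST service at
desk scale.  Defaults: BLOSUM62 with gap open 10 / extend 1 for proteins,
match +2 / mismatch −2 with gap open 5 / extend 2 for nucleotides (a gap of
length k costs open + k·extend).  E-values are not computed; a raw-score
threshold substitutes, and the hit's `bitscore` field carries the raw
Smith–Waterman score.  Translated (tblastn-like) searches split each frame
at stop codons into ORF segments of ≥ 20 aa before aligning, and record
the frame in the hit.  Equal-scoring hits order by subject id.  An
optional exact k-mer prescreen (11-mers, two-hit rule) accelerates
nucleotide searches; it is off by default because a borderline hit pair
sharing fewer than two words would be skipped, and it is enabled inside
the pipeline where the references are long enough for the two-hit rule to
be conservative in practice.

## rRNA/mRNA partition

The keyword list is fixed (13 phrases).  Matching is case-insensitive
substring search, except the three short abbreviations ITS, LSU and SSU,
which match case-sensitively as whole tokens (delimited by
non-alphanumerics) so that "its" or "sites" cannot fire; whether the
original screening was case-sensitive is not documented anywhere, so this
is a declared choice.  Bare "ribosomal protein" descriptions do not
qualify because "ribosomal" alone is not on the list.  Identity and
length thresholds are strict (>80%, >100 bp); inclusive comparison is
available via `PartitionRule(strict=False)`.  Any single qualifying hit
makes a unigene ribosomal; everything else, including unigenes without
hits, is putative mRNA.

## Taxonomic binning

MEGAN-style LCA with declared defaults: hits scoring at least
`min_score` (50 protein / 40 nucleotide) and within `top_percent = 10` of
the best hit contribute their subject taxa; the assignment is the lowest
common ancestor in the packaged demonstration taxonomy (a small hand-built
tree containing the bacterial classes, rhizarian and alveolate lineages
and bystander eukaryote groups the count tables use).  No hits → "No
hits"; hits all below threshold → "Not assigned".  Percent rows are
formatted by a rounding rule reverse-engineered from how such tables are
printed — half-up to an integer at ≥ 1%, half-up to one decimal below 1% —
and applies to presentation only; raw floats are kept internally.

## Clustering

CD-HIT semantics, re-implemented exactly rather than heuristically:
sequences are visited by decreasing length (id as tie-break) and each
joins the first cluster whose representative matches at ≥ 50% identity,
else founds a new cluster.  Identity is *identical residues / length of
the shorter sequence*, counted on the optimal-score semi-global alignment
(BLOSUM62, affine gaps, terminal gaps free); among co-optimal alignments
the dynamic programme maximises the identity count directly (lexicographic
(score, identities) objective), which makes the measure a deterministic
function of the sequence pair.  A pure LCS ("free gap") identity was
rejected: with no gap cost a long translation absorbs every shorter
peptide, collapsing the cluster structure.  Two exact upper bounds screen
pairs first — identities ≤ LCS, and LCS ≤ (m + n − d)/2 for unit-cost
edit distance d — so the affine table is only filled for borderline pairs.
All six frames of each unigene enter clustering as separate peptides;
clusters are collapsed to unigene level (membership via any frame) for
Venn counting, which assigns each cluster to exactly one sample subset.

## CTLD grammar

A domain is four conserved cysteines with residues-between gaps inside
inclusive bounds [(5, 60), (20, 90), (5, 40)] plus a WIGL-like 4-mer
(W, [ILV], G, [ILVF]) strictly between C1 and C3.  The spacing bounds are
a declared default chosen to admit compact CTLD architectures while
rejecting random cysteine scatter; the generator plants domains compatible
with them so no result hinges on the exact values.  When a region holds
more than four cysteines the scanner enumerates quadruples
leftmost-compact (C1, then C2, C3, C4 ascending) and accepts the first
satisfying all constraints; scanning resumes after C4, so reported
domains never overlap and multidomain transcripts are split
deterministically.  Sugar classification searches the C2–C4 region for
EPN (glucose/mannose) then LND (galactose); any other motif is read off
the alignment column of the packaged reference domain (global anchored
alignment, BLOSUM62 open 11 extend 1), because the motif is defined
positionally by alignment rather than by offset.  Deduplication collapses
domains greedily at ≥ 97% identity keeping the longest member — the exact
collapse threshold used originally is not documented; 0.97 is the declared
default and the generator's copy divergence (single-site variants) sits
well above it while family divergence sits well below.

In the pipeline the translated search acts as a pre-filter that selects
candidate (unigene, frame) pairs; the grammar then scans the whole frame
peptide.  Restricting the scan to hit windows is supported
(`scan(..., seed_hits=...)`) but not used by default because a local
alignment reports one best segment per reference, which would under-seed
multidomain transcripts; grammar-only scanning of a seeded frame finds a
superset of any seeded-window scan.

## Phylogeny

Progressive alignment uses a UPGMA guide tree over pairwise identity
distances and merges profiles by affine-gap Gotoh DP on mean
column-pair BLOSUM62 scores (gap-residue pairs contribute −1; open 10,
extend 1).  Curation reduces the Gblocks parameter set to three knobs:
maximum per-column gap fraction (default 0.0), minimum modal-residue
fraction (default 0.5) and minimum block length (default 10 columns);
kept columns are maximal runs passing both per-column rules.  Distances
are p-distances over columns ungapped in both rows, with an optional
Poisson correction −ln(1−p).  Trees come from Saitou–Nei neighbor
joining (scikit-bio) with negative branch lengths clamped to zero;
maximum-likelihood inference is deliberately out of scope, and branch
support, when requested, is a seeded nonparametric bootstrap over curated
columns rather than aLRT.  The pipeline relaxes curation to
max_gap_fraction 0.2 / min_conservation 0.3 for the domain alignment and
falls back to the full alignment when fewer than 20 columns survive,
since p-distances already ignore pairwise-gapped columns.

## Synthetic generator

`synthio` emulates the statistical structure the analysis assumes, not a
sequencing instrument.  Per sample: a taxon mixture (host, photosymbiont,
bacterial classes, bystander eukaryotes) with per-taxon GC targets; read
lengths from a truncated normal (mean 350, sd 90, min 150, max 1200 —
the minimum sits below the 200 bp filter on purpose); an rRNA fraction
drawn as windows of mock reference genes whose description lines carry
the rRNA keywords (16S for bacteria, 18S otherwise); mRNA reads drawn as
mutated windows of per-taxon mock transcripts (default substitution rate
0.02/site), with a configurable fraction (default 0.2) of "novel" reads
that match no reference and exercise the "No hits" path; poly-A tails of
10–30 nt on eukaryotic mRNA.  GC targets hold for the transcript body:
tails dilute read-level GC by roughly 5%, so GC recovery is checked on
poly-A-trimmed reads — which is also where the analysis computes GC.
Default sample profiles mirror the four-specimen study design, including
the 28-domains-in-8-families radiolarian-style sample and a non-symbiotic
sample with no planted domains; per-sample rRNA fractions (0.3–4.7%)
match the published library proportions.

Planted CTLD transcripts are assembled at the peptide level (C- and
W-free flanks and linkers, so the planted architecture is the only one in
frame), reverse-translated with a fixed codon table for determinism, and
embedded in a chosen reading frame; for negative frames the poly-A tail
is rounded up to a multiple of 3 so the planted frame's codon phase is
independent of tail length.  Truth coordinates are recorded against the
full read (after tail addition) and verified at generation time by
re-translation.  Families are derived per sample from one packaged
reference domain (10% divergence to the sample base, 14% per family, with
the WIGL variable positions re-drawn per family); redundant copies vary a
single architecture-safe site so all pairwise within-family identities
stay ≥ 0.97 by construction.  Negative controls are family-like peptides
with the fourth cysteine or the WIGL tryptophan destroyed.  One RNG
stream per (seed, sample) plus one for the shared references makes runs
bit-reproducible and samples independent.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: 454 homopolymer errors, chimeras, quality
scores, assembly artifacts, real codon usage and real protein families
(background peptides are translations of GC-biased random DNA, so
absolute cluster counts and private-cluster fractions are not comparable
to real libraries), and real taxonomic reference breadth (assignment
accuracy on the mock references is near-perfect by design; it measures
the LCA machinery, not database coverage).

## Packaged data

`data/published_assembly_stats.tsv` and `data/published_taxon_counts.tsv`
carry the published per-library summary statistics and taxonomic summary
counts of the four real libraries (A. elongata, Collozoum sp.,
S. streptacantha, A. scolymantha); they are inputs to the table
arithmetic, not outputs of this package.  `data/reference_ctld_synthetic.fasta`
is a constructed stand-in reference CTLD set (real coral/anemone/nematode
lectin sequences are not redistributable here); every entry is labelled
synthetic in its header.  `data/demo_taxonomy.tsv` is the hand-built
demonstration taxonomy.

## Problem sizes

The default analysis runs 60 background reads per sample and the test
suite and acceptance script 30–40, with planted-transcript counts fixed
by the study design (8 + 2 + 2 + 0 CTLD transcripts, 28 domains in the
large sample).  These desk-scale sizes are a package choice: every
algorithm is exact, so correctness properties (oracle equivalence,
coordinate-exact recovery, NJ exactness) do not depend on scale, and the
binomial-noise checks state their own n (e.g. 2000 reads/taxon for GC
recovery).

## Known limitations

* The partition rule inherits the keyword list's blind spots: an rRNA
  unigene whose best references lack the keywords is called mRNA.
* Identity-based clustering at 50% on six-frame translations includes
  stop-riddled junk frames by design (as the original protocol did);
  biological interpretation belongs at the cluster-count level only.
* The anchored-alignment localisation of variant sugar motifs depends on
  the packaged reference domain; a domain highly diverged from the anchor
  can yield a shifted variant tripeptide.
* NJ on p-distances is a stand-in for maximum likelihood; topologies for
  deeply diverged families should be treated as qualitative.
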
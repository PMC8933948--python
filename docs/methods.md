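# Methods

## Structure models

A gene locus is held internally as a nucleotide string in transcription
orientation (minus-strand loci are reverse-complemented at load, so the
token grammar is orientation-free); all coordinates are 0-based half-open
in that frame, converted losslessly from the GTF's 1-based inclusive
genomic convention. Functional sites — start codon `[`, donor `<`,
acceptor `>`, stop codon `]` — are zero-length boundaries carrying a motif
(dinucleotide for splice sites, trinucleotide for start/stop); coding
blocks are half-open coding intervals. The stop codon is modelled inside
the terminal block: annotation dialects that exclude it from CDS features
(the default, Ensembl-style; `stop_in_cds` flips this) have the last CDS
exon extended by three nucleotides at load, so an assembled CDS always
ends with its stop trinucleotide and `is_valid_cds` can check start, frame,
internal stops and terminal stop on the plain concatenation.

The gene model is built from its known transcripts: site tokens are
deduplicated by (kind, position), coding coverage is the union of exon
intervals, and blocks are the coverage cut at every site position. This
re-segmentation makes every alternative 5'/3' exon extension a pair of
directly adjacent blocks and guarantees each transcript re-expresses as a
token subsequence. Transcripts implying two different reading frames for
one block raise a model-conflict error naming the transcripts; rare
legitimate dual-frame exons are therefore out of scope. Tokens anchored
at the same coordinate are ordered stop, donor, acceptor, start, block —
a fixed tie-break that yields the conventional spellings `]>` and `]<`.

## Pairwise comparison and prediction

Only tokens known at entry seed alignments; predictions never chain
across pairs. Known blocks of the source gene are aligned against the
target locus with a local pairwise aligner (Biopython's
`PairwiseAligner`) using match +2, mismatch −3, gap open −5, gap extend
−2. These scores, like the 0.70 block-identity threshold, are package
defaults chosen for reproducibility; all are configurable. Identity is
counted as alignment identities divided by *query* length, which makes a
short high-identity sub-match of a long block score poorly — the behaviour
wanted when probing whether a whole coding block survives in the other
genome. Block hits must conserve the reading-frame length offset
(mod 3); this alignment-time check can be disabled, in which case frame
violations are still caught by the executability test. Anchoring is
colinear: blocks are processed longest first and each search window is
bounded by the nearest already-anchored neighbours, which excludes
crossing anchors by construction and guards against paralogous exon
matches. Equal-score hits are broken toward the smallest target
coordinate and logged.

Functional sites are mapped through their attached block's anchor (a
site always delimits at least one known block); an acceptor/start maps to
the anchor's 5' edge, a donor/stop to its 3' edge. A mapped site is
accepted only if the target has a known same-kind site there or shows the
exact motif (GT donor, AG acceptor, configured start/stop sets);
non-canonical splice motifs are accepted in known annotations but
rejected for predictions unless `allow_noncanonical_predicted` is set.
Sites of unanchored blocks are reported unaligned — a motif-plus-context
aligner (`align_token`, 12 nt of flanking context per side) exists for
direct queries, but the pipeline deliberately does not use it as a
fallback: in diverged introns it manufactures spurious AG/GT hits that
fragment the block segmentation.

Anchor spans falling (partly) outside the target's annotated coding
coverage become predicted coverage; after all pairs run, each gene is
re-segmented over known + predicted sites and coverage. Predicted blocks
whose edges carry neither a site nor an adjacent block are pruned.
Token orthologies are then derived: site edges from the recorded
mappings, block edges by overlap (≥ 50 % of the shorter interval) between
anchor-mapped images and target blocks. Blocks are unified under one
letter per connected component of the orthology relation (union-find); a
merge that would force two blocks of one gene onto one letter drops the
offending orthology and reports it. Letters are assigned in species-order,
coordinate-order traversal; more than 26 components is an error — a
deliberate desk-scale bound of the single-letter grammar.

Site components holding at most one site per gene are closed into
complete cross-gene cliques: two sites independently predicted from a
common ortholog are orthologous to each other even though predicted
tokens never seed pairwise alignment. Without this closure a site known
in only one species could never classify as shared-by-three. Components
with two same-gene sites are left untouched and classify as irregular.

A transcript model is expressible in another gene when every token's
orthology component has a member there, and executable when the mapped
token chain is structurally consistent (adjacent blocks stay adjacent,
sites sit on the mapped exon boundaries) and the assembled target
sequence is a valid CDS. Predictions are deduplicated by unified model
string, carry the full ordered set of seeding species (first species in
`species_order` is the primary source), and get IDs `<gene>.predN` in
model-string lexicographic order for determinism.

## Graphs, classification, redundancy, evidence

The site graph covers sites involved in known and predicted transcripts —
predicted sites participate exactly as known ones. Triplet components
must be 3-cliques (three pairwise orthologies); a 3-node path and any
component with two same-species nodes are irregular. A gene triplet is
*retained* when no component is irregular, *structurally orthologous*
when all components are triplets. Transcript-graph edges are cross-gene
only; same-species redundancy surfaces through shared neighbours. A CDS
orthology group is a component spanning all three species; *all-conserved*
requires every component to span, *single-copy* additionally one
transcript per species per component. Redundant-CDS sets are per-species
groups (size ≥ 2) of known transcripts sharing a model string; transcripts
lacking a 5' or 3' UTR are excluded from that enumeration (their identical
CDS may reflect truncated annotation, not genuine alternative
transcription) and reported separately.

Evidence tagging is a strict precedence: `confirmed` on an exact ordered
coding-exon-chain match (genomic coordinates, UTRs ignored) in any
supplied annotation collection; else `possible` when the prediction has
no specific exon junction (one absent from every known transcript of the
whole input set, compared as genomic intron spans); else `achievable`
when all specific junctions have read support ≥ `min_reads` (default 1;
no threshold is inherent to the method), else `not_achievable`. Support
comes as a junction summary (5-column tab or BED6); read alignment itself
is out of scope.

## The synthetic generator

Fixtures declare a master grammar, per-species grammars (blocks physically
present), known transcript structures with UTR lengths, block lengths
(multiples of three, so every block subset preserves frame), intron
lengths, and identities. Coding blocks derive from one ancestral sequence
of stop-free codons with boundary motifs pinned (ATG at start-flanked
block heads, TAA at stop-flanked tails, CAG tails / GT heads where an
acceptor or donor sits on an exon-internal block boundary); per-species
copies are mutated codon-wise to the requested block identity (default
1.0) with pinned positions untouched and stop-creating substitutions
resampled. Introns mutate independently to a low identity (default 0.4),
preserving their GT/AG ends. Equal seeds give byte-identical files.

The generator emulates conserved coding blocks with divergent introns,
annotation asymmetry between species, UTR variants, genuine block loss,
and junction read summaries. It does **not** emulate indels inside coding
sequence (except one hand-built frame-shift test case), exon shuffling,
paralogy, non-canonical splice sites, split stop codons, or realistic
base composition — so passing tests demonstrate the correctness of the
orthology logic under its stated assumptions, not robustness to the full
messiness of real annotation. Real-data behaviour additionally depends on
the alignment parameters above.

## Problem sizes and numerics

The test suite and the acceptance script run the three worked-example
triplets (loci of roughly 0.5–0.7 kb, 3–6 blocks, 1–4 transcripts per
gene), 50 random single-gene fixtures for self-comparison identity,
1,000 random grammar strings for parse/format round-trip, exhaustive
subsequence enumeration as an independent oracle on gene models with at
most 12 tokens, and planted-orthology recovery at block identities 1.0,
0.9, 0.5 and 0.2 — sizes chosen so the whole suite completes in seconds
while every code path is exercised. Degenerate inputs are errors, not
silent repairs: empty CDSs, exons outside the locus, duplicate ortholog
map entries, malformed junction lines (reported with line number), and
grammar strings missing a start/stop (reported with character offset).

## Known limitations

Classification rules are specified for triplets; the data model allows
more species but singleton/couple/triplet classes do not generalize.
UTRs are never modelled as tokens and predictions are CDS-only. A CDS
predictable only through chained predictions (A predicts into B, B's
prediction into C) is not created, by design. Kozak-context quality of
predicted starts is not assessed.
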
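# spliceortho

Splicing-structure orthology across orthologous genes: identification of
genes with conserved splicing structure and prediction of orthologous
spliced CDS isoforms.

## The problem

Orthologous genes in related species (human, mouse, dog, ...) often
express several alternative transcripts, but annotation depth differs
wildly between species: a CDS isoform annotated in mouse may be perfectly
encodable by the human or dog gene without ever having been annotated
there. `spliceortho` formalizes *splicing-structure orthology* and uses it
to (i) detect orthologous splice sites, start and stop codons, (ii)
predict missing spliced CDS isoforms by comparative genomics, and (iii)
classify gene triplets by how completely their coding structure and
isoform repertoire are conserved.

## The model

The coding structure of a gene *i* is a *gene structure model*
M<sup>G</sup><sub>i</sub>: an ordered string of **tokens** — functional
sites (start codon `[`, splice donor `<`, splice acceptor `>`, stop codon
`]`) and lettered **coding blocks** (`A`, `B`, ...), the maximal coding
segments between consecutive sites. Each known transcript contributes a
*transcript structure model* M<sup>T</sup><sub>i,u</sub>, a token
subsequence describing one spliced CDS; the gene model is their ordered
union, e.g. `[A<>B<>C]>D]` for a gene expressing `[A<>B<>C]` and
`[A<>B<>D]`. Alternative 5'/3' exon extensions appear as directly
adjacent blocks (exon *BC* vs exon *C*).

Between two orthologous genes, every known coding block is locally
aligned against the other gene's sequence (colinear anchoring, longest
blocks first; match +2 / mismatch −3 / gap −5 / −2, identity ≥ 0.70,
frame-conserving). A hit on annotated sequence records a **token
orthology** A(K<sub>i,m</sub>, K<sub>j,n</sub>); a hit in unannotated
sequence with the exact splice/codon motif records a **predicted** token.
Orthologous blocks are unified under a single letter, so syntactic
equality of model strings *is* spliced-CDS orthology.

A transcript model of gene *i* is **expressible** in gene *j* if every
token has an ortholog in M<sup>G</sup><sub>j</sub>, and **executable**,
E(M<sup>T</sup><sub>i,u</sub>, M<sup>G</sup><sub>j</sub>), if the
concatenation S of *j*'s orthologous block sequences forms a valid CDS
(ATG start, in-frame stop-free body, terminal stop codon). Executable
models without an equal known transcript become *predicted transcripts*.

Per triplet, a **functional-site graph** (nodes: sites; edges: pairwise
orthologies) classifies each site as species-specific (singleton), shared
by two (couple) or by three species (triplet = 3-clique); a gene triplet
whose graph contains only triplets is **structurally orthologous**. A
**transcript graph** (edges: equal model strings across genes) yields
**CDS orthology groups** — components spanning all three species.
Predicted transcripts are tagged `confirmed` (exact coding-exon chain in
an external annotation), `possible` (no transcript-specific exon
junction), `achievable` (all specific junctions read-supported) or
`not_achievable`.

## Worked example

The package ships a deterministic tri-species fixture generator. The
`fig1` fixture realizes one gene triplet with alternative exon variants
C/BC and F/EF: mouse knows all four CDS structures, human two, dog one
(seven known transcripts in total).

```bash
spliceortho simulate --fixture fig1 --outdir fix --seed 7
spliceortho run \
  --species human fix/human.gtf fix/human.fa \
  --species mouse fix/mouse.gtf fix/mouse.fa \
  --species dog   fix/dog.gtf   fix/dog.fa \
  --junctions human fix/human.junctions.tab \
  --junctions mouse fix/mouse.junctions.tab \
  --junctions dog   fix/dog.junctions.tab \
  --orthologs fix/orthologs.tsv --outdir out
```

prints

```json
{
  "all_conserved": 1,
  "cds_orthology_groups": 4,
  "errors": 0,
  "evidence_tags": {"achievable": 5},
  "predictions": {"dog": 3, "human": 2, "mouse": 0},
  "redundant_sets": {"dog": 0, "human": 0, "mouse": 0},
  "retained": 1,
  "single_copy": 1,
  "structurally_orthologous": 1,
  "triplets": 1
}
```

Reading this: the seven known transcripts represent four distinct CDS
splicing structures; five new CDSs are predicted (two in human — the
structures needing the unannotated acceptors of C and F — and three in
dog, which additionally lacks annotation for block B), every prediction's
specific exon junctions are covered by the read data (`achievable`), and
the completed transcript graph consists of four three-species CDS
orthology groups, one per structure — so the triplet is structurally
orthologous with a fully conserved, single-copy isoform repertoire.
`out/groups.tsv` lists the members, e.g. group 1 (`[A<>BC<>D<>EF]`) =
known human t1 + known mouse t1 + predicted `dog_fig1.pred1`.

Other outputs: `tokens.tsv` (gene models), `orthologies.tsv` (token
orthology relation), `predicted_<species>.gtf`, `verdicts.tsv`,
`redundancy.tsv`, `evidence.tsv`, and `--sqlite` adds a relational export
(tables genes / transcripts / tokens / orthologies / groups).

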
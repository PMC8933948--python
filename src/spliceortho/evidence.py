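"""Evidence tagging of predicted transcripts.

Each predicted transcript receives exactly one of four tags:

* ``confirmed`` -- some transcript of a supplied annotation collection has
  exactly the prediction's ordered coding-exon chain;
* ``possible`` -- not confirmed, but the prediction uses no *specific* exon
  junction (every junction occurs in some known transcript of the input
  set), so no new splicing event is required;
* ``achievable`` -- every specific junction is covered by aligned reads in
  the junction-support data (count >= ``config.min_reads``);
* ``not_achievable`` -- at least one specific junction lacks read support.

Junctions are compared as genomic intron spans (seqname, first and last
intronic base), making the comparison independent of strand bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneInput, SpeciesData
from .models import Config, DEFAULT_CONFIG, InputError, TranscriptModel

__all__ = [
    "Junction",
    "EvidenceTag",
    "junction_span",
    "known_junction_set",
    "confirm_in_annotations",
    "specific_junctions",
    "tag",
    "assign_evidence",
]


@dataclass(frozen=True)
class Junction:
    """One exon junction in locus coordinates (transcription orientation)."""

    gene_id: str
    donor_position: int
    acceptor_position: int

    def __post_init__(self):
        if self.acceptor_position <= self.donor_position:
            raise InputError("junction donor must lie upstream of acceptor")


@dataclass
class EvidenceTag:
    transcript_id: str
    tag: str  # confirmed | possible | achievable | not_achievable
    detail: str = ""


def junction_span(gene: GeneInput,
                  junction: tuple[int, int]) -> tuple[str, int, int]:
    """Genomic intron span (seqname, start, end; 1-based inclusive) of a
    local (donor, acceptor) junction."""
    gs, ge = gene.to_genomic(junction)
    return (gene.seqname, gs, ge)


def known_junction_set(species_data: SpeciesData) -> set[tuple[str, int, int]]:
    """Genomic spans of every junction of every known transcript of the
    whole input set (all genes of the species)."""
    out: set[tuple[str, int, int]] = set()
    for gene in species_data.genes.values():
        for rec in gene.records:
            for i in range(len(rec.cds_exons) - 1):
                j = (rec.cds_exons[i][1], rec.cds_exons[i + 1][0])
                out.add(junction_span(gene, j))
    return out


def confirm_in_annotations(pred: TranscriptModel, gene: GeneInput,
                           annotation_sets: list[tuple[str, SpeciesData]]
                           ) -> tuple[bool, str]:
    """Exact coding-exon-chain match against external annotation sets.

    The prediction's ordered CDS exon chain (genomic coordinates, UTRs
    ignored) must equal some annotated transcript's chain exactly; a single
    boundary shifted by even one base is no match.  Returns
    ``(matched, source name)``.
    """
    pred_chain = tuple(sorted(gene.to_genomic(iv) for iv in pred.exon_chain))
    for name, data in annotation_sets:
        for ann_gene in data.genes.values():
            if ann_gene.seqname != gene.seqname:
                continue
            if ann_gene.gene_id == gene.gene_id and (
                    ann_gene.span[1] < gene.span[0]
                    or ann_gene.span[0] > gene.span[1]):
                raise InputError(
                    f"annotation set {name}: gene {gene.gene_id} lies "
                    "outside the input locus (coordinate-system mismatch?)")
            for rec in ann_gene.records:
                chain = tuple(sorted(ann_gene.to_genomic(iv)
                                     for iv in rec.cds_exons))
                if chain == pred_chain:
                    return True, name
    return False, ""


def specific_junctions(pred: TranscriptModel, gene: GeneInput,
                       known: set[tuple[str, int, int]]) -> list[Junction]:
    """Junctions of the prediction observed in no known transcript of the
    input set.  A prediction that only reuses known junctions (including
    intron-retention-like structures with fewer junctions) yields an empty
    set."""
    out = []
    for d, a in pred.junctions():
        if junction_span(gene, (d, a)) not in known:
            out.append(Junction(gene.gene_id, d, a))
    return out


def tag(pred: TranscriptModel, gene: GeneInput, confirmed: bool,
        source: str, specific: list[Junction],
        support: dict[tuple[str, int, int], int],
        config: Config = DEFAULT_CONFIG) -> EvidenceTag:
    """Combine annotation and read evidence into the four-level tag.

    Annotation confirmation takes precedence; otherwise an empty specific
    set gives ``possible``; otherwise the prediction is ``achievable`` iff
    every specific junction has read support of at least
    ``config.min_reads``."""
    if confirmed:
        return EvidenceTag(pred.transcript_id, "confirmed", source)
    if not specific:
        return EvidenceTag(pred.transcript_id, "possible",
                           "no specific exon junction")
    counts = [support.get(junction_span(
        gene, (j.donor_position, j.acceptor_position)), 0)
        for j in specific]
    supported = sum(1 for c in counts if c >= config.min_reads)
    detail = f"{supported}/{len(specific)} specific junctions supported"
    if supported == len(specific):
        return EvidenceTag(pred.transcript_id, "achievable", detail)
    return EvidenceTag(pred.transcript_id, "not_achievable", detail)


def assign_evidence(predictions: list[TranscriptModel], gene: GeneInput,
                    annotation_sets: list[tuple[str, SpeciesData]],
                    known: set[tuple[str, int, int]],
                    support: dict[tuple[str, int, int], int],
                    config: Config = DEFAULT_CONFIG) -> dict[str, EvidenceTag]:
    """One tag per predicted transcript of a gene (a partition)."""
    out: dict[str, EvidenceTag] = {}
    for pred in predictions:
        conf, source = confirm_in_annotations(pred, gene, annotation_sets)
        spec = specific_junctions(pred, gene, known)
        out[pred.transcript_id] = tag(pred, gene, conf, source, spec,
                                      support, config)
    return out
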
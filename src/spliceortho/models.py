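"""Token grammar and structure models for spliced CDSs.

A gene's coding structure is written as an ordered string of *tokens*:
functional sites -- start codon ``[``, splice donor ``<``, splice acceptor
``>``, stop codon ``]`` -- and lettered *coding blocks* (``A``, ``B``, ...),
the maximal coding segments between consecutive functional sites.  A gene
structure model is the ordered union of the structures of its transcripts,
e.g. ``[A<>B<>C]>D]`` for a gene expressing ``[A<>B<>C]`` and ``[A<>B<>D]``.
A transcript structure model is the token subsequence describing one spliced
CDS; transcripts of orthologous genes with syntactically equal models are
*spliced CDS orthologs*.

All coordinates here are 0-based half-open intervals on the gene locus in
transcription orientation (the locus of a minus-strand gene is
reverse-complemented at load time, see :mod:`spliceortho.io_formats`), so
every model reads left to right 5'->3'.  Sites are zero-length boundaries
carrying a motif (dinucleotide for splice sites, trinucleotide for
start/stop); blocks are half-open coding intervals.  The stop codon is part
of the terminal block's interval, so an assembled CDS ends with its stop
trinucleotide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

__all__ = [
    "Config",
    "GrammarError",
    "StructureError",
    "ModelConflictError",
    "InputError",
    "AlphabetError",
    "UnresolvedTokenError",
    "Token",
    "TranscriptRecord",
    "TranscriptModel",
    "GeneModel",
    "parse_model_string",
    "format_model",
    "build_transcript_model",
    "build_gene_model",
    "assemble_cds_sequence",
    "is_valid_cds",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Config:
    """Tunable parameters shared across the pipeline.

    Alignment scoring and thresholds apply to the pairwise token alignment
    (:mod:`spliceortho.align`); codon/motif sets apply to CDS validity and
    to predicted-site acceptance.  Splice sites are canonically GT/AG;
    non-canonical motifs are accepted in known annotations but, by default,
    rejected for predicted sites.
    """

    start_codons: tuple[str, ...] = ("ATG",)
    stop_codons: tuple[str, ...] = ("TAA", "TAG", "TGA")
    donor_motif: str = "GT"
    acceptor_motif: str = "AG"
    allow_noncanonical_predicted: bool = False

    #: minimum identity (matches / query length) for a coding-block hit
    block_identity_threshold: float = 0.70
    #: nucleotides of flanking context on each side of a site motif
    site_context: int = 12
    match_score: float = 2.0
    mismatch_score: float = -3.0
    open_gap_score: float = -5.0
    extend_gap_score: float = -2.0
    #: require block hits to conserve reading-frame length offset (mod 3)
    frame_check_at_alignment: bool = True
    #: minimum fractional overlap for mapping an aligned block onto a target block
    min_anchor_overlap: float = 0.5

    #: minimum read count for a supported exon junction (evidence tagging)
    min_reads: int = 1
    #: whether GTF CDS features include the stop codon
    stop_in_cds: bool = False
    #: species precedence: prediction source attribution and label ordering
    species_order: tuple[str, ...] = ("human", "mouse", "dog")


DEFAULT_CONFIG = Config()


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class GrammarError(ValueError):
    """Malformed model string; carries the offending character offset."""

    def __init__(self, offset: int, message: str):
        self.offset = offset
        super().__init__(f"offset {offset}: {message}")


class StructureError(ValueError):
    """Token list violates a structural invariant."""


class ModelConflictError(StructureError):
    """Transcripts of one gene imply inconsistent coding frames."""

    def __init__(self, transcripts, message: str):
        self.transcripts = list(transcripts)
        super().__init__(f"{message} (transcripts: {', '.join(self.transcripts)})")


class InputError(ValueError):
    """Invalid input record (coordinates outside locus, empty CDS, ...)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class UnresolvedTokenError(ValueError):
    """Token lacks genomic coordinates required for sequence assembly."""


# --------------------------------------------------------------------------
# tokens
# --------------------------------------------------------------------------

START, DONOR, ACCEPTOR, STOP, BLOCK = "start", "donor", "acceptor", "stop", "block"

SITE_KINDS = (START, DONOR, ACCEPTOR, STOP)

SYMBOL_OF = {START: "[", DONOR: "<", ACCEPTOR: ">", STOP: "]"}
KIND_OF_SYMBOL = {v: k for k, v in SYMBOL_OF.items()}

# Tokens anchored at the same coordinate are ordered: sites that close a
# block (stop, donor), then sites that open one (acceptor, start), then the
# block itself -- which yields the conventional spellings "]>" and "]<".
_RANK = {STOP: 0, DONOR: 1, ACCEPTOR: 2, START: 3, BLOCK: 4}


@dataclass
class Token:
    """One grammar symbol anchored to locus coordinates.

    Sites have ``start == end`` (zero-length boundaries); blocks are
    half-open coding intervals.  ``status`` is ``known`` when the token is
    derived from an annotated transcript and ``predicted`` when it was
    revealed by cross-species alignment, in which case ``sources`` names the
    predicting species.
    """

    kind: str
    label: str = ""
    gene_id: str = ""
    start: int = 0
    end: int = 0
    motif: str = ""
    status: str = "known"
    sources: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in _RANK:
            raise StructureError(f"unknown token kind {self.kind!r}")
        if self.kind in SITE_KINDS and self.start != self.end:
            raise StructureError(f"{self.kind} token must be zero-length")
        if self.kind == BLOCK and self.end <= self.start:
            raise StructureError("block token must have a non-empty interval")

    @property
    def symbol(self) -> str:
        return self.label if self.kind == BLOCK else SYMBOL_OF[self.kind]

    @property
    def is_site(self) -> bool:
        return self.kind != BLOCK

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.start, _RANK[self.kind])

    @property
    def key(self) -> tuple:
        """Identity key: position-based, stable across relabelling."""
        if self.kind == BLOCK:
            return (self.gene_id, BLOCK, self.start, self.end)
        return (self.gene_id, self.kind, self.start)

    def __len__(self) -> int:
        return self.end - self.start


# --------------------------------------------------------------------------
# grammar strings
# --------------------------------------------------------------------------

def parse_model_string(text: str) -> list[Token]:
    """Parse a grammar string into an ordered, coordinate-free token list.

    Valid strings are drawn from ``{[, ], <, >, A-Z}``, begin with a start
    token, end with a stop token, contain at least one coding block, and
    every donor is followed by a later acceptor.  Raises
    :class:`GrammarError` naming the offending offset otherwise.
    """
    if not text:
        raise GrammarError(0, "empty model string")
    for i, ch in enumerate(text):
        if ch not in KIND_OF_SYMBOL and not ("A" <= ch <= "Z"):
            raise GrammarError(i, f"unknown symbol {ch!r}")
    if text[0] != "[":
        raise GrammarError(0, "model must begin with a start token '['")
    if text[-1] != "]":
        raise GrammarError(len(text) - 1, "model must end with a stop token ']'")
    if not any("A" <= ch <= "Z" for ch in text):
        raise GrammarError(0, "model contains no coding block")
    for i, ch in enumerate(text):
        if ch == "<" and ">" not in text[i + 1:]:
            raise GrammarError(i, "donor without a later acceptor")
    tokens = []
    for ch in text:
        if ch in KIND_OF_SYMBOL:
            tokens.append(Token(kind=KIND_OF_SYMBOL[ch]))
        else:
            tokens.append(Token(kind=BLOCK, label=ch, end=1))
    return tokens


def format_model(tokens: list[Token]) -> str:
    """Render a token list as its canonical one-line grammar string.

    Inverse of :func:`parse_model_string`; raises :class:`StructureError`
    on token lists violating the grammar invariants.
    """
    if not tokens:
        raise StructureError("empty token list")
    if tokens[0].kind != START:
        raise StructureError("first token must be a start codon")
    if tokens[-1].kind != STOP:
        raise StructureError("last token must be a stop codon")
    kinds = [t.kind for t in tokens]
    if BLOCK not in kinds:
        raise StructureError("model contains no coding block")
    for i, t in enumerate(tokens):
        if t.kind == DONOR and ACCEPTOR not in kinds[i + 1:]:
            raise StructureError("donor without a later acceptor")
        if t.kind == BLOCK and not t.label:
            raise StructureError("block token without a label")
    return "".join(t.symbol for t in tokens)


# --------------------------------------------------------------------------
# transcript records and models
# --------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    """Annotated transcript: CDS and UTR exon intervals in locus coordinates.

    ``cds_exons`` include the stop codon (the GTF reader appends it when the
    annotation dialect excludes it from CDS features).
    """

    transcript_id: str
    gene_id: str
    cds_exons: list[tuple[int, int]]
    utr5_exons: list[tuple[int, int]] = field(default_factory=list)
    utr3_exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = None
        for s, e in self.cds_exons:
            if e <= s:
                raise InputError(f"{self.transcript_id}: empty CDS exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise InputError(f"{self.transcript_id}: overlapping/unordered CDS exons")
            prev_end = e

    @property
    def has_utr5(self) -> bool:
        return bool(self.utr5_exons)

    @property
    def has_utr3(self) -> bool:
        return bool(self.utr3_exons)


@dataclass
class TranscriptModel:
    """Token subsequence describing one spliced CDS structure.

    ``exon_chain`` is the authoritative list of coding exon intervals
    (stop codon included); ``tokens`` is the expression of that chain over
    the owning gene model's segmentation and is refreshed whenever the gene
    model is re-segmented.
    """

    transcript_id: str
    gene_id: str
    exon_chain: list[tuple[int, int]]
    tokens: list[Token] = field(default_factory=list)
    status: str = "known"
    sources: tuple[str, ...] = ()
    cds_sequence_checksum: str = ""

    @property
    def model_string(self) -> str:
        return format_model(self.tokens)

    def junctions(self) -> list[tuple[int, int]]:
        """Exon junctions as (donor position, acceptor position) pairs."""
        return [
            (self.exon_chain[i][1], self.exon_chain[i + 1][0])
            for i in range(len(self.exon_chain) - 1)
        ]


def _checksum(seq: str) -> str:
    return hashlib.md5(seq.encode()).hexdigest()


def build_transcript_model(rec: TranscriptRecord, locus: str,
                           config: Config = DEFAULT_CONFIG) -> TranscriptModel:
    """Build a standalone transcript structure model from a CDS exon chain.

    One start token at the CDS 5' end, a block per coding exon (labelled
    provisionally ``A``, ``B``, ... -- labels are reassigned by
    :func:`build_gene_model` and by cross-species unification), donor /
    acceptor pairs at each intron, and one stop token at the 3' end.  UTR
    exons contribute no tokens: records differing only in UTRs yield models
    with equal checksums.
    """
    if not rec.cds_exons:
        raise InputError(f"{rec.transcript_id}: no CDS exons")
    for s, e in rec.cds_exons:
        if s < 0 or e > len(locus):
            raise InputError(
                f"{rec.transcript_id}: CDS exon [{s}, {e}) outside locus "
                f"of length {len(locus)}")
    gid = rec.gene_id
    chain = [tuple(x) for x in rec.cds_exons]
    tokens: list[Token] = []
    first_s = chain[0][0]
    last_e = chain[-1][1]
    tokens.append(Token(START, gene_id=gid, start=first_s, end=first_s,
                        motif=locus[first_s:first_s + 3]))
    for i, (s, e) in enumerate(chain):
        if i > 0:
            tokens.append(Token(ACCEPTOR, gene_id=gid, start=s, end=s,
                                motif=locus[s - 2:s]))
        tokens.append(Token(BLOCK, label=chr(ord("A") + i) if i < 26 else "Z",
                            gene_id=gid, start=s, end=e))
        if i < len(chain) - 1:
            tokens.append(Token(DONOR, gene_id=gid, start=e, end=e,
                                motif=locus[e:e + 2]))
    tokens.append(Token(STOP, gene_id=gid, start=last_e, end=last_e,
                        motif=locus[last_e - 3:last_e]))
    seq = "".join(locus[s:e] for s, e in chain)
    return TranscriptModel(rec.transcript_id, gid, chain, tokens,
                           cds_sequence_checksum=_checksum(seq))


# --------------------------------------------------------------------------
# gene models
# --------------------------------------------------------------------------

_LETTERS = [chr(ord("A") + i) for i in range(26)]


@dataclass
class GeneModel:
    """Ordered token string of a gene: known plus predicted structure.

    ``known_coverage`` records the coding intervals supported by annotated
    transcripts; block tokens lying outside it are predicted.  Blocks are
    re-segmented so that every site position is a block boundary, which
    encodes alternative sites inside an exon as directly adjacent blocks.
    """

    gene_id: str
    species: str = ""
    strand: str = "+"
    locus: str = ""
    tokens: list[Token] = field(default_factory=list)
    transcripts: list[TranscriptModel] = field(default_factory=list)
    known_coverage: list[tuple[int, int]] = field(default_factory=list)

    # -- token access -----------------------------------------------------

    def sites(self) -> list[Token]:
        return [t for t in self.tokens if t.is_site]

    def blocks(self) -> list[Token]:
        return [t for t in self.tokens if t.kind == BLOCK]

    def site_at(self, kind: str, pos: int) -> Token | None:
        for t in self.tokens:
            if t.kind == kind and t.start == pos:
                return t
        return None

    def known_blocks(self) -> list[Token]:
        return [t for t in self.blocks() if t.status == "known"]

    @property
    def model_string(self) -> str:
        return format_model(self.tokens)

    def known_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.status == "known"]

    def predicted_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.status == "predicted"]

    # -- structure editing ------------------------------------------------

    def tokens_for_chain(self, exon_chain: list[tuple[int, int]]) -> list[Token]:
        """Express a coding exon chain as a subsequence of this gene's tokens.

        Each exon maps onto the run of (possibly several, directly adjacent)
        gene blocks tiling it; boundary sites (start, donors, acceptors,
        stop) must exist in the gene model.
        """
        by_start = {b.start: b for b in self.blocks()}
        out: list[Token] = []
        start_site = self.site_at(START, exon_chain[0][0])
        if start_site is None:
            raise StructureError(
                f"{self.gene_id}: no start token at {exon_chain[0][0]}")
        out.append(start_site)
        for i, (s, e) in enumerate(exon_chain):
            if i > 0:
                acc = self.site_at(ACCEPTOR, s)
                if acc is None:
                    raise StructureError(f"{self.gene_id}: no acceptor at {s}")
                out.append(acc)
            pos = s
            while pos < e:
                blk = by_start.get(pos)
                if blk is None or blk.end > e:
                    raise StructureError(
                        f"{self.gene_id}: exon [{s}, {e}) not tiled by blocks")
                out.append(blk)
                pos = blk.end
            if i < len(exon_chain) - 1:
                don = self.site_at(DONOR, e)
                if don is None:
                    raise StructureError(f"{self.gene_id}: no donor at {e}")
                out.append(don)
        stop = self.site_at(STOP, exon_chain[-1][1])
        if stop is None:
            raise StructureError(
                f"{self.gene_id}: no stop token at {exon_chain[-1][1]}")
        out.append(stop)
        return out

    def resegment(self) -> None:
        """Recut blocks at all site positions and refresh transcript tokens.

        Keeps existing site tokens; rebuilds block tokens from the current
        coding coverage (known coverage plus intervals of predicted blocks),
        cutting at every site position that falls strictly inside a coding
        interval.  Block labels are reset to per-gene coordinate order; the
        align module overwrites them with triplet-unified letters.
        """
        sites = sorted((t for t in self.tokens if t.is_site),
                       key=lambda t: t.sort_key)
        coverage = _merge_intervals(
            self.known_coverage
            + [(t.start, t.end) for t in self.tokens if t.kind == BLOCK])
        cuts = sorted({t.start for t in sites})
        blocks: list[Token] = []
        for (s, e) in coverage:
            bounds = [s] + [c for c in cuts if s < c < e] + [e]
            for a, b in zip(bounds, bounds[1:]):
                status = "known" if _contained((a, b), self.known_coverage) \
                    else "predicted"
                srcs = ()
                if status == "predicted":
                    for t in self.tokens:
                        if t.kind == BLOCK and t.start <= a and b <= t.end:
                            srcs = t.sources
                            break
                blocks.append(Token(BLOCK, gene_id=self.gene_id, start=a,
                                    end=b, status=status, sources=srcs))
        if len(blocks) > len(_LETTERS):
            raise StructureError(
                f"{self.gene_id}: more than {len(_LETTERS)} coding blocks")
        for letter, blk in zip(_LETTERS, blocks):
            blk.label = letter
        self.tokens = sorted(sites + blocks, key=lambda t: t.sort_key)
        for tr in self.transcripts:
            tr.tokens = self.tokens_for_chain(tr.exon_chain)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _contained(ival: tuple[int, int], coverage: list[tuple[int, int]]) -> bool:
    return any(s <= ival[0] and ival[1] <= e for s, e in coverage)


def build_gene_model(transcripts: list[TranscriptModel], locus: str,
                     species: str = "", strand: str = "+",
                     config: Config = DEFAULT_CONFIG) -> GeneModel:
    """Merge transcript structure models into the gene structure model.

    The token union is ordered by coordinate, and blocks are re-segmented so
    that every site position of any transcript is a block boundary
    (alternative 5'/3' exon extensions become separate, directly adjacent
    blocks).  Each input transcript is re-expressed as a token subsequence
    of the result.  Transcripts implying inconsistent coding frames for a
    shared block raise :class:`ModelConflictError`.
    """
    if not transcripts:
        raise InputError("no transcripts")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise InputError(f"transcripts from several genes: {sorted(gene_ids)}")
    gid = gene_ids.pop()

    site_tokens: dict[tuple, Token] = {}
    for tm in transcripts:
        for tok in tm.tokens:
            if tok.is_site:
                site_tokens.setdefault((tok.kind, tok.start), replace(tok))
    gene = GeneModel(
        gene_id=gid, species=species, strand=strand, locus=locus,
        tokens=[replace(t, gene_id=gid) for t in site_tokens.values()],
        transcripts=transcripts,
        known_coverage=_merge_intervals(
            [iv for tm in transcripts for iv in tm.exon_chain]),
    )
    gene.resegment()
    _check_frames(gene)
    return gene


def _check_frames(gene: GeneModel) -> None:
    """Verify every block is used in one consistent coding frame."""
    frames: dict[tuple[int, int], tuple[int, str]] = {}
    for tm in gene.transcripts:
        cum = 0
        for tok in tm.tokens:
            if tok.kind != BLOCK:
                continue
            prev = frames.get((tok.start, tok.end))
            if prev is not None and prev[0] != cum % 3:
                raise ModelConflictError(
                    [prev[1], tm.transcript_id],
                    f"{gene.gene_id}: block [{tok.start}, {tok.end}) used in "
                    f"frames {prev[0]} and {cum % 3}")
            frames[(tok.start, tok.end)] = (cum % 3, tm.transcript_id)
            cum += len(tok)


# --------------------------------------------------------------------------
# CDS assembly and validity
# --------------------------------------------------------------------------

def assemble_cds_sequence(model: TranscriptModel, locus: str) -> str:
    """Concatenate the block sequences of a transcript model, 5'->3'.

    The locus is already in transcription orientation (minus-strand genes
    are reverse-complemented at load time), so the concatenation is the
    coding-strand CDS, stop codon included.
    """
    blocks = [t for t in model.tokens if t.kind == BLOCK]
    if not blocks:
        raise UnresolvedTokenError(f"{model.transcript_id}: no block tokens")
    for b in blocks:
        if b.end > len(locus) or b.start < 0:
            raise UnresolvedTokenError(
                f"{model.transcript_id}: block [{b.start}, {b.end}) has no "
                "sequence on the locus")
    return "".join(locus[b.start:b.end] for b in blocks)


def is_valid_cds(seq: str, config: Config = DEFAULT_CONFIG) -> tuple[bool, str]:
    """Check that a nucleotide string forms a complete CDS.

    Valid means: length >= 6 and divisible by 3, first codon a configured
    start codon, last codon a stop codon, and no internal in-frame stop.
    Returns ``(ok, reason)`` with ``reason == ""`` when valid.
    """
    if any(c not in "ACGT" for c in seq):
        raise AlphabetError("sequence contains non-ACGT characters")
    if len(seq) < 6:
        return False, "too short"
    if len(seq) % 3 != 0:
        return False, "frame"
    if seq[:3] not in config.start_codons:
        return False, "start motif"
    if seq[-3:] not in config.stop_codons:
        return False, "stop motif"
    for i in range(3, len(seq) - 3, 3):
        if seq[i:i + 3] in config.stop_codons:
            return False, "internal in-frame stop"
    return True, ""
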
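"""Expressibility / executability tests and predicted-transcript creation.

A transcript structure model of gene *i* is *expressible* in an orthologous
gene *j* when every one of its tokens has an orthologous token (known or
predicted) in *j*'s gene model.  It is *executable* when, additionally, the
concatenation of the orthologous coding-block sequences of *j* forms a
valid CDS (frame, start/stop motifs, no internal in-frame stop).  An
executable model with no equal known transcript in *j* becomes a predicted
transcript: a spliced CDS ortholog of the seeding known transcript.
"""

from __future__ import annotations

from .align import TripletComparison
from .models import (
    ACCEPTOR, BLOCK, DONOR, START, STOP,
    Config, DEFAULT_CONFIG, GeneModel, Token, TranscriptModel,
    assemble_cds_sequence, is_valid_cds, _checksum,
)

__all__ = ["is_expressible", "is_executable", "predict_transcripts"]


def _mapped_tokens(model: TranscriptModel, target: GeneModel,
                   comparison: TripletComparison) -> list[Token] | None:
    """Orthologs of the model's tokens in the target gene, or None."""
    mapped = []
    for tok in model.tokens:
        ortho = comparison.ortholog_in(tok, target.gene_id)
        if ortho is None:
            return None
        mapped.append(ortho)
    return mapped


def is_expressible(model: TranscriptModel, target: GeneModel,
                   comparison: TripletComparison) -> bool:
    """True iff every token of the model has an orthologous token in the
    target gene model (trivially true against the model's own gene)."""
    return _mapped_tokens(model, target, comparison) is not None


def _target_chain(model: TranscriptModel,
                  mapped: list[Token]) -> list[tuple[int, int]] | None:
    """Exon chain of the mapped token sequence; None on a structural
    mismatch (non-colinear orthologs, or exon-adjacent blocks whose
    orthologs are not adjacent)."""
    chain: list[tuple[int, int]] = []
    cur_start = cur_end = None
    pending_acceptor = None
    for src, dst in zip(model.tokens, mapped):
        if src.kind != dst.kind:
            return None
        if src.kind == BLOCK:
            if cur_start is None:
                if pending_acceptor is not None \
                        and dst.start != pending_acceptor:
                    return None
                cur_start, cur_end = dst.start, dst.end
            else:
                if dst.start != cur_end:  # must be directly adjacent
                    return None
                cur_end = dst.end
            pending_acceptor = None
        elif src.kind == ACCEPTOR:
            if cur_start is not None:
                return None
            pending_acceptor = dst.start
        elif src.kind == DONOR:
            if cur_start is None or dst.start != cur_end:
                return None
            chain.append((cur_start, cur_end))
            cur_start = cur_end = None
        elif src.kind == START:
            if chain or cur_start is not None:
                return None
        elif src.kind == STOP:
            if cur_start is None or dst.start != cur_end:
                return None
            chain.append((cur_start, cur_end))
            cur_start = cur_end = None
    if cur_start is not None or not chain:
        return None
    if any(b[0] < a[1] for a, b in zip(chain, chain[1:])):
        return None
    if mapped[0].kind != START or mapped[0].start != chain[0][0]:
        return None
    return chain


def is_executable(model: TranscriptModel, target: GeneModel,
                  comparison: TripletComparison,
                  config: Config = DEFAULT_CONFIG
                  ) -> tuple[bool, str, str]:
    """Executability of a transcript model in an orthologous gene.

    Returns ``(ok, sequence, reason)``: the candidate CDS assembled from
    the target's orthologous blocks and, on failure, the reason
    (missing orthologs, structural mismatch, frame, internal stop,
    start/stop motif).
    """
    mapped = _mapped_tokens(model, target, comparison)
    if mapped is None:
        return False, "", "not expressible"
    chain = _target_chain(model, mapped)
    if chain is None:
        return False, "", "structure"
    candidate = TranscriptModel("candidate", target.gene_id, chain,
                                tokens=mapped)
    seq = assemble_cds_sequence(candidate, target.locus)
    ok, reason = is_valid_cds(seq, config)
    return ok, seq, reason


def predict_transcripts(comparison: TripletComparison,
                        config: Config = DEFAULT_CONFIG
                        ) -> dict[str, list[TranscriptModel]]:
    """Create predicted transcripts for every gene of the comparison.

    For every known transcript model of any gene and every other gene: if
    the model is executable there and no known transcript of that gene has
    an equal (unified-label) model string, exactly one predicted transcript
    is emitted, deduplicated by model string, carrying the full set of
    seeding source species (ordered by configured species precedence).
    Predicted transcripts are appended to the gene models and receive IDs
    ``<gene_id>.pred<N>`` in model-string lexicographic order.
    """
    genes = comparison.genes

    def order_key(gid: str) -> tuple:
        sp = genes[gid].species
        try:
            return (config.species_order.index(sp), gid)
        except ValueError:
            return (len(config.species_order), gid)

    gids = sorted(genes, key=order_key)
    known_strings = {gid: {tm.model_string
                           for tm in genes[gid].known_transcripts()}
                     for gid in gids}
    # candidate predictions: (target gid, model string) -> details
    cands: dict[tuple[str, str], dict] = {}
    for src_gid in gids:
        src = genes[src_gid]
        for tm in src.known_transcripts():
            mstr = tm.model_string
            for dst_gid in gids:
                if dst_gid == src_gid or mstr in known_strings[dst_gid]:
                    continue
                dst = genes[dst_gid]
                ok, seq, _reason = is_executable(tm, dst, comparison, config)
                if not ok:
                    continue
                mapped = _mapped_tokens(tm, dst, comparison)
                chain = _target_chain(tm, mapped)
                entry = cands.setdefault((dst_gid, mstr), {
                    "chain": chain, "tokens": mapped, "seq": seq,
                    "sources": set()})
                entry["sources"].add(src.species or src_gid)

    out: dict[str, list[TranscriptModel]] = {gid: [] for gid in gids}
    for dst_gid in gids:
        mine = sorted(m for (g, m) in cands if g == dst_gid)
        for n, mstr in enumerate(mine, start=1):
            entry = cands[(dst_gid, mstr)]
            sources = _order_species(entry["sources"], config)
            pred = TranscriptModel(
                f"{dst_gid}.pred{n}", dst_gid, entry["chain"],
                tokens=entry["tokens"], status="predicted", sources=sources,
                cds_sequence_checksum=_checksum(entry["seq"]))
            assert pred.model_string == mstr, \
                "predicted model must equal its source model"
            genes[dst_gid].transcripts.append(pred)
            out[dst_gid].append(pred)
    return out


def _order_species(species: set[str], config: Config) -> tuple[str, ...]:
    def key(s):
        try:
            return (config.species_order.index(s), s)
        except ValueError:
            return (len(config.species_order), s)
    return tuple(sorted(species, key=key))
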
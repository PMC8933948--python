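"""Pairwise comparison of orthologous genes: token orthology and prediction.

Each known coding block of a gene is locally aligned against the locus of
the orthologous gene (colinear anchoring: search windows are bounded by the
nearest already-anchored blocks, longest blocks first).  A block hit either
lands on annotated coding sequence of the target -- recording a *token
orthology* -- or in unannotated sequence, recording a *predicted* block.
Known functional sites are then mapped through their attached block anchors
(or by aligning the site motif with flanking context when the block did not
anchor) and accepted only where the target shows the exact splice/codon
motif.  Predicted sites re-segment the target's blocks, so an alternative
exon extension annotated in one species splits the longer exon of the other
into directly adjacent blocks.

Orthologous coding blocks across a gene set are unified under a single
letter (union-find over the symmetric orthology relation); functional-site
orthology components with at most one site per gene are closed into
complete cross-gene cliques, since two sites independently aligned from a
common ortholog are orthologous to each other.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field

from Bio import Align

from .models import (
    ACCEPTOR, BLOCK, DONOR, START, STOP,
    Config, DEFAULT_CONFIG, GeneModel, Token,
)

__all__ = [
    "Hit",
    "TokenOrthology",
    "PairwiseComparison",
    "TripletComparison",
    "align_token",
    "compare_genes",
    "compare_triplet",
    "unify_labels",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# local alignment primitives
# --------------------------------------------------------------------------

def _make_aligner(config: Config) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.open_gap_score
    aligner.extend_gap_score = config.extend_gap_score
    return aligner


@dataclass
class Hit:
    """Best local alignment of a token inside a target window.

    For blocks, ``start``/``end`` span the aligned target interval; for
    sites they both equal the mapped boundary position.
    """

    start: int
    end: int
    identity: float
    score: float


def _best_alignment(aligner, target: str, query: str, max_ties: int = 8):
    """Highest-scoring local alignment; score ties broken by smallest
    target coordinate (and logged)."""
    try:
        alns = aligner.align(target, query)
    except ValueError:
        return None
    if len(alns) == 0:
        return None
    best = None
    n_ties = 0
    for i, aln in enumerate(alns):
        if i >= max_ties:
            break
        n_ties += 1
        t0 = int(aln.aligned[0][0][0])
        if best is None or t0 < best[0]:
            best = (t0, aln)
    if n_ties > 1:
        logger.debug("equal-score hits (%d examined), kept smallest "
                     "target coordinate %d", n_ties, best[0])
    return best[1]


def _map_query_offset(aln, qoff: int) -> int | None:
    """Target coordinate corresponding to a query offset, extrapolating
    from the nearest aligned segment when the offset falls in a gap."""
    tsegs, qsegs = aln.aligned
    for (ts, te), (qs, qe) in zip(tsegs, qsegs):
        if qs <= qoff < qe:
            return int(ts + (qoff - qs))
    first_t, first_q = tsegs[0], qsegs[0]
    if qoff < first_q[0]:
        return int(first_t[0] - (first_q[0] - qoff))
    last_t, last_q = tsegs[-1], qsegs[-1]
    if qoff >= last_q[1]:
        return int(last_t[1] + (qoff - last_q[1]))
    return None


def _site_motif_ok(kind: str, locus: str, pos: int, config: Config) -> bool:
    if kind == DONOR:
        return locus[pos:pos + 2] == config.donor_motif
    if kind == ACCEPTOR:
        return pos >= 2 and locus[pos - 2:pos] == config.acceptor_motif
    if kind == START:
        return locus[pos:pos + 3] in config.start_codons
    if kind == STOP:
        return pos >= 3 and locus[pos - 3:pos] in config.stop_codons
    return False


def align_token(token: Token, source: GeneModel, target: GeneModel,
                window: tuple[int, int] | None = None,
                config: Config = DEFAULT_CONFIG) -> Hit | None:
    """Align one token of ``source`` inside a window of ``target``'s locus.

    Blocks: best local alignment of the block sequence; a hit requires
    identity >= ``config.block_identity_threshold`` over the block and, when
    ``config.frame_check_at_alignment`` is set, a length offset divisible by
    three.  Sites: the motif with ``config.site_context`` nucleotides of
    flanking context on each side is aligned and the boundary mapped; a hit
    requires either a known same-kind site of the target at the mapped
    position or the exact splice/codon motif there (non-canonical motifs
    are rejected for predictions unless configured otherwise).

    An empty window is a no-hit, not an error.
    """
    lo, hi = window if window is not None else (0, len(target.locus))
    lo, hi = max(0, lo), min(len(target.locus), hi)
    if hi <= lo:
        return None
    sub = target.locus[lo:hi]
    aligner = _make_aligner(config)

    if token.kind == BLOCK:
        query = source.locus[token.start:token.end]
        if not query or len(sub) < 4:
            return None
        aln = _best_alignment(aligner, sub, query)
        if aln is None:
            return None
        identity = aln.counts().identities / len(query)
        if identity < config.block_identity_threshold:
            return None
        ts = lo + int(aln.aligned[0][0][0])
        te = lo + int(aln.aligned[0][-1][1])
        if config.frame_check_at_alignment and ((te - ts) - len(query)) % 3:
            return None
        return Hit(ts, te, identity, float(aln.score))

    # functional site: motif plus flanking context
    w = config.site_context + 3
    qlo = max(0, token.start - w)
    qhi = min(len(source.locus), token.start + w)
    query = source.locus[qlo:qhi]
    if not query or len(sub) < 4:
        return None
    aln = _best_alignment(aligner, sub, query)
    if aln is None:
        return None
    pos = _map_query_offset(aln, token.start - qlo)
    if pos is None:
        return None
    pos += lo
    if pos < 0 or pos > len(target.locus):
        return None
    identity = aln.counts().identities / len(query)
    known = target.site_at(token.kind, pos)
    if known is not None and known.status == "known":
        return Hit(pos, pos, identity, float(aln.score))
    if _site_motif_ok(token.kind, target.locus, pos, config):
        return Hit(pos, pos, identity, float(aln.score))
    if config.allow_noncanonical_predicted and token.kind in (DONOR, ACCEPTOR):
        return Hit(pos, pos, identity, float(aln.score))
    return None


# --------------------------------------------------------------------------
# orthology containers
# --------------------------------------------------------------------------

@dataclass
class TokenOrthology:
    """Symmetric orthology relation between two same-kind tokens."""

    token_a: Token
    token_b: Token
    identity: float | None = None
    alignment_span: tuple | None = None  # ((a_start, a_end), (b_start, b_end))

    @property
    def key(self) -> frozenset:
        return frozenset((self.token_a.key, self.token_b.key))

    def other(self, token: Token) -> Token:
        if token.key == self.token_a.key:
            return self.token_b
        if token.key == self.token_b.key:
            return self.token_a
        raise KeyError(token.key)


@dataclass
class PairwiseComparison:
    """Result of comparing two orthologous genes."""

    gene_a: GeneModel
    gene_b: GeneModel
    orthologies: list[TokenOrthology]
    predicted_tokens_a: list[Token]
    predicted_tokens_b: list[Token]
    unaligned_tokens: dict[str, list[Token]]
    conflicts: list[str] = field(default_factory=list)


@dataclass
class TripletComparison:
    """Cross-species comparison state for a gene set (usually a triplet).

    Gene models are augmented copies of the inputs (predicted tokens added,
    blocks re-segmented, labels unified).  ``orthologies`` contains the
    cross-gene token orthologies, including closure edges between sites
    independently predicted from a common ortholog.
    """

    genes: dict[str, GeneModel]
    orthologies: list[TokenOrthology]
    conflicts: list[str]
    dropped_blocks: list[Token]
    components: list[list[Token]]
    _comp_of: dict[tuple, int]

    def component_of(self, token: Token) -> list[Token]:
        idx = self._comp_of.get(token.key)
        return self.components[idx] if idx is not None else [token]

    def ortholog_in(self, token: Token, gene_id: str) -> Token | None:
        """Member of the token's orthology component in another gene."""
        if token.gene_id == gene_id:
            return token
        for member in self.component_of(token):
            if member.gene_id == gene_id:
                return member
        return None

    def site_orthologies(self) -> list[TokenOrthology]:
        return [o for o in self.orthologies if o.token_a.kind != BLOCK]


# --------------------------------------------------------------------------
# the comparator
# --------------------------------------------------------------------------

class _Comparator:
    """Runs anchoring, prediction, re-segmentation and unification."""

    def __init__(self, genes: dict[str, GeneModel], config: Config,
                 copy: bool = True):
        self.config = config
        self.genes = {gid: (_copy.deepcopy(g) if copy else g)
                      for gid, g in genes.items()}
        # only tokens known at entry ever seed alignments
        self.seed_blocks = {gid: [(b.start, b.end) for b in g.known_blocks()]
                            for gid, g in self.genes.items()}
        self.seed_sites = {gid: [(s.kind, s.start) for s in g.sites()
                                 if s.status == "known"]
                           for gid, g in self.genes.items()}
        self.pair_anchors: dict[tuple, dict] = {}
        self.pair_site_cands: dict[tuple, list] = {}
        self.unaligned: dict[str, list[Token]] = {gid: []
                                                  for gid in self.genes}
        self.conflicts: list[str] = []
        self.dropped_blocks: list[Token] = []

    def _order(self, gid: str) -> tuple:
        g = self.genes[gid]
        try:
            idx = self.config.species_order.index(g.species)
        except ValueError:
            idx = len(self.config.species_order)
        return (idx, gid)

    # -- phase A: anchoring and site candidates ---------------------------

    def _anchor_pair(self, src: str, dst: str) -> None:
        gi, gj = self.genes[src], self.genes[dst]
        anchors: dict[tuple[int, int], tuple[int, int, float]] = {}
        order = sorted(self.seed_blocks[src],
                       key=lambda iv: (-(iv[1] - iv[0]), iv[0]))
        for qs, qe in order:
            lo, hi = 0, len(gj.locus)
            for (aqs, aqe), (ts, te, _ident) in anchors.items():
                if aqe <= qs:
                    lo = max(lo, te)
                elif aqs >= qe:
                    hi = min(hi, ts)
            if hi <= lo:
                continue
            tok = Token(BLOCK, gene_id=src, start=qs, end=qe)
            hit = align_token(tok, gi, gj, (lo, hi), self.config)
            if hit is not None:
                anchors[(qs, qe)] = (hit.start, hit.end, hit.identity)
        self.pair_anchors[(src, dst)] = anchors

        cands: list[tuple[str, int, int]] = []
        for kind, pos in self.seed_sites[src]:
            tpos = self._map_site(src, dst, kind, pos, anchors)
            if tpos is None:
                tok = gi.site_at(kind, pos)
                if tok is not None:
                    self.unaligned[src].append(tok)
                continue
            cands.append((kind, pos, tpos))
        self.pair_site_cands[(src, dst)] = cands

    def _map_site(self, src: str, dst: str, kind: str, pos: int,
                  anchors: dict) -> int | None:
        gi, gj = self.genes[src], self.genes[dst]
        attached = None
        for (qs, qe) in self.seed_blocks[src]:
            if kind in (ACCEPTOR, START) and qs == pos:
                attached = (qs, qe)
                break
            if kind in (DONOR, STOP) and qe == pos:
                attached = (qs, qe)
                break
        # sites sit on block edges and are mapped through their attached
        # block's anchor; an unanchored block leaves its sites unaligned
        if attached is None or attached not in anchors:
            return None
        ts, te, _ = anchors[attached]
        tpos = ts if kind in (ACCEPTOR, START) else te
        known = gj.site_at(kind, tpos)
        if (known is not None and known.status == "known") or \
                _site_motif_ok(kind, gj.locus, tpos, self.config) or \
                (self.config.allow_noncanonical_predicted
                 and kind in (DONOR, ACCEPTOR)):
            return tpos
        return None

    # -- phase B: apply predictions, re-segment ---------------------------

    def _apply_predictions(self, pairs) -> None:
        for dst in sorted(self.genes, key=self._order):
            g = self.genes[dst]
            site_adds: dict[tuple[str, int], set[str]] = {}
            span_adds: dict[tuple[int, int], set[str]] = {}
            for (src, d) in pairs:
                if d != dst or src == dst:
                    continue
                src_species = self.genes[src].species or src
                for kind, _qpos, tpos in self.pair_site_cands[(src, d)]:
                    existing = g.site_at(kind, tpos)
                    if existing is not None and existing.status == "known":
                        continue
                    site_adds.setdefault((kind, tpos), set()).add(src_species)
                for (_qs, _qe), (ts, te, _i) in \
                        self.pair_anchors[(src, d)].items():
                    if not _contained((ts, te), g.known_coverage):
                        span_adds.setdefault((ts, te), set()).add(src_species)
            for (kind, pos), sources in sorted(site_adds.items(),
                                               key=lambda kv: kv[0][1]):
                motif = _motif_at(kind, g.locus, pos)
                g.tokens.append(Token(kind, gene_id=g.gene_id, start=pos,
                                      end=pos, motif=motif,
                                      status="predicted",
                                      sources=_order_sources(sources,
                                                             self.config)))
            for (ts, te), sources in sorted(span_adds.items()):
                g.tokens.append(Token(BLOCK, gene_id=g.gene_id, start=ts,
                                      end=te, status="predicted",
                                      sources=_order_sources(sources,
                                                             self.config)))
            g.resegment()
            self._prune_unflanked(g)

    def _prune_unflanked(self, g: GeneModel) -> None:
        """Drop predicted blocks whose edges carry neither a site nor an
        adjacent block (keeps the gene-model invariant)."""
        while True:
            blocks = g.blocks()
            starts = {b.start for b in blocks}
            ends = {b.end for b in blocks}
            bad = None
            for b in blocks:
                if b.status != "predicted":
                    continue
                left_ok = (g.site_at(START, b.start) is not None
                           or g.site_at(ACCEPTOR, b.start) is not None
                           or b.start in ends)
                right_ok = (g.site_at(STOP, b.end) is not None
                            or g.site_at(DONOR, b.end) is not None
                            or b.end in starts)
                if not (left_ok and right_ok):
                    bad = b
                    break
            if bad is None:
                return
            self.dropped_blocks.append(bad)
            g.tokens = [t for t in g.tokens if t is not bad]

    # -- phase C: orthology edges -----------------------------------------

    def _collect_edges(self, pairs) -> list[TokenOrthology]:
        edges: dict[frozenset, TokenOrthology] = {}

        def add(tok_a, tok_b, identity, span=None):
            if tok_a is None or tok_b is None:
                return
            orth = TokenOrthology(tok_a, tok_b, identity, span)
            prev = edges.get(orth.key)
            if prev is None or (identity or 0) > (prev.identity or 0):
                edges[orth.key] = orth

        for (src, dst) in pairs:
            gi, gj = self.genes[src], self.genes[dst]
            for kind, qpos, tpos in self.pair_site_cands[(src, dst)]:
                add(gi.site_at(kind, qpos), gj.site_at(kind, tpos), None)
            blocks_j = gj.blocks()
            for (qs, qe), (ts, te, ident) in \
                    self.pair_anchors[(src, dst)].items():
                for u in gi.blocks():
                    if not (qs <= u.start and u.end <= qe):
                        continue
                    u_ts = ts + (u.start - qs)
                    u_te = te - (qe - u.end)
                    if u_te <= u_ts:
                        continue
                    best, best_ov = None, 0
                    for v in blocks_j:
                        ov = min(u_te, v.end) - max(u_ts, v.start)
                        if ov > best_ov:
                            best, best_ov = v, ov
                    if best is None:
                        continue
                    need = max(1.0, self.config.min_anchor_overlap
                               * min(u_te - u_ts, len(best)))
                    if best_ov >= need:
                        add(u, best, ident,
                            ((u.start, u.end), (best.start, best.end)))
        return sorted(edges.values(),
                      key=lambda o: (-(o.identity or 1.0),
                                     sorted(map(str, o.key))))

    # -- phase D: unification and closure ---------------------------------

    def run(self, pairs=None) -> TripletComparison:
        gids = sorted(self.genes, key=self._order)
        if pairs is None:
            pairs = [(a, b) for i, a in enumerate(gids)
                     for b in gids[i + 1:]]
            pairs = [p for ab in pairs for p in (ab, ab[::-1])]
        for src, dst in pairs:
            self._anchor_pair(src, dst)
        self._apply_predictions(pairs)
        edges = self._collect_edges(pairs)
        cross = [e for e in edges
                 if e.token_a.gene_id != e.token_b.gene_id
                 or e.token_a.key != e.token_b.key]
        conflicts = unify_labels(self.genes, cross, self.config)
        self.conflicts.extend(conflicts["conflicts"])
        kept = conflicts["orthologies"]
        closure = _close_site_components(self.genes, kept)
        all_orth = kept + closure
        comp_of, components = _components(self.genes, all_orth)
        # keep self-edges available for pairwise bijection queries
        self._self_edges = [e for e in edges if e not in cross]
        return TripletComparison(self.genes, all_orth, self.conflicts,
                                 self.dropped_blocks, components, comp_of)


def _contained(ival, coverage) -> bool:
    s, e = ival
    return any(cs <= s and e <= ce for cs, ce in coverage)


def _motif_at(kind: str, locus: str, pos: int) -> str:
    if kind == DONOR:
        return locus[pos:pos + 2]
    if kind == ACCEPTOR:
        return locus[max(0, pos - 2):pos]
    if kind == START:
        return locus[pos:pos + 3]
    return locus[max(0, pos - 3):pos]


def _order_sources(sources: set[str], config: Config) -> tuple[str, ...]:
    def key(s):
        try:
            return (config.species_order.index(s), s)
        except ValueError:
            return (len(config.species_order), s)
    return tuple(sorted(sources, key=key))


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb, key=str)] = min(ra, rb, key=str)


def unify_labels(genes: dict[str, GeneModel],
                 orthologies: list[TokenOrthology],
                 config: Config = DEFAULT_CONFIG) -> dict:
    """Assign one letter per cross-gene block-orthology component.

    Labelling is per connected set of the orthology relation (chained
    orthologies i-j, j-k give all three blocks the same letter).  An edge
    that would force two distinct blocks of one gene onto one letter is a
    conflict: the offending orthologies are dropped and reported.  Returns
    ``{"orthologies": kept, "conflicts": messages}``; gene models are
    relabelled in place.  Within-gene token order (by coordinate) is
    untouched.
    """
    uf = _UnionFind()
    registry: dict[tuple, Token] = {}
    for g in genes.values():
        for tok in g.tokens:
            registry[tok.key] = tok

    # per union-find root: gene_id -> token keys in the component
    members: dict[tuple, dict[str, set[tuple]]] = {}

    kept: list[TokenOrthology] = []
    conflicts: list[str] = []
    block_edges = [o for o in orthologies if o.token_a.kind == BLOCK]
    site_edges = [o for o in orthologies if o.token_a.kind != BLOCK]
    for orth in block_edges:
        ka, kb = orth.token_a.key, orth.token_b.key
        ra, rb = uf.find(ka), uf.find(kb)
        ma = members.setdefault(ra, {orth.token_a.gene_id: {ka}})
        mb = members.setdefault(rb, {orth.token_b.gene_id: {kb}})
        if ra == rb:
            kept.append(orth)
            continue
        clash = any(len(ma.get(gid, set()) | mb.get(gid, set())) > 1
                    for gid in set(ma) | set(mb))
        if clash:
            conflicts.append(
                f"label merge {orth.token_a.gene_id}:{orth.token_a.start}-"
                f"{orth.token_a.end} ~ {orth.token_b.gene_id}:"
                f"{orth.token_b.start}-{orth.token_b.end} would fuse two "
                "blocks of one gene; orthology dropped")
            continue
        uf.union(ka, kb)
        root = uf.find(ka)
        merged: dict[str, set] = {}
        for d in (ma, mb):
            for gid, toks in d.items():
                merged.setdefault(gid, set()).update(toks)
        members[root] = merged
        kept.append(orth)

    # letters per component, ordered by the earliest member in species order
    def order_key(gid):
        g = genes[gid]
        try:
            return (config.species_order.index(g.species), gid)
        except ValueError:
            return (len(config.species_order), gid)

    all_blocks = [t for g in genes.values() for t in g.blocks()]
    roots: dict[tuple, list[Token]] = {}
    for tok in all_blocks:
        roots.setdefault(uf.find(tok.key), []).append(tok)
    comp_order = sorted(
        roots.values(),
        key=lambda toks: min((order_key(t.gene_id), t.start) for t in toks))
    if len(comp_order) > 26:
        raise ValueError("more than 26 unified block labels required")
    for letter, toks in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", comp_order):
        for tok in toks:
            tok.label = letter
    return {"orthologies": kept + site_edges, "conflicts": conflicts}


def _components(genes, orthologies):
    uf = _UnionFind()
    registry: dict[tuple, Token] = {}
    for g in genes.values():
        for tok in g.tokens:
            registry[tok.key] = tok
    for o in orthologies:
        uf.union(o.token_a.key, o.token_b.key)
        registry.setdefault(o.token_a.key, o.token_a)
        registry.setdefault(o.token_b.key, o.token_b)
    groups: dict = {}
    for key, tok in registry.items():
        groups.setdefault(uf.find(key), []).append(tok)
    components = [sorted(toks, key=lambda t: (t.gene_id, t.sort_key))
                  for root, toks in sorted(groups.items(), key=lambda kv:
                                           str(kv[0]))]
    comp_of = {t.key: i for i, toks in enumerate(components) for t in toks}
    return comp_of, components


def _close_site_components(genes, orthologies) -> list[TokenOrthology]:
    """Add missing cross-gene edges inside site components that have at
    most one site per gene: sites aligned to a common ortholog are
    orthologous to each other even if never directly compared."""
    comp_of, components = _components(genes, orthologies)
    have = {frozenset((o.token_a.key, o.token_b.key)) for o in orthologies}
    closure: list[TokenOrthology] = []
    for toks in components:
        sites = [t for t in toks if t.kind != BLOCK]
        if len(sites) < 3 or len(sites) != len(toks):
            continue
        per_gene: dict[str, list[Token]] = {}
        for t in sites:
            per_gene.setdefault(t.gene_id, []).append(t)
        if any(len(v) > 1 for v in per_gene.values()):
            continue  # conflicted component; leave as aligned
        for i, ta in enumerate(sites):
            for tb in sites[i + 1:]:
                if ta.gene_id == tb.gene_id:
                    continue
                key = frozenset((ta.key, tb.key))
                if key not in have:
                    have.add(key)
                    closure.append(TokenOrthology(ta, tb, None))
    return closure


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------

def compare_genes(gene_a: GeneModel, gene_b: GeneModel,
                  config: Config = DEFAULT_CONFIG) -> PairwiseComparison:
    """Full pairwise comparison of two orthologous genes.

    Runs colinear anchoring in both directions, records token orthologies,
    creates predicted tokens in unannotated sequence, re-segments both
    models and unifies block labels.  Works on copies; the inputs are not
    modified.  Comparing a gene with itself yields the identity bijection
    and no predictions.
    """
    self_compare = gene_a.gene_id == gene_b.gene_id
    if self_compare:
        comp = _Comparator({gene_a.gene_id: gene_a}, config)
        pairs = [(gene_a.gene_id, gene_a.gene_id)]
    else:
        comp = _Comparator({gene_a.gene_id: gene_a,
                            gene_b.gene_id: gene_b}, config)
        pairs = [(gene_a.gene_id, gene_b.gene_id),
                 (gene_b.gene_id, gene_a.gene_id)]
    result = comp.run(pairs)
    ga = result.genes[gene_a.gene_id]
    gb = result.genes[gene_b.gene_id]
    orthologies = list(result.orthologies)
    if self_compare:
        orthologies = comp._self_edges
        gb = ga
    predicted_a = [t for t in ga.tokens if t.status == "predicted"]
    predicted_b = [] if self_compare else \
        [t for t in gb.tokens if t.status == "predicted"]
    linked = {k for o in orthologies for k in (o.token_a.key, o.token_b.key)}
    unaligned = {
        ga.gene_id: [t for t in ga.tokens if t.key not in linked],
        gb.gene_id: [t for t in gb.tokens if t.key not in linked],
    }
    if self_compare:
        unaligned = {ga.gene_id: [t for t in ga.tokens
                                  if t.key not in linked]}
    return PairwiseComparison(ga, gb, orthologies, predicted_a, predicted_b,
                              unaligned, comp.conflicts)


def compare_triplet(genes: dict[str, GeneModel],
                    config: Config = DEFAULT_CONFIG) -> TripletComparison:
    """Compare a set of orthologous genes (one per species) all-vs-all.

    Ordered pairs follow ``config.species_order`` (human->mouse, human->dog,
    mouse->dog by default, each direction run once); only tokens known at
    entry seed alignments, so predictions never chain across pairs.
    """
    return _Comparator(genes, config).run()
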
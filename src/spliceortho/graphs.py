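"""Per-triplet orthology graphs, classification, and CDS orthology groups.

The *functional-site graph* has one node per start/stop codon and splice
site involved in a known or predicted transcript of the three genes, and
one edge per cross-gene site orthology.  Its connected components classify
as singletons (site in one species), couples (two species), triplets
(three species, all three pairwise edges) or irregular; a gene triplet is
*retained* when no component is irregular and *structurally orthologous*
when every component is a triplet.

The *transcript graph* has one node per known or predicted transcript and
an edge between every cross-gene pair of transcripts with equal
(unified-label) model strings -- spliced CDS orthologs.  Components
spanning the three species are *CDS orthology groups*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .align import TripletComparison
from .models import GeneModel, Token, TranscriptModel, TranscriptRecord

__all__ = [
    "SiteGraph",
    "TranscriptGraph",
    "CDSOrthologyGroup",
    "build_site_graph",
    "classify_components",
    "build_transcript_graph",
    "extract_groups",
    "find_redundant_sets",
]


# --------------------------------------------------------------------------
# functional-site graph
# --------------------------------------------------------------------------

@dataclass
class SiteGraph:
    graph: nx.Graph
    tokens: dict[tuple, Token]

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_site_graph(comparison: TripletComparison) -> SiteGraph:
    """Graph over the functional sites involved in known and predicted
    transcripts, with cross-gene orthology edges."""
    g = nx.Graph()
    tokens: dict[tuple, Token] = {}
    for gene in comparison.genes.values():
        for tm in gene.transcripts:
            for tok in tm.tokens:
                if tok.is_site:
                    tokens[tok.key] = tok
                    g.add_node(tok.key, species=gene.species,
                               gene_id=gene.gene_id, kind=tok.kind,
                               status=tok.status)
    for orth in comparison.site_orthologies():
        ka, kb = orth.token_a.key, orth.token_b.key
        if ka in tokens and kb in tokens and ka != kb:
            g.add_edge(ka, kb)
    return SiteGraph(g, tokens)


def classify_components(sg: SiteGraph) -> tuple[list[tuple[set, str]], dict]:
    """Classify site-graph components and derive the gene-triplet verdict.

    Component classes: ``singleton`` (one node), ``couple`` (two nodes of
    two species), ``triplet`` (three nodes of three species forming a
    3-clique: a site shared by all three species via three pairwise
    orthologies), ``irregular`` otherwise (including two same-species
    nodes in one component, or a 3-node path missing an edge).

    Verdict: ``retained`` iff no component is irregular;
    ``structurally_orthologous`` iff every component is a triplet.
    """
    classes: list[tuple[set, str]] = []
    for comp in sg.components:
        species = [sg.graph.nodes[n]["species"] for n in comp]
        n = len(comp)
        if n == 1:
            cls = "singleton"
        elif n == 2 and len(set(species)) == 2:
            cls = "couple"
        elif n == 3 and len(set(species)) == 3 \
                and sg.graph.subgraph(comp).number_of_edges() == 3:
            cls = "triplet"
        else:
            cls = "irregular"
        classes.append((comp, cls))
    kinds = [cls for _c, cls in classes]
    verdict = {
        "retained": "irregular" not in kinds,
        "structurally_orthologous": bool(kinds) and
        all(k == "triplet" for k in kinds),
    }
    return classes, verdict


# --------------------------------------------------------------------------
# transcript graph and CDS orthology groups
# --------------------------------------------------------------------------

@dataclass
class TranscriptGraph:
    graph: nx.Graph
    models: dict[tuple[str, str], TranscriptModel]

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]


def build_transcript_graph(comparison: TripletComparison) -> TranscriptGraph:
    """Nodes: known plus predicted transcripts; edges: cross-gene pairs
    with equal model strings (spliced CDS orthologs)."""
    g = nx.Graph()
    models: dict[tuple[str, str], TranscriptModel] = {}
    nodes = []
    for gene in comparison.genes.values():
        for tm in gene.transcripts:
            node = (gene.gene_id, tm.transcript_id)
            models[node] = tm
            g.add_node(node, species=gene.species, status=tm.status,
                       model=tm.model_string)
            nodes.append(node)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if a[0] != b[0] and g.nodes[a]["model"] == g.nodes[b]["model"]:
                g.add_edge(a, b)
    return TranscriptGraph(g, models)


@dataclass
class CDSOrthologyGroup:
    """Cross-species set of transcripts sharing one spliced CDS structure."""

    group_id: str
    model_string: str
    #: species -> [(transcript_id, status)]
    members: dict[str, list[tuple[str, str]]]
    #: species -> number of known transcripts encoding this CDS
    redundancy: dict[str, int] = field(default_factory=dict)


def extract_groups(tg: TranscriptGraph,
                   species: tuple[str, ...] = ("human", "mouse", "dog")
                   ) -> tuple[list[CDSOrthologyGroup], dict]:
    """CDS orthology groups and the per-gene conservation verdicts.

    One group per connected component spanning all species.  The verdict
    ``all_conserved`` holds iff every component spans all species (no CDS
    is species-specific or missing somewhere); ``single_copy`` additionally
    requires exactly one known-or-predicted transcript per species per
    component.
    """
    groups: list[CDSOrthologyGroup] = []
    all_conserved = True
    single_copy = True
    comps = sorted(tg.components,
                   key=lambda c: min(tg.graph.nodes[n]["model"] for n in c))
    for comp in comps:
        per_species: dict[str, list[tuple[str, str]]] = {}
        for node in sorted(comp):
            data = tg.graph.nodes[node]
            per_species.setdefault(data["species"], []).append(
                (node[1], data["status"]))
        spans_all = all(sp in per_species for sp in species)
        if not spans_all:
            all_conserved = False
            single_copy = False
            continue
        if any(len(v) != 1 for v in per_species.values()):
            single_copy = False
        model = tg.graph.nodes[next(iter(comp))]["model"]
        redundancy = {sp: sum(1 for _t, st in per_species.get(sp, [])
                              if st == "known") for sp in species}
        groups.append(CDSOrthologyGroup(
            f"group{len(groups) + 1}", model, per_species, redundancy))
    verdict = {"all_conserved": all_conserved and bool(comps),
               "single_copy": single_copy and all_conserved and bool(comps)}
    return groups, verdict


# --------------------------------------------------------------------------
# redundant-CDS enumeration
# --------------------------------------------------------------------------

def find_redundant_sets(gene: GeneModel,
                        records: list[TranscriptRecord]
                        ) -> tuple[list[list[str]], list[str]]:
    """Maximal sets (size >= 2) of known transcripts encoding one CDS.

    Transcripts lacking a 5' or 3' UTR are excluded from the enumeration
    (their identical CDS may reflect incomplete annotation rather than
    genuine alternative transcription) and reported separately.
    """
    utr_ok = {r.transcript_id: (r.has_utr5 and r.has_utr3) for r in records}
    excluded = []
    by_model: dict[str, list[str]] = {}
    for tm in gene.known_transcripts():
        complete = utr_ok.get(tm.transcript_id, False)
        if not complete:
            excluded.append(tm.transcript_id)
            continue
        by_model.setdefault(tm.model_string, []).append(tm.transcript_id)
    sets = [sorted(tids) for _m, tids in sorted(by_model.items())
            if len(tids) >= 2]
    return sets, sorted(excluded)
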
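"""Shared fixtures and helpers for the test suite.

Fixtures are generated programmatically by :mod:`spliceortho.synthetic`;
nothing is read from checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from spliceortho.io_formats import load_species
from spliceortho.models import (
    DEFAULT_CONFIG, GeneModel, build_gene_model, build_transcript_model,
    is_valid_cds, parse_model_string,
)
from spliceortho.pipeline import run_analysis
from spliceortho.synthetic import figure_fixtures, realize

FIXTURE_SEED = 7


def build_models(fx, species, config=DEFAULT_CONFIG):
    """Load a realized fixture and build one GeneModel per gene."""
    out = {}
    for sp in species:
        sd = load_species(fx.gtf[sp], fx.fasta[sp], sp, config)
        for gid, gi in sd.genes.items():
            tms = [build_transcript_model(r, gi.locus, config)
                   for r in gi.records]
            out[gid] = build_gene_model(tms, gi.locus, species=sp,
                                        strand=gi.strand, config=config)
    return out


def run_fixture(fx, config=DEFAULT_CONFIG):
    """Run the full pipeline on a realized fixture's files."""
    species_files = {sp: (fx.gtf[sp], fx.fasta[sp]) for sp in fx.species}
    junctions = {sp: fx.junctions[sp] for sp in fx.species}
    return run_analysis(species_files, fx.ortholog_map, junctions,
                        config=config)


@pytest.fixture(scope="session")
def figure_runs(tmp_path_factory):
    """Realized figure fixtures plus their full pipeline runs."""
    runs = {}
    for name, spec in figure_fixtures(seed=FIXTURE_SEED).items():
        fx = realize(spec, tmp_path_factory.mktemp(f"fx_{name}"))
        report, species_data = run_fixture(fx)
        runs[name] = (fx, report, species_data)
    return runs


# --------------------------------------------------------------------------
# property-suite helpers (shared between topic tests and acceptance tests)
# --------------------------------------------------------------------------

_GAP_PATTERNS = ("", "<>", "]>", ">", "][")


def random_model_string(rng: np.random.Generator) -> str:
    """A random grammar-valid model string."""
    n = int(rng.integers(1, 9))
    out = ["["]
    for i in range(n):
        out.append(chr(ord("A") + i))
        if i < n - 1:
            out.append(_GAP_PATTERNS[int(rng.integers(len(_GAP_PATTERNS)))])
    out.append("]")
    return "".join(out)


def site_roles(realized_gene):
    """Map each planted site position to a species-independent role."""
    roles = {}
    for label, (s, e) in realized_gene.coords.items():
        for kind, pos in realized_gene.planted_sites:
            if pos == s:
                roles[(kind, pos)] = (kind, label, "5p")
            elif pos == e:
                roles[(kind, pos)] = (kind, label, "3p")
    return roles


def site_recovery(comparison, fixture, fixture_name):
    """Precision/recall of recovered cross-species site orthologies
    against the planted ground truth."""
    role_of = {}
    species_of = {}
    for (name, sp), rg in fixture.genes.items():
        if name != fixture_name:
            continue
        roles = site_roles(rg)
        for key, role in roles.items():
            role_of[(rg.gene_id, key)] = role
        species_of[rg.gene_id] = sp
    # planted cross-species pairs: same role in two genes
    by_role = {}
    for (gid, key), role in role_of.items():
        by_role.setdefault(role, []).append((gid, key))
    planted = set()
    for role, entries in by_role.items():
        for i, a in enumerate(entries):
            for b in entries[i + 1:]:
                if a[0] != b[0]:
                    planted.add(frozenset((a, b)))
    recovered = set()
    false_positive = 0
    for orth in comparison.site_orthologies():
        ta, tb = orth.token_a, orth.token_b
        ra = role_of.get((ta.gene_id, (ta.kind, ta.start)))
        rb = role_of.get((tb.gene_id, (tb.kind, tb.start)))
        pair = frozenset(((ta.gene_id, (ta.kind, ta.start)),
                          (tb.gene_id, (tb.kind, tb.start))))
        if ra is None or rb is None or ra != rb or pair not in planted:
            false_positive += 1
        else:
            recovered.add(pair)
    n_rec = len(recovered) + false_positive
    precision = len(recovered) / n_rec if n_rec else 1.0
    recall = len(recovered) / len(planted) if planted else 1.0
    return precision, recall


def brute_force_models(gene: GeneModel, config=DEFAULT_CONFIG) -> set[str]:
    """Independent oracle: every grammar-valid block chain of a gene model
    whose assembled sequence is a valid CDS, by exhaustive enumeration."""
    blocks = gene.blocks()
    starts = {t.start for t in gene.tokens if t.kind == "start"}
    stops = {t.start for t in gene.tokens if t.kind == "stop"}
    donors = {t.start for t in gene.tokens if t.kind == "donor"}
    acceptors = {t.start for t in gene.tokens if t.kind == "acceptor"}
    found: set[str] = set()
    n = len(blocks)
    for mask in range(1, 2 ** n):
        chosen = [blocks[i] for i in range(n) if mask >> i & 1]
        if chosen[0].start not in starts or chosen[-1].end not in stops:
            continue
        symbols = ["[", chosen[0].label]
        ok = True
        for u, v in zip(chosen, chosen[1:]):
            if u.end == v.start:
                symbols.append(v.label)
            elif u.end in donors and v.start in acceptors:
                symbols += ["<", ">", v.label]
            else:
                ok = False
                break
        if not ok:
            continue
        symbols.append("]")
        seq = "".join(gene.locus[b.start:b.end] for b in chosen)
        valid, _ = is_valid_cds(seq, config)
        if valid:
            found.add("".join(symbols))
    return found


def assert_round_trip(text: str) -> None:
    from spliceortho.models import format_model
    assert format_model(parse_model_string(text)) == text
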
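"""Token alignment, orthology, prediction of sites/blocks, unification."""

import pytest

from spliceortho.align import (
    TokenOrthology, align_token, compare_genes, compare_triplet,
    unify_labels,
)
from spliceortho.models import (
    ACCEPTOR, BLOCK, DONOR, STOP, Config, GeneModel, Token,
)
from spliceortho.synthetic import random_fixture_spec, realize

from conftest import build_models, site_recovery


@pytest.fixture(scope="module")
def fig1_models(figure_runs):
    fx, _report, _sd = figure_runs["fig1"]
    return fx, build_models(fx, fx.species)


class TestAlignToken:
    def test_block_against_own_gene_hits_itself(self, fig1_models):
        _fx, models = fig1_models
        gene = models["mouse_fig1"]
        for block in gene.known_blocks():
            hit = align_token(block, gene, gene)
            assert hit is not None
            assert (hit.start, hit.end) == (block.start, block.end)
            assert hit.identity == 1.0

    def test_empty_window_is_no_hit(self, fig1_models):
        _fx, models = fig1_models
        gene = models["mouse_fig1"]
        block = gene.known_blocks()[0]
        assert align_token(block, gene, gene, window=(50, 50)) is None

    def test_site_requires_exact_motif(self, fig1_models):
        """A predicted site is only accepted on the canonical motif."""
        fx, models = fig1_models
        mouse = models["mouse_fig1"]
        human = models["human_fig1"]
        planted_c = fx.genes[("fig1", "human")].coords["C"]
        acc = mouse.site_at(ACCEPTOR,
                            fx.genes[("fig1", "mouse")].coords["C"][0])
        hit = align_token(acc, mouse, human)
        assert hit is not None and hit.start == planted_c[0]
        # destroying the motif suppresses the hit
        broken = GeneModel(human.gene_id, human.species, human.strand,
                           human.locus[:planted_c[0] - 2] + "TT"
                           + human.locus[planted_c[0]:],
                           list(human.tokens), list(human.transcripts),
                           list(human.known_coverage))
        assert align_token(acc, mouse, broken) is None


class TestCompareGenes:
    def test_self_comparison_is_identity(self, fig1_models):
        _fx, models = fig1_models
        gene = models["mouse_fig1"]
        comp = compare_genes(gene, gene)
        assert comp.predicted_tokens_a == []
        linked = {o.token_a.key for o in comp.orthologies}
        assert linked == {t.key for t in comp.gene_a.tokens}
        assert all(o.token_a.key == o.token_b.key for o in comp.orthologies)
        assert comp.unaligned_tokens[gene.gene_id] == []

    def test_self_comparison_on_random_fixtures(self, tmp_path):
        """Identity mapping and zero predictions on 50 random genes."""
        for seed in range(50):
            spec = random_fixture_spec(seed + 1000)
            fx = realize(spec, tmp_path / f"s{seed}")
            models = build_models(fx, ("human",))
            (gene,) = models.values()
            comp = compare_genes(gene, gene)
            assert comp.predicted_tokens_a == [], seed
            linked = {o.token_a.key for o in comp.orthologies}
            assert linked == {t.key for t in comp.gene_a.tokens}, seed

    def test_mouse_vs_human_predicts_internal_acceptors(self, fig1_models):
        """The human gene, knowing only the BC and EF exon forms, gains
        predicted acceptors for the C and F alternative 5' extensions."""
        fx, models = fig1_models
        comp = compare_genes(models["mouse_fig1"], models["human_fig1"])
        planted = fx.genes[("fig1", "human")]
        predicted = {(t.kind, t.start) for t in comp.predicted_tokens_b}
        assert (ACCEPTOR, planted.coords["C"][0]) in predicted
        assert (ACCEPTOR, planted.coords["F"][0]) in predicted
        assert not any(t.kind == BLOCK for t in comp.predicted_tokens_b)
        # predictions carry the source species
        assert all(t.sources == ("mouse",) for t in comp.predicted_tokens_b)

    def test_mouse_vs_dog_predicts_block_b(self, fig1_models):
        """The dog gene gains coding block B plus its acceptor."""
        fx, models = fig1_models
        comp = compare_genes(models["mouse_fig1"], models["dog_fig1"])
        planted = fx.genes[("fig1", "dog")]
        pred_blocks = [(t.start, t.end) for t in comp.predicted_tokens_b
                       if t.kind == BLOCK]
        assert planted.coords["B"] in pred_blocks
        pred_sites = {(t.kind, t.start) for t in comp.predicted_tokens_b
                      if t.is_site}
        assert (ACCEPTOR, planted.coords["B"][0]) in pred_sites

    def test_predicted_site_motifs_match_consensus(self, fig1_models):
        fx, models = fig1_models
        comp = compare_genes(models["mouse_fig1"], models["dog_fig1"])
        for tok in comp.predicted_tokens_b:
            if tok.kind == ACCEPTOR:
                assert tok.motif == "AG"
            elif tok.kind == DONOR:
                assert tok.motif == "GT"

    def test_orthology_symmetry(self, fig1_models):
        _fx, models = fig1_models
        comp = compare_genes(models["mouse_fig1"], models["human_fig1"])
        keys = [o.key for o in comp.orthologies]
        assert len(keys) == len(set(keys))  # stored once
        for o in comp.orthologies:
            assert o.other(o.token_a) is o.token_b
            assert o.other(o.token_b) is o.token_a

    def test_colinearity(self, figure_runs):
        """Orthologous token pairs appear in the same relative order in
        both genes of every comparison."""
        for name, (_fx, report, _sd) in figure_runs.items():
            comparison = report.triplets[0].comparison
            by_pair = {}
            for o in comparison.orthologies:
                a, b = sorted((o.token_a, o.token_b),
                              key=lambda t: t.gene_id)
                by_pair.setdefault((a.gene_id, b.gene_id), []).append((a, b))
            for pairs in by_pair.values():
                pairs.sort(key=lambda ab: ab[0].sort_key)
                b_positions = [ab[1].sort_key for ab in pairs]
                assert b_positions == sorted(b_positions), name


class TestUnifyLabels:
    def _gene(self, gid, blocks):
        tokens = [Token(BLOCK, gene_id=gid, start=s, end=e)
                  for s, e in blocks]
        return GeneModel(gene_id=gid, species=gid, tokens=tokens)

    def test_chained_orthologies_share_one_letter(self):
        """Union-find oracle: i~j and j~k edges suffice for one label."""
        gi = self._gene("i", [(0, 10)])
        gj = self._gene("j", [(0, 10)])
        gk = self._gene("k", [(0, 10)])
        genes = {"i": gi, "j": gj, "k": gk}
        orth = [TokenOrthology(gi.tokens[0], gj.tokens[0], 1.0),
                TokenOrthology(gj.tokens[0], gk.tokens[0], 1.0)]
        config = Config(species_order=("i", "j", "k"))
        res = unify_labels(genes, orth, config)
        assert res["conflicts"] == []
        assert gi.tokens[0].label == gj.tokens[0].label \
            == gk.tokens[0].label == "A"

    def test_conflicting_merge_is_dropped_and_reported(self):
        gi = self._gene("i", [(0, 10), (20, 30)])
        gj = self._gene("j", [(0, 10)])
        genes = {"i": gi, "j": gj}
        orth = [TokenOrthology(gi.tokens[0], gj.tokens[0], 1.0),
                TokenOrthology(gi.tokens[1], gj.tokens[0], 0.9)]
        config = Config(species_order=("i", "j"))
        res = unify_labels(genes, orth, config)
        assert len(res["conflicts"]) == 1
        assert gi.tokens[0].label != gi.tokens[1].label

    def test_identical_genes_get_identical_strings(self, figure_runs):
        fx, report, _sd = figure_runs["fig1"]
        genes = report.triplets[0].comparison.genes
        strings = {g.model_string for g in genes.values()}
        assert len(strings) == 1  # fully unified triplet


class TestPlantedRecovery:
    def test_full_recovery_at_identity_one(self, tmp_path):
        """At 100% block identity and divergent introns the pipeline
        recovers exactly the planted site orthologies."""
        for seed in (21, 22, 23):
            spec = random_fixture_spec(seed,
                                       species=("human", "mouse", "dog"))
            fx = realize(spec, tmp_path / f"r{seed}")
            models = build_models(fx, fx.species)
            comparison = compare_triplet(models)
            precision, recall = site_recovery(comparison, fx, spec.name)
            assert precision == 1.0, seed
            assert recall == 1.0, seed

    def test_recovery_monotone_in_identity(self, tmp_path):
        """Degrading block identity below the alignment threshold turns
        planted orthologies into singletons; recovery never increases as
        identity decreases."""
        from dataclasses import replace
        for seed in (31, 32):
            recalls = []
            for ident in (1.0, 0.9, 0.5, 0.2):
                spec = replace(
                    random_fixture_spec(seed,
                                        species=("human", "mouse", "dog")),
                    block_identity=ident)
                fx = realize(spec, tmp_path / f"m{seed}_{ident}")
                models = build_models(fx, fx.species)
                comparison = compare_triplet(models)
                _p, recall = site_recovery(comparison, fx, spec.name)
                recalls.append(recall)
            assert recalls[0] == 1.0, seed
            assert all(a >= b for a, b in zip(recalls, recalls[1:])), \
                (seed, recalls)
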
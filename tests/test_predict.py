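"""Expressibility, executability, transcript prediction, and the
brute-force enumeration oracle."""

from dataclasses import replace

import pytest

from spliceortho.align import compare_triplet
from spliceortho.models import (
    Config, TranscriptRecord, assemble_cds_sequence, build_gene_model,
    build_transcript_model, is_valid_cds,
)
from spliceortho.predict import is_executable, is_expressible, \
    predict_transcripts
from spliceortho.synthetic import random_fixture_spec, realize

from conftest import brute_force_models, build_models


@pytest.fixture(scope="module")
def fig5_comparison(figure_runs):
    _fx, report, _sd = figure_runs["fig5"]
    return report.triplets[0].comparison


def _known(comparison, gene_id, model_string):
    gene = comparison.genes[gene_id]
    for tm in gene.known_transcripts():
        if tm.model_string == model_string:
            return tm
    raise KeyError(model_string)


class TestExpressible:
    def test_c_transcript_feasible_in_gene_with_predicted_elements(
            self, fig5_comparison):
        """The C-containing structure, known only in mouse, becomes
        expressible in human once the block and its flanking sites are
        predicted there."""
        t_c = _known(fig5_comparison, "mouse_fig5", "[A<>B<>C]")
        human = fig5_comparison.genes["human_fig5"]
        assert is_expressible(t_c, human, fig5_comparison)

    def test_unfeasible_where_block_is_deleted(self, fig5_comparison):
        """Gene k lacks block C entirely: no ortholog, not expressible."""
        t_c = _known(fig5_comparison, "mouse_fig5", "[A<>B<>C]")
        dog = fig5_comparison.genes["dog_fig5"]
        assert not is_expressible(t_c, dog, fig5_comparison)

    def test_own_gene_is_always_expressible(self, fig5_comparison):
        for gene in fig5_comparison.genes.values():
            for tm in gene.known_transcripts():
                assert is_expressible(tm, gene, fig5_comparison)


class TestExecutable:
    def test_known_transcript_in_own_gene_yields_annotated_cds(
            self, fig5_comparison):
        for gene in fig5_comparison.genes.values():
            for tm in gene.known_transcripts():
                ok, seq, reason = is_executable(tm, gene, fig5_comparison)
                assert ok, reason
                assert seq == assemble_cds_sequence(tm, gene.locus)

    def test_frame_shifted_ortholog_is_expressible_not_executable(self):
        """A block ortholog lengthened by one nucleotide keeps the
        structure expressible but breaks the reading frame."""
        intron1 = "GT" + "ATATATATATAT" + "AG"
        intron2 = "GT" + "CGCGCGCGCGCG" + "AG"
        a = "ATGGCACCA"
        b = "GGACCTGGACCT"
        c = "GGGCCATAA"
        flank = "TTTTTTTT"
        locus_x = flank + a + intron1 + b + intron2 + c + flank
        b_long = b[:6] + "A" + b[6:]
        locus_y = flank + a + intron1 + b_long + intron2 + c + flank

        f = len(flank)
        x_chain = [(f, f + 9), (f + 9 + 16, f + 9 + 16 + 12),
                   (f + 9 + 16 + 12 + 16, f + 9 + 16 + 12 + 16 + 9)]
        y_chain = [(f, f + 9),
                   (f + 9 + 16 + 13 + 16, f + 9 + 16 + 13 + 16 + 9)]
        gx = build_gene_model(
            [build_transcript_model(
                TranscriptRecord("x1", "gx", x_chain), locus_x)],
            locus_x, species="human")
        gy = build_gene_model(
            [build_transcript_model(
                TranscriptRecord("y1", "gy", y_chain), locus_y)],
            locus_y, species="mouse")
        config = Config(frame_check_at_alignment=False,
                        species_order=("human", "mouse"))
        comparison = compare_triplet({"gx": gx, "gy": gy}, config)
        t_x = comparison.genes["gx"].known_transcripts()[0]
        target = comparison.genes["gy"]
        assert is_expressible(t_x, target, comparison)
        ok, seq, reason = is_executable(t_x, target, comparison, config)
        assert not ok
        assert reason == "frame"
        assert len(seq) % 3 == 1  # one inserted nucleotide


class TestPredictTranscripts:
    def test_fig1_five_predictions(self, figure_runs):
        _fx, report, _sd = figure_runs["fig1"]
        t = report.triplets[0]
        counts = {gid.split("_")[0]: len(p)
                  for gid, p in t.predictions.items()}
        assert counts == {"human": 2, "mouse": 0, "dog": 3}

    def test_identical_genes_no_predictions(self, tmp_path):
        """Three species with identical known structures: nothing to
        predict."""
        spec = random_fixture_spec(55, species=("human", "mouse", "dog"))
        fx = realize(spec, tmp_path)
        models = build_models(fx, fx.species)
        comparison = compare_triplet(models)
        preds = predict_transcripts(comparison)
        assert all(v == [] for v in preds.values())

    def test_no_prediction_where_block_deleted(self, figure_runs):
        _fx, report, _sd = figure_runs["fig5"]
        t = report.triplets[0]
        assert t.predictions["dog_fig5"] == []
        assert [p.model_string for p in t.predictions["human_fig5"]] \
            == ["[A<>B<>C]"]

    def test_predictions_are_valid_and_have_known_orthologs(
            self, figure_runs):
        """Every predicted CDS passes validity, equals its source model
        string exactly, and has a known spliced-CDS ortholog."""
        for name, (_fx, report, _sd) in figure_runs.items():
            t = report.triplets[0]
            known_by_string = {}
            for gene in t.comparison.genes.values():
                for tm in gene.known_transcripts():
                    known_by_string.setdefault(tm.model_string, []).append(
                        (gene.gene_id, tm.transcript_id))
            for gid, preds in t.predictions.items():
                gene = t.comparison.genes[gid]
                for p in preds:
                    seq = assemble_cds_sequence(p, gene.locus)
                    ok, reason = is_valid_cds(seq)
                    assert ok, (name, p.transcript_id, reason)
                    partners = known_by_string.get(p.model_string, [])
                    assert any(g != gid for g, _t in partners), \
                        (name, p.transcript_id)

    def test_sources_recorded_in_species_order(self, figure_runs):
        _fx, report, _sd = figure_runs["fig1"]
        t = report.triplets[0]
        for preds in t.predictions.values():
            for p in preds:
                assert p.sources
                order = ("human", "mouse", "dog")
                idx = [order.index(s) for s in p.sources]
                assert idx == sorted(idx)

    def test_deterministic_ids_in_model_string_order(self, figure_runs):
        _fx, report, _sd = figure_runs["fig1"]
        t = report.triplets[0]
        for gid, preds in t.predictions.items():
            strings = [p.model_string for p in preds]
            assert strings == sorted(strings)
            assert [p.transcript_id for p in preds] == \
                [f"{gid}.pred{i}" for i in range(1, len(preds) + 1)]


class TestBruteForceOracle:
    @pytest.mark.parametrize("name", ["fig4", "fig5"])
    def test_enumeration_superset_on_small_gene_models(self, figure_runs,
                                                       name):
        """On gene models with few tokens, exhaustive enumeration of all
        grammar-valid, CDS-valid block chains contains every known and
        predicted model, and every predicted model is in it."""
        _fx, report, _sd = figure_runs[name]
        t = report.triplets[0]
        for gid, gene in t.comparison.genes.items():
            assert len(gene.tokens) <= 12
            oracle = brute_force_models(gene)
            known = {tm.model_string for tm in gene.known_transcripts()}
            predicted = {tm.model_string
                         for tm in gene.predicted_transcripts()}
            assert known | predicted <= oracle, (name, gid)
            assert predicted <= oracle

    def test_oracle_on_random_small_fixtures(self, tmp_path):
        for seed in (61, 62, 63, 64):
            spec = random_fixture_spec(seed,
                                       species=("human", "mouse", "dog"))
            fx = realize(spec, tmp_path / f"o{seed}")
            models = build_models(fx, fx.species)
            comparison = compare_triplet(models)
            predict_transcripts(comparison)
            for gid, gene in comparison.genes.items():
                if len(gene.tokens) > 12:
                    continue
                oracle = brute_force_models(gene)
                strings = {tm.model_string for tm in gene.transcripts}
                assert strings <= oracle, (seed, gid)
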
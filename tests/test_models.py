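"""Token grammar, structure models, CDS assembly and validity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spliceortho.models import (
    ACCEPTOR, BLOCK, DONOR, START, STOP,
    AlphabetError, GrammarError, ModelConflictError, StructureError,
    TranscriptRecord, assemble_cds_sequence, build_gene_model,
    build_transcript_model, format_model, is_valid_cds, parse_model_string,
)
from spliceortho.synthetic import random_fixture_spec, realize

from conftest import build_models, random_model_string, assert_round_trip


class TestGrammar:
    @pytest.mark.parametrize("text,kinds", [
        ("[A<>B<>C]", [START, BLOCK, DONOR, ACCEPTOR, BLOCK, DONOR,
                       ACCEPTOR, BLOCK, STOP]),
        ("[A]", [START, BLOCK, STOP]),
        ("[A<>B<>C]>D]", [START, BLOCK, DONOR, ACCEPTOR, BLOCK, DONOR,
                          ACCEPTOR, BLOCK, STOP, ACCEPTOR, BLOCK, STOP]),
    ])
    def test_parse_token_kinds(self, text, kinds):
        assert [t.kind for t in parse_model_string(text)] == kinds

    @pytest.mark.parametrize("text,offset", [
        ("A<>B]", 0),        # missing start
        ("", 0),             # empty
        ("[A<>B", 4),        # missing stop
        ("[A<B]", 2),        # donor without later acceptor
        ("[A*B]", 2),        # unknown symbol
        ("[<>]", 0),         # no coding block
    ])
    def test_parse_errors_carry_offset(self, text, offset):
        with pytest.raises(GrammarError) as err:
            parse_model_string(text)
        assert err.value.offset == offset

    def test_format_rejects_invalid_token_lists(self):
        tokens = parse_model_string("[A<>B]")
        with pytest.raises(StructureError):
            format_model(tokens[1:])  # first token not a start
        with pytest.raises(StructureError):
            format_model([])

    def test_round_trip_on_random_models(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            assert_round_trip(random_model_string(rng))


def _locus_with(exons, seq=None, n=200, seed=0):
    """Hand-made locus: random background with ATG/stop/GT/AG planted."""
    rng = np.random.default_rng(seed)
    locus = list(seq or "".join(rng.choice(list("ACGT")) for _ in range(n)))
    first, last = exons[0], exons[-1]
    locus[first[0]:first[0] + 3] = "ATG"
    locus[last[1] - 3:last[1]] = "TAA"
    for (s, e), (s2, _e2) in zip(exons, exons[1:]):
        locus[e:e + 2] = "GT"
        locus[s2 - 2:s2] = "AG"
    return "".join(locus)


class TestTranscriptModel:
    def test_three_exon_cds_shape(self):
        exons = [(10, 22), (40, 52), (80, 95)]
        locus = _locus_with(exons)
        rec = TranscriptRecord("t1", "g", exons)
        tm = build_transcript_model(rec, locus)
        assert tm.model_string == "[A<>B<>C]"

    def test_single_exon_cds(self):
        locus = _locus_with([(10, 25)])
        tm = build_transcript_model(TranscriptRecord("t", "g", [(10, 25)]),
                                    locus)
        assert tm.model_string == "[A]"

    def test_utr_variants_share_checksum(self):
        exons = [(10, 22), (40, 52)]
        locus = _locus_with(exons)
        a = build_transcript_model(
            TranscriptRecord("a", "g", exons, utr5_exons=[(2, 10)]), locus)
        b = build_transcript_model(
            TranscriptRecord("b", "g", exons, utr3_exons=[(52, 70)]), locus)
        assert a.cds_sequence_checksum == b.cds_sequence_checksum
        assert a.model_string == b.model_string

    def test_exon_outside_locus_rejected(self):
        from spliceortho.models import InputError
        with pytest.raises(InputError):
            build_transcript_model(
                TranscriptRecord("t", "g", [(10, 400)]), "A" * 100)


class TestGeneModel:
    def test_union_of_alternative_last_exons(self):
        # two transcripts sharing A and B, ending in C or in D
        e_c = [(10, 22), (40, 52), (80, 95)]
        e_d = [(10, 22), (40, 52), (120, 135)]
        locus = _locus_with(e_c, n=220)
        locus = _locus_with(e_d, seq=locus)
        tms = [build_transcript_model(TranscriptRecord("tc", "g", e_c), locus),
               build_transcript_model(TranscriptRecord("td", "g", e_d), locus)]
        gene = build_gene_model(tms, locus)
        assert gene.model_string == "[A<>B<>C]>D]"

    def test_single_transcript_gene_equals_transcript(self):
        exons = [(10, 22), (40, 52)]
        locus = _locus_with(exons)
        tm = build_transcript_model(TranscriptRecord("t", "g", exons), locus)
        gene = build_gene_model([tm], locus)
        assert gene.model_string == tm.model_string == "[A<>B]"

    def test_alternative_extension_becomes_adjacent_blocks(self):
        # exon BC in one transcript, exon C alone in the other
        e_bc = [(10, 22), (40, 61)]
        e_c = [(10, 22), (52, 61)]
        locus = _locus_with(e_bc)
        locus = _locus_with(e_c, seq=locus)
        tms = [build_transcript_model(TranscriptRecord("t1", "g", e_bc), locus),
               build_transcript_model(TranscriptRecord("t2", "g", e_c), locus)]
        gene = build_gene_model(tms, locus)
        assert gene.model_string == "[A<>B>C]"
        accs = [t for t in gene.tokens if t.kind == ACCEPTOR]
        assert [a.start for a in accs] == [40, 52]
        # both transcripts re-expressed as subsequences
        assert tms[0].model_string == "[A<>BC]"
        assert tms[1].model_string == "[A<>C]"

    def test_idempotent_rebuild(self):
        e_bc = [(10, 22), (40, 61)]
        e_c = [(10, 22), (52, 61)]
        locus = _locus_with(e_bc)
        locus = _locus_with(e_c, seq=locus)
        tms = [build_transcript_model(TranscriptRecord("t1", "g", e_bc), locus),
               build_transcript_model(TranscriptRecord("t2", "g", e_c), locus)]
        gene = build_gene_model(tms, locus)
        again = build_gene_model(gene.transcripts, locus)
        assert again.model_string == gene.model_string
        assert [(t.kind, t.start, t.end) for t in again.tokens] == \
            [(t.kind, t.start, t.end) for t in gene.tokens]

    def test_frame_conflict_is_reported(self):
        t1 = [(10, 19), (30, 45)]
        t2 = [(10, 20), (30, 44)]
        locus = _locus_with(t1)
        locus = _locus_with(t2, seq=locus)
        tms = [build_transcript_model(TranscriptRecord("t1", "g", t1), locus),
               build_transcript_model(TranscriptRecord("t2", "g", t2), locus)]
        with pytest.raises(ModelConflictError) as err:
            build_gene_model(tms, locus)
        assert "t1" in str(err.value) and "t2" in str(err.value)


class TestAssemblyAndValidity:
    @pytest.mark.parametrize("seq,valid,reason", [
        ("ATGTAA", True, ""),
        ("ATGTAATGA", False, "internal in-frame stop"),
        ("ATGAATAA", False, "frame"),
        ("ATGAAA", False, "stop motif"),
        ("TTGAAATAA", False, "start motif"),
        ("ATG", False, "too short"),
    ])
    def test_is_valid_cds(self, seq, valid, reason):
        ok, why = is_valid_cds(seq)
        assert ok is valid
        assert why == reason

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            is_valid_cds("ATGNNNTAA")

    def test_assembly_concatenates_blocks(self):
        exons = [(10, 22), (40, 52), (80, 95)]
        locus = _locus_with(exons)
        tm = build_transcript_model(TranscriptRecord("t", "g", exons), locus)
        seq = assemble_cds_sequence(tm, locus)
        assert seq == locus[10:22] + locus[40:52] + locus[80:95]
        assert is_valid_cds(seq)[0]

    @given(st.integers(min_value=0, max_value=6))
    @settings(max_examples=6, deadline=None, database=None)
    def test_strand_invariance(self, seed):
        """The same gene serialized on + or - strand yields identical
        models and CDS sequences after load normalization."""
        spec = random_fixture_spec(seed + 300)
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            fx_fwd = realize(spec, tmp + "/fwd")
            minus = type(spec)(**{**spec.__dict__, "strand": {"human": "-"}})
            fx_rev = realize(minus, tmp + "/rev")
            fwd = build_models(fx_fwd, ("human",))
            rev = build_models(fx_rev, ("human",))
        for gid in fwd:
            assert fwd[gid].model_string == rev[gid].model_string
            for a, b in zip(fwd[gid].transcripts, rev[gid].transcripts):
                assert assemble_cds_sequence(a, fwd[gid].locus) == \
                    assemble_cds_sequence(b, rev[gid].locus)


def test_loaded_known_transcripts_are_valid(figure_runs):
    """Every annotated CDS in the fixtures assembles into a valid CDS; the
    load-time validity report is empty."""
    for name, (_fx, report, species_data) in figure_runs.items():
        for sp, sd in species_data.items():
            assert sd.cds_validity_report == [], (name, sp)
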
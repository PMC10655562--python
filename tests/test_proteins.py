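"""Mature-transcript assembly, translation, HGVS p. nomenclature."""

import numpy as np
import pytest

from _oracles import check_hgvs_roundtrip
from agscan.models import MatureTranscript, TranscriptModel
from agscan.proteins import (assemble_exon_skip_transcript,
                             assemble_new_acceptor_transcript, hgvs_protein,
                             predict_exon_skip, predict_new_acceptor,
                             translate_cds)
from agscan.scanner import normalize_variant, detect_ag_gain
from agscan.zones import delineate_zones


def _call_for(fxobj, name):
    pv = next(p for p in fxobj.fixture.variants if p.truth["name"] == name)
    intron = fxobj.db.introns[(pv.transcript_id, pv.intron_index)]
    zones = delineate_zones(intron, fxobj.db.ranked_bps(intron))
    (variant,) = normalize_variant(pv.chrom, pv.pos, name, pv.ref, [pv.alt])
    calls, _ = detect_ag_gain(variant, intron, zones, fxobj.genome)
    (call,) = calls
    transcript = fxobj.db.transcripts[intron.transcript_id]
    return transcript, intron, call


class TestNewAcceptorAssembly:
    @pytest.mark.parametrize("name,retained,in_frame", [
        ("VAR5", 6, True),   # Phe+stop insertion geometry
        ("VAR1", 8, False),  # 8-nt retention, out of frame
        ("VAR3", 3, True),   # minimal retention, in frame
    ])
    def test_retained_tail_length_and_frame(self, worked, name, retained,
                                            in_frame):
        transcript, intron, call = _call_for(worked, name)
        assert call.acc_dist == retained
        mature = assemble_new_acceptor_transcript(transcript, intron, call,
                                                  worked.genome)
        wt_len = sum(e - s + 1 for s, e in transcript.exons)
        assert len(mature.sequence) == wt_len + retained
        out = predict_new_acceptor(transcript, intron, call, worked.genome,
                                   _wt_protein(worked, transcript))
        assert out.frameshift is (not in_frame)

    def test_retained_tail_is_mutated_intron_suffix(self, worked):
        transcript, intron, call = _call_for(worked, "VAR5")
        mature = assemble_new_acceptor_transcript(transcript, intron, call,
                                                  worked.genome)
        (tail,) = [seq for label, seq, _ in mature.segments
                   if label.startswith("retained")]
        assert tail == "TTTTAG"  # Phe + stop, carrying the variant allele


def _wt_protein(fxobj, transcript):
    from agscan.proteins import assemble_wild_type

    return translate_cds(assemble_wild_type(transcript, fxobj.genome),
                         transcript).protein


class TestExonSkip:
    def test_in_frame_63nt_exon_deletes_21_residues(self, worked):
        transcript, intron, call = _call_for(worked, "VAR5")
        out = predict_exon_skip(transcript, intron, worked.genome,
                                _wt_protein(worked, transcript))
        assert out.in_frame and not out.frameshift
        assert out.hgvs_p.endswith("del")
        wt = _wt_protein(worked, transcript)
        assert len(wt) - len(out.protein) == 21

    def test_skipping_start_codon_exon_ablates_transcript(self, tmp_path):
        from conftest import load_fixture
        from agscan.simulate import (GenePlan, IntronPlan, PlantSpec,
                                     _random_mature, build_fixture)

        # 30-nt exon 1 is all 5'UTR; the start codon sits in exon 2
        rng = np.random.default_rng(3)
        mature = _random_mature(rng, 36, 120, 186)
        plan = GenePlan(
            "GS", "+", [mature[:30], mature[30:110], mature[110:]], 36, 120,
            [IntronPlan(length=90, bp1=-26,
                        plants=[PlantSpec("snv-new-A", bp_dist=10,
                                          name="v")]),
             IntronPlan(length=90, bp1=-26)])
        fxobj = load_fixture(build_fixture([plan], rng), tmp_path)
        transcript, intron, call = _call_for(fxobj, "v")
        out = predict_exon_skip(transcript, intron, fxobj.genome,
                                _wt_protein(fxobj, transcript))
        assert out.transcript_ablation and out.hgvs_p == "p.0?"
        assert out.protein == ""

    def test_skipping_64nt_exon_frameshifts(self, tmp_path):
        from conftest import load_fixture
        from agscan.simulate import (GenePlan, IntronPlan, PlantSpec,
                                     _random_mature, build_fixture)

        rng = np.random.default_rng(4)
        total, utr5 = 60 + 64 + 76, 12
        cds_len = total - utr5 - 12
        cds_len -= cds_len % 3
        mature = _random_mature(rng, utr5, cds_len, total)
        plan = GenePlan(
            "GF", "+", [mature[:60], mature[60:124], mature[124:]], utr5,
            cds_len,
            [IntronPlan(length=90, bp1=-26,
                        plants=[PlantSpec("snv-new-A", bp_dist=12,
                                          name="v")]),
             IntronPlan(length=90, bp1=-26)])
        fxobj = load_fixture(build_fixture([plan], rng), tmp_path)
        transcript, intron, call = _call_for(fxobj, "v")
        out = predict_exon_skip(transcript, intron, fxobj.genome,
                                _wt_protein(fxobj, transcript))
        assert out.frameshift
        assert "fs" in out.hgvs_p or out.hgvs_p.endswith("*")

    def test_skipping_terminal_exon_flags_stop_lost(self, worked):
        # VAR3/VAR4 sit in the last intron: the "next exon" is terminal
        transcript, intron, call = _call_for(worked, "VAR3")
        out = predict_exon_skip(transcript, intron, worked.genome,
                                _wt_protein(worked, transcript))
        assert out.stop_lost

    def test_last_intron_required_for_skip(self):
        t = TranscriptModel("T", "G", "chr1", "+", [(1, 50), (101, 150)])

        class FakeIntron:
            transcript_id, intron_index, key = "T", 2, "T_IVS2"

        with pytest.raises(ValueError, match="downstream exon"):
            assemble_exon_skip_transcript(t, FakeIntron(), None)


class TestTranslate:
    def test_simple_cds_translates_to_first_stop(self):
        t = TranscriptModel("T", "G", "chr1", "+", [(1, 9)],
                            cds_start=1, cds_end=9)
        mature = MatureTranscript("wild-type",
                                  [("exon1", "ATGTTTTAG", list(range(1, 10)))])
        out = translate_cds(mature, t)
        assert out.protein == "MF"
        assert not out.stop_lost and not out.stop_in_insertion

    def test_stop_inside_retained_tail_flagged(self, worked):
        transcript, intron, call = _call_for(worked, "VAR5")
        out = predict_new_acceptor(transcript, intron, call, worked.genome,
                                   _wt_protein(worked, transcript))
        assert out.stop_in_insertion and out.in_frame
        assert out.hgvs_p == "p.Lys26_Asn27insPhe*"

    def test_frameshifted_tail_translates_into_shifted_frame(self, worked):
        transcript, intron, call = _call_for(worked, "VAR1")
        out = predict_new_acceptor(transcript, intron, call, worked.genome,
                                   _wt_protein(worked, transcript))
        assert out.frameshift
        assert out.hgvs_p.startswith("p.") and "fs" in out.hgvs_p


class TestHgvs:
    @pytest.mark.parametrize("wt,mut,kwargs,expected", [
        ("MKNDL", "MKNDL", {}, "p.(=)"),
        ("MKNDL", "", {"transcript_ablation": True}, "p.0?"),
        ("MKNDL", "MKGR", {"frameshift": True}, "p.Asn3Glyfs*3"),
        ("MKNDL", "MKL", {}, "p.Asn3_Asp4del"),
        ("MKND", "MKFND", {}, "p.Lys2_Asn3insPhe"),
        ("MKNDL", "MKF", {"stop_in_insertion": True},
         "p.Lys2_Asn3insPhe*"),
        ("MKNDL", "MK", {}, "p.Asn3*"),
        ("MKNDL", "MKQDL", {}, "p.Asn3delinsGln"),
    ])
    def test_forms(self, wt, mut, kwargs, expected):
        assert hgvs_protein(wt, mut, **kwargs) == expected

    def test_single_residue_deletion(self):
        assert hgvs_protein("MKNDL", "MKNL") == "p.Asp4del"

    def test_roundtrip_on_all_fixture_products(self, worked, fx):
        for fxobj in (worked, fx):
            for pv in fxobj.fixture.variants:
                if not pv.truth["is_call"]:
                    continue
                transcript, intron, call = _call_for(fxobj, pv.truth["name"])
                wt = _wt_protein(fxobj, transcript)
                for out in (
                    predict_new_acceptor(transcript, intron, call,
                                         fxobj.genome, wt),
                    predict_exon_skip(transcript, intron, fxobj.genome, wt),
                ):
                    check_hgvs_roundtrip(wt, out.protein, out.hgvs_p)

    def test_new_acceptor_frame_rule(self, worked, fx):
        """len change = acc_dist; frameshift iff acc_dist % 3 != 0."""
        for fxobj in (worked, fx):
            for pv in fxobj.fixture.variants:
                if not pv.truth["is_call"]:
                    continue
                transcript, intron, call = _call_for(fxobj, pv.truth["name"])
                wt = _wt_protein(fxobj, transcript)
                out = predict_new_acceptor(transcript, intron, call,
                                           fxobj.genome, wt)
                assert out.frameshift == (call.acc_dist % 3 != 0)
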
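"""Variant normalization, AG-gain detection, distances, risk, score, scan."""

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_detect
from agscan.models import revcomp
from agscan.scanner import (ScanOptions, classify_risk, compute_distances,
                            detect_ag_gain, normalize_variant, scan_vcf,
                            score_from_factors)
from agscan.zones import delineate_zones


class TestNormalize:
    def test_multiallelic_split(self):
        vs = normalize_variant("chr1", 100, "v", "A", ["G", "T"])
        assert [(v.pos, v.ref, v.alt, v.var_type) for v in vs] == [
            (100, "A", "G", "snv"), (100, "A", "T", "snv")]

    def test_deletion_trimmed_to_anchor(self):
        (v,) = normalize_variant("chr1", 100, ".", "CAG", ["CG"])
        assert (v.pos, v.ref, v.alt) == (100, "CA", "C")
        assert (v.core_pos, v.ref_core, v.alt_core) == (101, "A", "")
        assert v.var_type == "1 nt-deletion"

    def test_insertion(self):
        (v,) = normalize_variant("chr1", 100, ".", "C", ["CAG"])
        assert v.var_type == "2 nt-insertion"
        assert (v.core_pos, v.ref_core, v.alt_core) == (101, "", "AG")

    def test_complex_substitution(self):
        (v,) = normalize_variant("chr1", 100, ".", "CAT", ["CGC"])
        assert v.var_type == "complex"
        assert (v.core_pos, v.ref_core, v.alt_core) == (101, "AT", "GC")

    def test_symbolic_and_identity_alts_skipped(self):
        assert normalize_variant("chr1", 100, ".", "A", ["<DEL>"]) == []
        assert normalize_variant("chr1", 100, ".", "A", ["A"]) == []
        assert normalize_variant("chr1", 100, ".", "T", ["T]ctg:123]"]) == []


class TestDistancesRiskScore:
    @pytest.mark.parametrize("a,g,bp,expected", [
        (-8, -7, -26, (18, 6)),    # 18 past the BP, 6-nt retention
        (-10, -9, -26, (16, 8)),   # 16 past the BP, 8-nt retention
        (-25, -24, -26, (1, 23)),  # boundary: first position past the BP
    ])
    def test_compute_distances(self, a, g, bp, expected):
        assert compute_distances(a, g, bp) == expected

    def test_compute_distances_rejects_bad_geometry(self):
        with pytest.raises(RuntimeError):
            compute_distances(-30, -29, -26)

    @pytest.mark.parametrize("zone,bp_dist,g,expected", [
        ("ZONE 1", 18, -7, True),
        ("ZONE 1", 5, -20, False),   # in [BP+1, BP+7]
        ("ZONE 1", 8, -4, True),     # inclusive boundary of [BP+8, ACC-4]
        ("ZONE 2", 18, -30, False),  # zone 2 never high-risk
    ])
    def test_classify_risk(self, zone, bp_dist, g, expected):
        assert classify_risk(zone, bp_dist, g) is expected

    def test_score_extremes(self):
        assert score_from_factors(True, True, True, True) == 5
        assert score_from_factors(False, False, False, False) == 1

    def test_score_bounded_and_monotone_over_all_factor_combinations(self):
        from itertools import product

        for combo in product([False, True], repeat=4):
            s = score_from_factors(*combo)
            assert 1 <= s <= 5
            for k in range(4):
                if not combo[k]:
                    up = list(combo)
                    up[k] = True
                    assert score_from_factors(*up) >= s

    def test_score_weights_overridable(self):
        assert score_from_factors(True, True, False, False,
                                  weights={"high_risk": 2}) == 4


def _detect_for(fxobj, pv):
    db, genome = fxobj.db, fxobj.genome
    intron = db.introns[(pv.transcript_id, pv.intron_index)]
    zones = delineate_zones(intron, db.ranked_bps(intron))
    (variant,) = normalize_variant(pv.chrom, pv.pos, pv.truth["name"],
                                   pv.ref, [pv.alt])
    return detect_ag_gain(variant, intron, zones, genome)


class TestDetect:
    def test_planted_mechanisms_are_recovered(self, fx):
        for pv in fx.fixture.variants:
            if not pv.truth["is_call"]:
                continue
            calls, nocall = _detect_for(fx, pv)
            assert nocall is None
            assert len(calls) == 1, pv.truth["name"]
            c = calls[0]
            t = pv.truth
            assert (c.zone, c.mechanism, c.yag, c.bp_dist, c.acc_dist,
                    c.high_risk, c.score) == (
                t["zone"], t["mechanism"], t["yag"], t["bp_dist"],
                t["acc_dist"], t["high_risk"], t["score"])

    def test_bp_variant_rejected_with_reason(self, fx):
        pv = next(p for p in fx.fixture.variants if p.truth["name"] == "n_bp")
        calls, nocall = _detect_for(fx, pv)
        assert calls == [] and nocall.reason == "BP-variant"

    def test_acceptor_variant_rejected_with_reason(self, fx):
        pv = next(p for p in fx.fixture.variants if p.truth["name"] == "n_acc")
        calls, nocall = _detect_for(fx, pv)
        assert calls == [] and nocall.reason == "canonical-ACC variant"

    def test_aa_creating_snv_is_not_a_gain(self, fx):
        pv = next(p for p in fx.fixture.variants if p.truth["name"] == "n_aa")
        calls, nocall = _detect_for(fx, pv)
        assert calls == [] and nocall is None

    def test_zone3_ag_is_outside_scan_extent(self, fx):
        pv = next(p for p in fx.fixture.variants
                  if p.truth["name"] == "n_zone3")
        calls, _ = _detect_for(fx, pv)
        assert calls == []

    def test_deletion_preserving_junction_ag_is_not_a_gain(self, tmp_path):
        """Deleting one A of AAG leaves an AG at the junction: no new locus."""
        from conftest import load_fixture
        from agscan.simulate import (GenePlan, IntronPlan, _random_mature,
                                     build_fixture)

        rng = np.random.default_rng(5)
        mature = _random_mature(rng, 12, 120, 144)
        plan = GenePlan("GX", "+", [mature[:72], mature[72:]], 12, 120,
                        [IntronPlan(length=90, bp1=-26,
                                    extra_forced={-15: "A", -14: "A",
                                                  -13: "G"})])
        fxobj = load_fixture(build_fixture([plan], rng, suppress=False),
                             tmp_path)
        intron = next(iter(fxobj.db.introns.values()))
        gpos = intron.genomic(-15)
        seq = fxobj.fixture.genome_seq
        (variant,) = normalize_variant(
            intron.chrom, gpos - 1, ".", seq[gpos - 2 : gpos], [seq[gpos - 2]])
        zones = delineate_zones(intron, fxobj.db.ranked_bps(intron))
        calls, nocall = detect_ag_gain(variant, intron, zones, fxobj.genome)
        assert calls == [] and nocall is None
        # sanity: the reference really carried AAG at -15..-13
        from agscan.zones import zone_sequence

        ref_zone, _ = zone_sequence(fxobj.genome, intron, (-15, -13))
        assert ref_zone == "AAG"


class TestOracleEquivalence:
    N_VARIANTS = 2000

    def _random_variants(self, fxobj, rng, n):
        """Random SNVs/indels across the acceptor-proximal intron regions."""
        introns = [i for i in fxobj.db.introns.values()
                   if fxobj.db.ranked_bps(i)]
        seq = fxobj.fixture.genome_seq
        out = []
        for _ in range(n):
            intron = introns[rng.integers(len(introns))]
            off = int(rng.integers(-70, 0))  # 3'-anchored target offset
            gpos = intron.genomic(off)
            kind = rng.choice(["snv", "del", "ins", "complex"])
            if kind == "snv":
                ref = seq[gpos - 1]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                out.append((intron, gpos, ref, str(alt)))
            elif kind == "del":
                ell = int(rng.integers(1, 4))
                if gpos + ell > intron.end + 4:
                    continue
                out.append((intron, gpos - 1, seq[gpos - 2 : gpos + ell - 1],
                            seq[gpos - 2]))
            elif kind == "ins":
                ins = "".join(rng.choice(list("ACGT"),
                                         size=int(rng.integers(1, 4))))
                out.append((intron, gpos, seq[gpos - 1], seq[gpos - 1] + ins))
            else:
                ell = 2
                alt = "".join(rng.choice(list("ACGT"), size=ell))
                out.append((intron, gpos, seq[gpos - 1 : gpos + ell - 1], alt))
        return out

    def test_scanner_equals_full_rebuild_oracle(self, fx):
        rng = np.random.default_rng(11)
        checked = 0
        for intron, pos, ref, alt in self._random_variants(
                fx, rng, self.N_VARIANTS):
            norm = normalize_variant(intron.chrom, pos, ".", ref, [alt])
            if not norm:
                continue
            (variant,) = norm
            zones = delineate_zones(intron, fx.db.ranked_bps(intron))
            calls, _ = detect_ag_gain(variant, intron, zones, fx.genome)
            expected = oracle_detect(
                fx.fixture.genome_seq, intron, zones.bp1, zones.bp2,
                variant.core_pos, variant.ref_core, variant.alt_core)
            got = sorted((c.a_pos, c.g_pos, c.zone, c.bp_dist, c.acc_dist,
                          c.yag) for c in calls)
            want = sorted((c.a_pos, c.g_pos, c.zone, c.bp_dist, c.acc_dist,
                           c.yag) for c in expected)
            assert got == want, (intron.key, pos, ref, alt)
            checked += 1
        assert checked > self.N_VARIANTS * 0.8


class TestScanVcf:
    def test_truth_table_reproduced(self, fx):
        table, errors = scan_vcf(fx.vcf, fx.db, fx.genome, ScanOptions())
        truth = pd.read_csv(fx.truth_path, sep="\t")
        pos = truth[truth.is_call].set_index("name")
        assert errors == []
        assert sorted(table.ID) == sorted(pos.index)
        for _, row in table.iterrows():
            t = pos.loc[row.ID]
            assert row.AGAIN_ZONE == t.zone
            assert row.AGAIN_MECHANISM == t.mechanism
            assert (row.AGAIN_YAG == "YES") == t.yag
            assert row.AGAIN_BP_DIST == t.bp_dist
            assert row.AGAIN_ACC_DIST == t.acc_dist
            assert (row.AGAIN_HIGHRISK == "YES") == t.high_risk
            assert row.AGAIN_SCORE == t.score
            assert row.VAR_TYPE == t.var_type
            assert row.CANONICAL == row.TRANSCRIPT_IVS  # all canonical here

    def test_high_risk_only_filters_low_bp_dist_calls(self, fx):
        table, _ = scan_vcf(fx.vcf, fx.db, fx.genome,
                            ScanOptions(high_risk_only=True))
        truth = pd.read_csv(fx.truth_path, sep="\t")
        expected = truth[truth.is_call & truth.high_risk]
        assert sorted(table.ID) == sorted(expected.name)
        assert (table.AGAIN_HIGHRISK == "YES").all()

    def test_score_min_filter(self, fx):
        table, _ = scan_vcf(fx.vcf, fx.db, fx.genome,
                            ScanOptions(score_min=4))
        assert (table.AGAIN_SCORE >= 4).all()
        truth = pd.read_csv(fx.truth_path, sep="\t")
        assert len(table) == (truth.score >= 4).sum()

    def test_empty_vcf_yields_header_only_table(self, fx, tmp_path):
        empty = tmp_path / "empty.vcf"
        empty.write_text("##fileformat=VCFv4.2\n"
                         "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        table, errors = scan_vcf(empty, fx.db, fx.genome, ScanOptions())
        assert table.empty and errors == []
        assert "AGAIN_SCORE" in table.columns

    def test_reference_mismatch_is_row_level_error(self, fx, tmp_path):
        pv = next(p for p in fx.fixture.variants
                  if p.truth["name"] == "p_snvA_hr")
        bad_ref = "G" if pv.ref != "G" else "C"
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={pv.chrom}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"{pv.chrom}\t{pv.pos}\tbad\t{bad_ref}\tA\t.\t.\t.\n")
        table, errors = scan_vcf(vcf, fx.db, fx.genome, ScanOptions())
        assert table.empty and len(errors) == 1

    def test_missing_contig_is_fatal(self, fx, tmp_path):
        vcf = tmp_path / "contig.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chrZ>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chrZ\t100\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(KeyError):
            scan_vcf(vcf, fx.db, fx.genome, ScanOptions())

    def test_canonical_mode_restricts_transcripts(self, fx, tmp_path):
        from agscan.annotation_db import IntronDB

        # rebuild the db with a canonical list holding a single transcript
        keep = fx.fixture.transcripts[0].transcript_id
        short = tmp_path / "canon.txt"
        short.write_text(keep + "\n")
        db = IntronDB.build(fx.paths["gtf"], fx.paths["bp"],
                            canonical_path=short, genome=fx.genome)
        table, _ = scan_vcf(fx.vcf, db, fx.genome,
                            ScanOptions(transcripts="canonical"))
        assert set(table.TRANSCRIPT_IVS.str.rsplit("_", n=1).str[0]) <= {keep}
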
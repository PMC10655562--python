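"""Seeded synthetic fixtures: toy genome, gene models, branchpoints, variants.

The generator emulates the intron architecture the scanner targets:
multi-exon protein-coding transcripts on both strands, branchpoints planted
a fixed distance upstream of each acceptor (default -26, optionally a second
BP at -31), AG-depleted pyrimidine-rich zone-1 sequences (Y probability
0.76), and planted AG-gain variants of every mechanism class with
machine-readable truth labels.  Same seed, byte-identical outputs.

It makes no attempt to match real-genome base composition beyond the
pyrimidine-content and AG-suppression knobs, and the synthetic worked-case
genes are miniatures reproducing published local geometries, not real loci.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_db import extract_introns
from .models import IntronModel, TranscriptModel, revcomp
from .scanner import ACC_PROXIMAL_MAX, score_from_factors

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
)


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specs

@dataclass
class PlantSpec:
    """One roster entry: a variant to plant, with its expected annotation."""

    kind: str  # snv-new-A | snv-new-G | del-junction | ins-contains-AG |
    #            ins-junction | neg-snv-aa | neg-zone3-ag | neg-bp | neg-acc |
    #            neg-exonic
    bp_dist: int = 10
    yag: bool = True
    zone: str = "ZONE 1"
    del_len: int = 2
    name: str = ""
    extra_forced: dict = field(default_factory=dict)


@dataclass
class FixtureSpec:
    """Study conditions for a random fixture."""

    n_genes: int = 5
    seed: int = 0
    n_exons_range: tuple[int, int] = (3, 5)
    exon_len_range: tuple[int, int] = (60, 120)
    intron_len_range: tuple[int, int] = (80, 140)
    bp_offset: int = -26
    second_bp_offset: Optional[int] = -31  # used only by introns hosting zone-2 plants
    zone1_y_prob: float = 0.76
    suppress_zone_ag: bool = True
    roster: list[PlantSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.intron_len_range[0] < -self.bp_offset + 14:
            raise FixtureError(
                f"intron length range {self.intron_len_range} too short for "
                f"BP offset {self.bp_offset}"
            )
        if not (-100 <= self.bp_offset <= -12):
            raise FixtureError(f"BP offset {self.bp_offset} unusable")


@dataclass
class IntronPlan:
    length: int
    bp1: int = -26
    bp2: Optional[int] = None
    plants: list[PlantSpec] = field(default_factory=list)
    extra_forced: dict = field(default_factory=dict)
    sequence: str = ""  # filled by the builder


@dataclass
class GenePlan:
    name: str
    strand: str
    exon_seqs: list[str]  # transcribed orientation, transcription order
    utr5: int
    cds_len: int
    introns: list[IntronPlan]


@dataclass
class PreparedVariant:
    """A planted variant with genomic VCF alleles and its truth row."""

    entry: PlantSpec
    transcript_id: str
    intron_index: int  # 0 for exonic negatives
    chrom: str
    pos: int
    ref: str
    alt: str
    truth: dict


@dataclass
class Fixture:
    spec: Optional[FixtureSpec]
    chrom: str
    genome_seq: str
    transcripts: list[TranscriptModel]
    introns: list[IntronModel]
    bp_rows: list[tuple[str, int, int]]
    canonical_ids: list[str]
    variants: list[PreparedVariant]

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA/GTF/BP/canonical-list (and VCF+truth via make_variant_set)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "genes.gtf",
            "bp": outdir / "bp.tsv",
            "canonical": outdir / "canonical.txt",
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.genome_seq), 60):
                fh.write(self.genome_seq[i : i + 60] + "\n")
        with open(paths["gtf"], "w") as fh:
            fh.write(self._gtf_text())
        with open(paths["bp"], "w") as fh:
            for tid, idx, off in self.bp_rows:
                fh.write(f"{tid}\t{idx}\t{off}\n")
        with open(paths["canonical"], "w") as fh:
            fh.write("".join(f"{t}\n" for t in self.canonical_ids))
        return paths

    def _gtf_text(self) -> str:
        lines = []

        def feat(chrom, ftype, start, end, strand, attrs):
            a = " ".join(f'{k} "{v}";' for k, v in attrs)
            lines.append(f"{chrom}\ttoy\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{a}")

        for t in self.transcripts:
            g_lo = min(s for s, _ in t.exons)
            g_hi = max(e for _, e in t.exons)
            base = [("gene_id", t.gene_symbol), ("gene_name", t.gene_symbol),
                    ("gene_type", "protein_coding")]
            tx = base + [("transcript_id", t.transcript_id),
                         ("transcript_type", "protein_coding"),
                         ("tag", "basic"), ("level", "2")]
            feat(t.chrom, "gene", g_lo, g_hi, t.strand, base)
            feat(t.chrom, "transcript", g_lo, g_hi, t.strand, tx)
            for s, e in sorted(t.exons):
                feat(t.chrom, "exon", s, e, t.strand, tx)
            if t.cds_start is not None:
                for s, e in self._cds_intervals(t):
                    feat(t.chrom, "CDS", s, e, t.strand, tx)
                sc = t.start_codon_genomic()
                if t.strand == "+":
                    feat(t.chrom, "start_codon", sc, sc + 2, t.strand, tx)
                else:
                    feat(t.chrom, "start_codon", sc - 2, sc, t.strand, tx)
        return "\n".join(lines) + "\n"

    def _cds_intervals(self, t: TranscriptModel) -> list[tuple[int, int]]:
        out = []
        for s, e in sorted(t.exons):
            lo, hi = max(s, t.cds_start), min(e, t.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out


# ---------------------------------------------------------------------------
# plant preparation (transcribed intron frame)

@dataclass
class _Prep:
    forced: dict[int, str]
    var: tuple  # ("snv", offset, alt) | ("del", [offsets]) | ("ins", t, seq)
    #             | ("exonic",)
    truth: dict


def _prepare_plant(entry: PlantSpec, bp1: int, bp2: Optional[int]) -> _Prep:
    """Reference-base requirements and expected truth for one roster entry."""
    zone2 = entry.zone == "ZONE 2"
    if zone2 and bp2 is None:
        raise FixtureError(f"{entry.name or entry.kind}: zone-2 plant needs a second BP")
    anchor = bp2 if zone2 else bp1
    d = entry.bp_dist
    g_cap = (bp1 - 1) if zone2 else -4
    prev_nonyag = "A"  # A before the created AG can never extend it to YAG or AG

    def check(cond, msg):
        if not cond:
            raise FixtureError(f"{entry.name or entry.kind}: unplantable ({msg})")

    def truth(mech, a_alt, g_alt, var_type):
        high = (not zone2) and d >= 8
        return {
            "zone": entry.zone,
            "mechanism": mech,
            "yag": entry.yag,
            "bp_dist": d,
            "acc_dist": -g_alt - 1,
            "high_risk": high,
            "score": score_from_factors(not zone2, high, entry.yag,
                                        -g_alt - 1 <= ACC_PROXIMAL_MAX),
            "is_call": True,
            "var_type": var_type,
            "reason": ".",
        }

    k = entry.kind
    if k == "snv-new-A":
        a, g = anchor + d, anchor + d + 1
        check(d >= 1 and g <= g_cap, f"d={d} leaves no room")
        check(not (entry.yag and a - 1 == bp1), "YAG flank collides with the BP")
        forced = {a: "C", g: "G", a - 1: "T" if entry.yag else prev_nonyag}
        return _Prep(forced, ("snv", a, "A"), truth("snv-new-A", a, g, "snv"))
    if k == "snv-new-G":
        a, g = anchor + d, anchor + d + 1
        check(d >= 1 and g <= g_cap, f"d={d} leaves no room")
        check(not (entry.yag and a - 1 == bp1), "YAG flank collides with the BP")
        forced = {a: "A", g: "T", a - 1: "T" if entry.yag else prev_nonyag}
        return _Prep(forced, ("snv", g, "G"), truth("snv-new-G", a, g, "snv"))
    if k == "del-junction":
        ell = entry.del_len
        g = anchor + ell + d + 1
        a_ref = g - ell - 1
        check(d >= 1 and g <= g_cap, f"d={d}, del_len={ell} leaves no room")
        forced = {a_ref: "A", g: "G", a_ref - 1: "T" if entry.yag else prev_nonyag}
        forced.update({o: "C" for o in range(g - ell, g)})
        return _Prep(forced, ("del", list(range(g - ell, g))),
                     truth("del-junction", g - 1, g, f"{ell} nt-deletion"))
    if k == "ins-contains-AG":
        ins = "CAG" if entry.yag else "GAG"
        t = anchor + d - 1
        check(d >= 3 and t - 1 <= g_cap, f"d={d} out of range for a 3-nt insertion")
        forced = {t - 1: "C"}
        return _Prep(forced, ("ins", t, ins),
                     truth("ins-contains-AG", t - 2, t - 1, "3 nt-insertion"))
    if k == "ins-junction":
        t = anchor + d + 1
        check(d >= (2 if entry.yag else 1) and t - 1 <= g_cap, f"d={d} out of range")
        forced = {t - 1: "A", t: "C", t - 2: "T" if entry.yag else prev_nonyag}
        return _Prep(forced, ("ins", t, "G"),
                     truth("ins-junction", t - 2, t - 1, "1 nt-insertion"))

    no_call = {"zone": ".", "mechanism": ".", "yag": False, "bp_dist": 0,
               "acc_dist": 0, "high_risk": False, "score": 0, "is_call": False,
               "var_type": "snv", "reason": "."}
    if k == "neg-snv-aa":
        x = anchor + d
        check(x + 1 <= -4, f"d={d} too close to the acceptor")
        return _Prep({x: "C", x + 1: "A"}, ("snv", x, "A"),
                     {**no_call, "reason": "no-ag-gain"})
    if k == "neg-zone3-ag":
        zone3_anchor = bp2 if bp2 is not None else bp1
        a = zone3_anchor - 10
        return _Prep({a: "C", a + 1: "G"}, ("snv", a, "A"),
                     {**no_call, "reason": "outside-zone"})
    if k == "neg-bp":
        return _Prep({}, ("snv", bp1, "C"), {**no_call, "reason": "BP-variant"})
    if k == "neg-acc":
        return _Prep({-3: "C"}, ("snv", -3, "A"),
                     {**no_call, "reason": "canonical-ACC variant"})
    if k == "neg-exonic":
        return _Prep({}, ("exonic",), {**no_call, "reason": "not-intronic"})
    raise FixtureError(f"unknown plant kind {k!r}")


# ---------------------------------------------------------------------------
# sequence construction

def _intron_sequence(rng: np.random.Generator, plan: IntronPlan,
                     y_prob: float, suppress: bool) -> tuple[str, dict[int, str]]:
    """Random intron honouring donor/acceptor, BP, zone and plant constraints."""
    L = plan.length
    anchor = plan.bp2 if plan.bp2 is not None else plan.bp1
    if L < -anchor + 10:
        raise FixtureError(f"intron of {L} nt cannot hold a BP at {anchor}")

    arr = list("".join(rng.choice(list("ACGT"), size=L)))

    def setb(off: int, base: str) -> None:
        arr[L + off] = base

    def getb(off: int) -> str:
        return arr[L + off]

    # donor / acceptor / branchpoints
    setb(-L, "G"), setb(-L + 1, "T")
    zone_lo = anchor + 1
    for o in range(zone_lo, -3):
        setb(o, rng.choice(list("CT")) if rng.random() < y_prob
             else rng.choice(list("AG")))
    setb(plan.bp1, "A")
    if plan.bp2 is not None:
        setb(plan.bp2, "A")
    setb(-3, rng.choice(list("CT")))
    setb(-2, "A")
    setb(-1, "G")

    forced: dict[int, str] = dict(plan.extra_forced)
    for entry in plan.plants:
        prep = _prepare_plant(entry, plan.bp1, plan.bp2)
        for off, base in {**prep.forced, **entry.extra_forced}.items():
            if forced.get(off, base) != base:
                raise FixtureError(
                    f"{entry.name or entry.kind}: conflicting forced base at {off}"
                )
            forced[off] = base
    protected = set(forced) | {plan.bp1, plan.bp2, -3, -2, -1} - {None}
    for off, base in forced.items():
        if off < -L + 2:
            raise FixtureError(f"forced base at {off} outside intron of {L} nt")
        setb(off, base)

    if suppress:
        # remove reference AG (A offset in [anchor-2, -4]) except the terminal one
        for _ in range(3):
            dirty = False
            for o in range(max(anchor - 2, -L + 2), -3):
                if getb(o) == "A" and getb(o + 1) == "G":
                    if o + 1 not in protected:
                        setb(o + 1, "C")
                    elif o not in protected:
                        setb(o, "T")
                    else:
                        raise FixtureError(f"cannot suppress forced AG at {o}")
                    dirty = True
            if not dirty:
                break

    return "".join(arr), forced


def _random_gene_plan(rng: np.random.Generator, spec: FixtureSpec, idx: int,
                      plants_by_intron: dict[int, list[PlantSpec]],
                      intron_counter: list[int]) -> GenePlan:
    name = f"GENE{idx + 1}"
    strand = "+" if idx % 2 == 0 else "-"
    n_exons = int(rng.integers(spec.n_exons_range[0], spec.n_exons_range[1] + 1))
    exon_lens = [int(rng.integers(spec.exon_len_range[0], spec.exon_len_range[1] + 1))
                 for _ in range(n_exons)]
    total = sum(exon_lens)
    utr5 = int(rng.integers(12, 25))
    utr3 = total - utr5
    cds_len = total - utr5 - 12
    cds_len -= cds_len % 3
    if cds_len < 30:
        raise FixtureError("exon budget too small for a coding sequence")
    mature = _random_mature(rng, utr5, cds_len, total)
    exon_seqs, pos = [], 0
    for ln in exon_lens:
        exon_seqs.append(mature[pos : pos + ln])
        pos += ln
    introns = []
    for _ in range(n_exons - 1):
        i = intron_counter[0]
        intron_counter[0] += 1
        plants = plants_by_intron.get(i, [])
        needs_bp2 = any(p.zone == "ZONE 2" for p in plants)
        introns.append(IntronPlan(
            length=int(rng.integers(spec.intron_len_range[0],
                                    spec.intron_len_range[1] + 1)),
            bp1=spec.bp_offset,
            bp2=spec.second_bp_offset if needs_bp2 else None,
            plants=plants,
        ))
    return GenePlan(name=name, strand=strand, exon_seqs=exon_seqs,
                    utr5=utr5, cds_len=cds_len, introns=introns)


def _random_mature(rng: np.random.Generator, utr5: int, cds_len: int,
                   total: int) -> str:
    n_mid = cds_len // 3 - 2
    codons = [SENSE_CODONS[int(k)] for k in rng.integers(0, len(SENSE_CODONS),
                                                         size=n_mid)]
    cds = "ATG" + "".join(codons) + "TAA"
    utr = "".join(rng.choice(list("ACGT"), size=total - utr5 - cds_len))
    head = "".join(rng.choice(list("ACGT"), size=utr5))
    return head + cds + utr


# ---------------------------------------------------------------------------
# fixture assembly

SPACER = 150


def build_fixture(gene_plans: list[GenePlan], rng: np.random.Generator,
                  spec: Optional[FixtureSpec] = None, chrom: str = "chrT",
                  y_prob: float = 0.76, suppress: bool = True) -> Fixture:
    """Lay gene plans onto one chromosome and materialise planted variants."""
    genome_parts: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    introns_all: list[IntronModel] = []
    bp_rows: list[tuple[str, int, int]] = []
    prepared: list[PreparedVariant] = []

    for plan in gene_plans:
        spacer = "".join(rng.choice(list("ACGT"), size=SPACER))
        genome_parts.append(spacer)
        cursor += SPACER

        for ip in plan.introns:
            ip.sequence, _ = _intron_sequence(rng, ip, y_prob, suppress)

        segments: list[tuple[str, str]] = []
        for i, ex in enumerate(plan.exon_seqs):
            segments.append(("exon", ex))
            if i < len(plan.introns):
                segments.append(("intron", plan.introns[i].sequence))
        block = "".join(seq for _, seq in segments)
        block_start = cursor + 1  # 1-based genomic start of the gene block
        genome_parts.append(block if plan.strand == "+" else revcomp(block))
        cursor += len(block)

        # genomic intervals of transcription-orientation offsets
        exon_ivs: list[tuple[int, int]] = []
        off = 0
        B = len(block)
        for kind, seq in segments:
            if kind == "exon":
                if plan.strand == "+":
                    exon_ivs.append((block_start + off,
                                     block_start + off + len(seq) - 1))
                else:
                    exon_ivs.append((block_start + (B - off - len(seq)),
                                     block_start + B - off - 1))
            off += len(seq)

        tid = f"ENSTT{plan.name}"
        mature_len = sum(len(s) for s in plan.exon_seqs)
        cds_start_m = plan.utr5
        cds_end_m = plan.utr5 + plan.cds_len - 1
        g1 = _mature_to_genomic(exon_ivs, plan.strand, cds_start_m)
        g2 = _mature_to_genomic(exon_ivs, plan.strand, cds_end_m)
        transcript = TranscriptModel(
            transcript_id=tid, gene_symbol=plan.name, chrom=chrom,
            strand=plan.strand, exons=exon_ivs,
            cds_start=min(g1, g2), cds_end=max(g1, g2),
        )
        transcripts.append(transcript)
        gene_introns = extract_introns(transcript)
        introns_all.extend(gene_introns)
        for intron, ip in zip(gene_introns, plan.introns):
            bp_rows.append((tid, intron.intron_index, ip.bp1))
            if ip.bp2 is not None:
                bp_rows.append((tid, intron.intron_index, ip.bp2))
            for entry in ip.plants:
                prepared.append(_materialise(entry, ip, intron, transcript))

    genome_parts.append("".join(rng.choice(list("ACGT"), size=SPACER)))
    genome_seq = "".join(genome_parts)

    fixture = Fixture(
        spec=spec, chrom=chrom, genome_seq=genome_seq, transcripts=transcripts,
        introns=introns_all, bp_rows=bp_rows,
        canonical_ids=[t.transcript_id for t in transcripts],
        variants=prepared,
    )
    _finalise_variants(fixture)
    _back_check(fixture)
    return fixture


def _mature_to_genomic(exon_ivs, strand: str, m: int) -> int:
    for s, e in exon_ivs:
        ln = e - s + 1
        if m < ln:
            return s + m if strand == "+" else e - m
        m -= ln
    raise FixtureError("mature position outside transcript")


def _materialise(entry: PlantSpec, ip: IntronPlan, intron: IntronModel,
                 transcript: TranscriptModel) -> PreparedVariant:
    """Fill in the transcribed-frame variant; genomic alleles come later."""
    prep = _prepare_plant(entry, ip.bp1, ip.bp2)
    return PreparedVariant(
        entry=entry, transcript_id=transcript.transcript_id,
        intron_index=intron.intron_index, chrom=intron.chrom,
        pos=0, ref="", alt="",
        truth={**prep.truth, "name": entry.name or entry.kind,
               "transcript_ivs": intron.key, "_var": prep.var},
    )


def _finalise_variants(fixture: Fixture) -> None:
    """Convert transcribed-frame plants into plus-strand VCF alleles."""
    introns = {(i.transcript_id, i.intron_index): i for i in fixture.introns}
    transcripts = {t.transcript_id: t for t in fixture.transcripts}
    seq = fixture.genome_seq

    def plus(pos: int) -> str:
        return seq[pos - 1]

    for pv in fixture.variants:
        var = pv.truth.pop("_var")
        t = transcripts[pv.transcript_id]
        if var[0] == "exonic":
            s, e = t.exons[min(pv.intron_index, t.n_exons - 1)]
            pos = s + 4 if t.strand == "+" else e - 4
            ref = plus(pos)
            alt = "A" if ref != "A" else "C"
            pv.intron_index = 0
            pv.truth["transcript_ivs"] = "."
        else:
            intron = introns[(pv.transcript_id, pv.intron_index)]
            if var[0] == "snv":
                _, off, alt_t = var
                pos = intron.genomic(off)
                ref = plus(pos)
                alt = alt_t if intron.strand == "+" else revcomp(alt_t)
            elif var[0] == "del":
                _, offsets = var
                gpos = sorted(intron.genomic(o) for o in offsets)
                pos = gpos[0] - 1
                ref = seq[pos - 1 : gpos[-1]]
                alt = plus(pos)
            else:  # insertion of transcribed `ins` before offset t0
                _, t0, ins = var
                if intron.strand == "+":
                    pos = intron.genomic(t0) - 1
                    alt = plus(pos) + ins
                else:
                    pos = intron.genomic(t0)
                    alt = plus(pos) + revcomp(ins)
                ref = plus(pos)
        pv.pos, pv.ref, pv.alt = pos, ref, alt
        off = var[1] if var[0] == "snv" else None
        pv.truth["c_notation"] = (
            f"IVS{pv.intron_index}{off}"
            f"{plus(pos) if t.strand == '+' else revcomp(plus(pos))}>"
            f"{var[2]}" if var[0] == "snv" and pv.intron_index else "."
        )
        pv.truth.update(CHROM=pv.chrom, POS=pv.pos, REF=pv.ref, ALT=pv.alt)


def _back_check(fixture: Fixture) -> None:
    """Verify each plant against the generated sequence by local mutation."""
    introns = {(i.transcript_id, i.intron_index): i for i in fixture.introns}
    for pv in fixture.variants:
        if not pv.truth["is_call"]:
            continue
        intron = introns[(pv.transcript_id, pv.intron_index)]
        s = fixture.genome_seq[intron.start - 1 : intron.end]
        if intron.strand == "-":
            s = revcomp(s)
        # apply the edit in plus space, re-extract transcribed mutant
        gs = list(fixture.genome_seq)
        gs[pv.pos - 1 : pv.pos - 1 + len(pv.ref)] = list(pv.alt)
        shift = len(pv.alt) - len(pv.ref)
        end = intron.end + shift  # plus-space positions after the edit move
        start = intron.start
        mut = "".join(gs[start - 1 : end])
        if intron.strand == "-":
            mut = revcomp(mut)
        wt_ag = {i - len(s) for i in range(len(s) - 1) if s[i : i + 2] == "AG"}
        mut_ag = {i - len(mut) for i in range(len(mut) - 1) if mut[i : i + 2] == "AG"}
        gained = mut_ag - wt_ag
        a = -pv.truth["acc_dist"] - 2
        if a not in gained:
            raise FixtureError(
                f"{pv.truth['name']}: planted AG not recovered at offset {a} "
                f"(gained {sorted(gained)})"
            )


# ---------------------------------------------------------------------------
# public entry points

def make_toy_genome(spec: FixtureSpec) -> Fixture:
    """Random fixture per spec; roster entries are planted round-robin over introns."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plants_by_intron: dict[int, list[PlantSpec]] = {}
    for i, entry in enumerate(spec.roster):
        plants_by_intron.setdefault(i, []).append(entry)
    n_introns_needed = len(spec.roster)
    plans: list[GenePlan] = []
    counter = [0]
    for g in range(spec.n_genes):
        plans.append(_random_gene_plan(rng, spec, g, plants_by_intron, counter))
    if counter[0] < n_introns_needed:
        raise FixtureError(
            f"roster has {n_introns_needed} entries but fixture only "
            f"{counter[0]} introns"
        )
    return build_fixture(plans, rng, spec=spec, y_prob=spec.zone1_y_prob,
                         suppress=spec.suppress_zone_ag)


def make_variant_set(fixture: Fixture, outdir,
                     roster: Optional[list[PlantSpec]] = None
                     ) -> tuple[Path, Path]:
    """Write the fixture's planted variants as VCF plus a truth TSV.

    When ``roster`` is given it must name entries prepared in the fixture;
    an entry that was never planted raises :class:`FixtureError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = fixture.variants
    if roster is not None:
        by_name = {pv.truth["name"]: pv for pv in fixture.variants}
        missing = [e.name or e.kind for e in roster
                   if (e.name or e.kind) not in by_name]
        if missing:
            raise FixtureError(f"roster entries not plantable in this fixture: "
                               f"{missing}")
        variants = [by_name[e.name or e.kind] for e in roster]

    vcf_path = outdir / "variants.vcf"
    rows = sorted(variants, key=lambda pv: (pv.chrom, pv.pos, pv.ref, pv.alt))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={fixture.chrom},length={len(fixture.genome_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pv in rows:
            fh.write(f"{pv.chrom}\t{pv.pos}\t{pv.truth['name']}\t{pv.ref}\t"
                     f"{pv.alt}\t.\t.\t.\n")

    truth_path = outdir / "truth.tsv"
    cols = ["name", "CHROM", "POS", "REF", "ALT", "transcript_ivs", "zone",
            "mechanism", "yag", "bp_dist", "acc_dist", "high_risk", "score",
            "is_call", "var_type", "reason", "c_notation"]
    pd.DataFrame([pv.truth for pv in variants], columns=cols)[cols].to_csv(
        truth_path, sep="\t", index=False)
    return vcf_path, truth_path


DEFAULT_ROSTER = [
    PlantSpec("snv-new-A", bp_dist=16, yag=True, name="p_snvA_hr"),
    PlantSpec("snv-new-G", bp_dist=10, yag=False, name="p_snvG_hr"),
    PlantSpec("snv-new-A", bp_dist=5, yag=True, name="p_snvA_low"),
    PlantSpec("del-junction", bp_dist=9, del_len=2, yag=True, name="p_del"),
    PlantSpec("ins-contains-AG", bp_dist=12, yag=True, name="p_insAG"),
    PlantSpec("ins-junction", bp_dist=11, yag=False, name="p_insG"),
    PlantSpec("snv-new-A", bp_dist=2, zone="ZONE 2", yag=False, name="p_zone2"),
    PlantSpec("neg-snv-aa", bp_dist=13, name="n_aa"),
    PlantSpec("neg-zone3-ag", name="n_zone3"),
    PlantSpec("neg-bp", name="n_bp"),
    PlantSpec("neg-acc", name="n_acc"),
    PlantSpec("neg-exonic", name="n_exon"),
]


def default_fixture(seed: int = 0, n_genes: int = 6) -> Fixture:
    spec = FixtureSpec(n_genes=n_genes, seed=seed,
                       roster=copy.deepcopy(DEFAULT_ROSTER))
    return make_toy_genome(spec)


# ---------------------------------------------------------------------------
# worked-case miniatures (synthetic stand-ins for published geometries)

def make_worked_variants_fixture() -> Fixture:
    """Hand-crafted synthetic genes reproducing published AG-gain geometries.

    Three miniature genes (not the real loci) carry, in single introns with
    BP = -26: two variants 16 and 5 nt past the BP (inside/outside the
    high-risk region), two at 21 and 6 nt (the 21-nt one creating a TAG 3 nt
    from the acceptor), and one at 18 nt whose new acceptor splices a 6-nt
    Phe+stop insertion and whose skipped 63-nt exon gives an in-frame 21-residue
    deletion.
    """
    rng = np.random.default_rng(2024)

    var1 = PlantSpec("snv-new-G", bp_dist=16, yag=True, name="VAR1")
    var2 = PlantSpec("snv-new-A", bp_dist=5, yag=True, name="VAR2")
    var3 = PlantSpec("snv-new-A", bp_dist=21, yag=True, name="VAR3")
    var4 = PlantSpec("snv-new-A", bp_dist=6, yag=True, name="VAR4")
    var5 = PlantSpec("snv-new-G", bp_dist=18, yag=True, name="VAR5",
                     extra_forced={-6: "T", -5: "T", -4: "T", -3: "T"})

    def codons(n, rng):
        return "".join(SENSE_CODONS[int(k)]
                       for k in rng.integers(0, len(SENSE_CODONS), size=n))

    gene_a = _plain_gene("STT1A", "+", rng, n_exons=4,
                         plant_intron=3, plants=[var1, var2])
    gene_b = _plain_gene("IRF7B", "-", rng, n_exons=3,
                         plant_intron=2, plants=[var3, var4])

    # gene C: exon2 ends with a phase-0 Lys codon, exon3 is 21 codons
    # Asn...Trp, exon4 starts Gly; intron2 hosts the 18-nt variant with a
    # TTTTAG tail so the retained 6 nt read Phe-stop.
    u5 = 12
    e1 = "".join(rng.choice(list("ACGT"), size=u5)) + "ATG" + codons(10, rng)
    e2 = codons(14, rng) + "AAA"
    e3 = "AAT" + codons(19, rng) + "TGG"
    e4 = "GGT" + codons(12, rng) + "TAA" + "".join(rng.choice(list("ACGT"), size=12))
    cds_len = (11 + 15 + 21 + 14) * 3
    gene_c = GenePlan(
        name="SPL2C", strand="-", exon_seqs=[e1, e2, e3, e4], utr5=u5,
        cds_len=cds_len,
        introns=[IntronPlan(length=90, bp1=-26),
                 IntronPlan(length=90, bp1=-26, plants=[var5]),
                 IntronPlan(length=90, bp1=-26)],
    )
    return build_fixture([gene_a, gene_b, gene_c], rng, chrom="chrW")


def _plain_gene(name: str, strand: str, rng: np.random.Generator, n_exons: int,
                plant_intron: int, plants: list[PlantSpec]) -> GenePlan:
    exon_lens = [72] * n_exons
    total = sum(exon_lens)
    utr5 = 12
    cds_len = total - utr5 - 12
    cds_len -= cds_len % 3
    mature = _random_mature(rng, utr5, cds_len, total)
    exon_seqs, pos = [], 0
    for ln in exon_lens:
        exon_seqs.append(mature[pos : pos + ln])
        pos += ln
    introns = [IntronPlan(length=90, bp1=-26,
                          plants=plants if i + 1 == plant_intron else [])
               for i in range(n_exons - 1)]
    return GenePlan(name=name, strand=strand, exon_seqs=exon_seqs, utr5=utr5,
                    cds_len=cds_len, introns=introns)
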
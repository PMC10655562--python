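"""Detection and annotation of AG-gain variants against the intron database.

The scanner asks, for each variant falling between a ranked branchpoint and
the canonical acceptor of an intron: does the ALT allele carry an AG
dinucleotide, at a locus that had none in the reference, overlapping the
edited bases?  All sequence logic runs on the transcribed strand, and
created-AG coordinates are measured on the *mutated* intron, counting back
from its unchanged 3' end (the frame in which the spliceosome would see the
new acceptor).

The created-AG set is defined as the 3'-end-anchored AG occurrences of the
ALT intron minus those of the REF intron, filtered to occurrences that
overlap the edit (or the deletion junction).  End-anchoring makes an indel
that merely shifts or preserves an existing AG cancel out of the set
difference, so e.g. a deletion shortening a run while keeping a junction AG
is not a gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import pysam

from .annotation_db import IntronDB
from .models import AgGainCall, IntronModel, IntronZones, NormalizedVariant, revcomp
from .zones import delineate_zones

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {"base": 1, "zone1": 1, "high_risk": 1, "yag": 1, "acc_proximal": 1}
ACC_PROXIMAL_MAX = 17  # nt; acceptor-proximal bonus threshold

BOX_COLUMNS = [
    "CHROM", "POS", "ID", "REF", "ALT",
    "VAR_TYPE", "GENE", "TRANSCRIPT_IVS", "CANONICAL",
    "AGAIN_ZONE", "AGAIN_YAG", "AGAIN_BP_DIST", "AGAIN_ACC_DIST",
    "AGAIN_HIGHRISK", "AGAIN_SCORE",
    "PROT_SEQ_WT", "PROT_SEQ_NEW_ACC", "HGVS_NEW_ACC",
    "PROT_SEQ_EXON_SKIP", "HGVS_EXON_SKIP",
    "AGAIN_MECHANISM",
]


@dataclass
class ScanOptions:
    transcripts: str = "all"  # "all" | "canonical"
    protein: bool = True
    high_risk_only: bool = False
    score_min: Optional[int] = None
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))


# ---------------------------------------------------------------------------
# variant normalization

_SYMBOLIC = ("<", "[", "]")


def normalize_variant(chrom: str, pos: int, var_id: str, ref: str,
                      alts: Iterable[str], source: str = "") -> list[NormalizedVariant]:
    """Split a VCF record into minimal single-ALT representations.

    Symbolic/breakend ALTs are skipped with a warning; REF == ALT is rejected.
    """
    out: list[NormalizedVariant] = []
    for alt in alts:
        if alt is None or alt == "*":
            continue
        if any(c in alt for c in _SYMBOLIC):
            log.warning("%s:%d symbolic ALT %s skipped", chrom, pos, alt)
            continue
        if alt == ref:
            log.warning("%s:%d REF == ALT rejected", chrom, pos)
            continue
        r, a, p = ref.upper(), alt.upper(), pos
        # VCF-style minimal representation: trim shared suffix, then shared
        # prefix, always keeping one anchor base for indels.
        while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            r, a, p = r[1:], a[1:], p + 1
        # fully trimmed core (no anchor): empty ref_core = pure insertion
        rc, ac, cp = r, a, p
        while rc and ac and rc[-1] == ac[-1]:
            rc, ac = rc[:-1], ac[:-1]
        while rc and ac and rc[0] == ac[0]:
            rc, ac, cp = rc[1:], ac[1:], cp + 1
        if not rc and not ac:
            log.warning("%s:%d REF == ALT after trimming; rejected", chrom, pos)
            continue
        if not rc:  # pure insertion: core_pos = first base after the insertion point
            cp = cp + 0
        out.append(NormalizedVariant(chrom=chrom, pos=p, ref=r, alt=a,
                                     var_id=var_id or ".", core_pos=cp,
                                     ref_core=rc, alt_core=ac, source=source))
    return out


# ---------------------------------------------------------------------------
# distances, risk, score

def compute_distances(a_pos: int, g_pos: int, bp_anchor: int) -> tuple[int, int]:
    """(bp_dist, acc_dist) of a created AG: A offset past the BP, intronic nt 3' of the G."""
    if a_pos <= bp_anchor or g_pos > -4 or g_pos != a_pos + 1:
        raise RuntimeError(
            f"scanner bug: invalid created-AG geometry a={a_pos} g={g_pos} bp={bp_anchor}"
        )
    return a_pos - bp_anchor, -g_pos - 1


def classify_risk(zone: str, bp_dist: int, g_pos: int) -> bool:
    """High-risk = zone-1 gain at least 8 nt past the BP (the [BP+8, ACC-4] core)."""
    return zone == "ZONE 1" and bp_dist >= 8 and g_pos <= -4


def score_from_factors(zone1: bool, high_risk: bool, yag: bool,
                       acc_proximal: bool, weights: dict | None = None) -> int:
    """Additive 1-5 priority score: base + zone-1 + high-risk + YAG + ACC-proximity."""
    w = {**DEFAULT_WEIGHTS, **(weights or {})}
    s = (w["base"] + zone1 * w["zone1"] + high_risk * w["high_risk"]
         + yag * w["yag"] + acc_proximal * w["acc_proximal"])
    return max(1, min(5, s))


def score_call(call: AgGainCall, weights: dict | None = None) -> int:
    return score_from_factors(
        call.zone == "ZONE 1",
        call.high_risk,
        call.yag,
        call.acc_dist <= ACC_PROXIMAL_MAX,
        weights,
    )


# ---------------------------------------------------------------------------
# core detection

@dataclass
class NoCall:
    """A variant/intron pair yielding no call, with the reason why."""

    reason: str
    detail: str = ""


def _window_sequences(genome, intron: IntronModel, variant: NormalizedVariant,
                      wstart: int) -> tuple[str, str, int, str]:
    """REF and ALT transcribed sequences of the intron suffix [wstart, -1].

    Returns (ref_window, alt_window, d3, ref_core_transcribed) where d3 is
    the number of unchanged intron bases 3' of the edit.  The window is a
    suffix of the intron, so 3'-end-anchored offsets agree with the
    full-intron frame.
    """
    n_ref = len(variant.ref_core)
    if intron.strand == "+":
        d3 = intron.end - (variant.core_pos + n_ref) + 1
        gs = intron.end + wstart + 1
        seq = str(genome[intron.chrom][gs - 1 : intron.end]).upper()
        ref_ts, alt_ts = variant.ref_core, variant.alt_core
    else:
        d3 = variant.core_pos - intron.start
        ge = intron.start - wstart - 1
        seq = revcomp(str(genome[intron.chrom][intron.start - 1 : ge]).upper())
        ref_ts, alt_ts = revcomp(variant.ref_core), revcomp(variant.alt_core)
    j = -(d3 + n_ref) - wstart  # window index of the edit's 5'-most base
    if seq[j : j + n_ref] != ref_ts:
        raise ReferenceMismatch(
            f"{variant.chrom}:{variant.pos} REF {variant.ref_core!r} does not "
            f"match the reference genome"
        )
    alt_window = seq[:j] + alt_ts + seq[j + n_ref :]
    return seq, alt_window, d3, ref_ts


class ReferenceMismatch(ValueError):
    pass


def _ag_offsets(seq: str) -> set[int]:
    """3'-end-anchored offsets of the A of each AG in ``seq``."""
    n = len(seq)
    return {i - n for i in range(n - 1) if seq[i] == "A" and seq[i + 1] == "G"}


def detect_ag_gain(variant: NormalizedVariant, intron: IntronModel,
                   zones: IntronZones, genome,
                   weights: dict | None = None) -> tuple[list[AgGainCall], Optional[NoCall]]:
    """All AG-gain calls of one variant in one intron (possibly none).

    Returns ``(calls, nocall)``; ``nocall`` carries a reason code when the
    variant is rejected outright (touches the BP nucleotide, the canonical
    acceptor, or is not fully intronic).
    """
    n_ref, n_alt = len(variant.ref_core), len(variant.alt_core)
    net = n_alt - n_ref

    # the edited bases (or both insertion-junction flanks) must lie inside the intron
    if n_ref:
        if not (intron.start <= variant.core_pos
                and variant.core_pos + n_ref - 1 <= intron.end):
            return [], NoCall("not-intronic")
    else:
        if not (intron.start <= variant.core_pos - 1
                and variant.core_pos <= intron.end):
            return [], NoCall("not-intronic")

    if intron.strand == "+":
        d3 = intron.end - (variant.core_pos + n_ref) + 1
    else:
        d3 = variant.core_pos - intron.start

    # reference-frame extent of the edit (transcribed offsets)
    if n_ref:
        edit_lo_ref, edit_hi_ref = -(d3 + n_ref), -(d3 + 1)
    else:  # insertion junction between -(d3+1) and -d3
        edit_lo_ref, edit_hi_ref = -(d3 + 1), -d3

    for bp in (zones.bp1, zones.bp2):
        if bp is None:
            continue
        if n_ref and edit_lo_ref <= bp <= edit_hi_ref:
            return [], NoCall("BP-variant", "branchpoint nucleotide edited "
                                            "(branchpoint-variant scanner scope)")
    if n_ref and edit_hi_ref >= -3:
        return [], NoCall("canonical-ACC variant")
    if not n_ref and d3 < 3:
        return [], NoCall("canonical-ACC variant")

    extent_lo, _ = zones.scan_extent
    wstart = max(-intron.length, min(extent_lo, edit_lo_ref) - abs(net) - 2)
    try:
        ref_win, alt_win, d3, _ = _window_sequences(genome, intron, variant, wstart)
    except ReferenceMismatch:
        raise

    created = _ag_offsets(alt_win) - _ag_offsets(ref_win)

    if n_alt:
        alt_edit_lo, alt_edit_hi = -(d3 + n_alt), -(d3 + 1)
    else:
        alt_edit_lo, alt_edit_hi = None, None  # pure deletion: junction rule

    def overlaps_edit(a: int) -> bool:
        if n_alt:
            return a <= alt_edit_hi and a + 1 >= alt_edit_lo
        return a == -(d3 + 1)

    def alt_frame(offset: int) -> int:
        """ALT-frame position of a reference offset 5'/3' of the edit."""
        return offset - net if offset <= -(d3 + n_ref + 1) else offset

    bp1_alt = alt_frame(zones.bp1)
    bp2_alt = alt_frame(zones.bp2) if zones.bp2 is not None else None

    calls: list[AgGainCall] = []
    for a in sorted(created):
        g = a + 1
        if g > -4 or not overlaps_edit(a):
            continue
        if a >= bp1_alt + 1:
            zone, anchor = "ZONE 1", bp1_alt
        elif bp2_alt is not None and a >= bp2_alt + 1 and g <= bp1_alt - 1:
            zone, anchor = "ZONE 2", bp2_alt
        else:
            continue
        bp_dist, acc_dist = compute_distances(a, g, anchor)
        prev_idx = len(alt_win) + a - 1
        yag = prev_idx >= 0 and alt_win[prev_idx] in "CT"
        high_risk = classify_risk(zone, bp_dist, g)
        mechanism = _mechanism(variant, a, g, d3, n_alt)
        call = AgGainCall(
            variant=variant,
            transcript_id=intron.transcript_id,
            intron_index=intron.intron_index,
            gene_symbol="",
            zone=zone,
            a_pos=a,
            g_pos=g,
            mechanism=mechanism,
            yag=yag,
            bp_dist=bp_dist,
            acc_dist=acc_dist,
            high_risk=high_risk,
            noncanonical_acceptor=not intron.acceptor_is_ag,
            alt_intron_seq=alt_win,
        )
        call.score = score_call(call, weights)
        calls.append(call)
    return calls, None


def _mechanism(variant: NormalizedVariant, a: int, g: int, d3: int, n_alt: int) -> str:
    vt = variant.var_type
    if vt == "snv":
        edited = -(d3 + 1)
        return "snv-new-A" if a == edited else "snv-new-G"
    if vt.endswith("deletion"):
        return "del-junction"
    if vt.endswith("insertion"):
        ins_lo, ins_hi = -(d3 + n_alt), -(d3 + 1)
        if a >= ins_lo and g <= ins_hi:
            return "ins-contains-AG"
        return "ins-junction"
    return "complex"


# ---------------------------------------------------------------------------
# VCF-level scan

def iter_vcf(vcf_path: str) -> Iterable[NormalizedVariant]:
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            yield from normalize_variant(
                rec.chrom, rec.pos, rec.id, rec.ref, rec.alts or (),
                source=f"{rec.chrom}:{rec.pos}",
            )


def scan_vcf(vcf_path: str, db: IntronDB, genome,
             options: ScanOptions | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Annotate every AG-gain (variant x transcript-intron) in a VCF.

    Returns the annotation table (Box-style columns, deterministic order) and
    a list of row-level error records; a reference-genome contig missing from
    the FASTA is fatal.
    """
    from . import proteins  # deferred: heavy imports only when scanning

    options = options or ScanOptions()
    rows: list[dict] = []
    errors: list[dict] = []
    wt_cache: dict[str, tuple] = {}

    for variant in iter_vcf(vcf_path):
        if variant.chrom not in genome:
            raise KeyError(f"contig {variant.chrom} missing from the genome FASTA")
        span_lo = variant.core_pos - 1
        span_hi = variant.core_pos + max(len(variant.ref_core), 1) - 1
        for intron in db.introns_overlapping(variant.chrom, span_lo, span_hi):
            transcript = db.transcripts[intron.transcript_id]
            if options.transcripts == "canonical" and not transcript.is_canonical:
                continue
            bps = db.ranked_bps(intron)
            if not bps:
                continue
            zones = delineate_zones(intron, bps)
            if zones.zone1 is None:
                continue
            try:
                calls, nocall = detect_ag_gain(variant, intron, zones, genome,
                                               options.weights)
            except ReferenceMismatch as exc:
                errors.append({"variant": f"{variant.chrom}:{variant.pos}",
                               "intron": intron.key, "error": str(exc)})
                continue
            if nocall is not None:
                log.debug("%s:%d %s: %s", variant.chrom, variant.pos,
                          intron.key, nocall.reason)
                continue
            for call in calls:
                call.gene_symbol = transcript.gene_symbol
                call.canonical = transcript.is_canonical
                if options.high_risk_only and not call.high_risk:
                    continue
                if options.score_min is not None and call.score < options.score_min:
                    continue
                rows.append(_call_row(call, transcript, intron, genome,
                                      options, wt_cache, proteins))

    df = pd.DataFrame(rows, columns=BOX_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            ["CHROM", "POS", "REF", "ALT", "TRANSCRIPT_IVS", "AGAIN_ACC_DIST"]
        ).reset_index(drop=True)
    return df, errors


def _call_row(call: AgGainCall, transcript, intron, genome, options: ScanOptions,
              wt_cache: dict, proteins) -> dict:
    yn = {True: "YES", False: "NO"}
    row = {
        "CHROM": call.variant.chrom,
        "POS": call.variant.pos,
        "ID": call.variant.var_id,
        "REF": call.variant.ref,
        "ALT": call.variant.alt,
        "VAR_TYPE": call.variant.var_type,
        "GENE": call.gene_symbol,
        "TRANSCRIPT_IVS": call.transcript_ivs,
        "CANONICAL": call.transcript_ivs if call.canonical else ".",
        "AGAIN_ZONE": call.zone,
        "AGAIN_YAG": yn[call.yag],
        "AGAIN_BP_DIST": call.bp_dist,
        "AGAIN_ACC_DIST": call.acc_dist,
        "AGAIN_HIGHRISK": yn[call.high_risk],
        "AGAIN_SCORE": call.score,
        "PROT_SEQ_WT": ".", "PROT_SEQ_NEW_ACC": ".", "HGVS_NEW_ACC": ".",
        "PROT_SEQ_EXON_SKIP": ".", "HGVS_EXON_SKIP": ".",
        "AGAIN_MECHANISM": call.mechanism,
    }
    if options.protein and transcript.cds_start is not None:
        if transcript.transcript_id not in wt_cache:
            wt_mature = proteins.assemble_wild_type(transcript, genome)
            wt_out = proteins.translate_cds(wt_mature, transcript)
            wt_cache[transcript.transcript_id] = (wt_mature, wt_out)
        _, wt_out = wt_cache[transcript.transcript_id]
        new_acc = proteins.predict_new_acceptor(transcript, intron, call, genome,
                                                wt_out.protein)
        skip = proteins.predict_exon_skip(transcript, intron, genome, wt_out.protein)
        row.update({
            "PROT_SEQ_WT": wt_out.protein or ".",
            "PROT_SEQ_NEW_ACC": new_acc.protein or ".",
            "HGVS_NEW_ACC": new_acc.hgvs_p,
            "PROT_SEQ_EXON_SKIP": skip.protein or ".",
            "HGVS_EXON_SKIP": skip.hgvs_p,
        })
    return row
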
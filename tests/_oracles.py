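"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's windowed scanner: the AG-gain oracle
rebuilds the entire mutated chromosome with per-base provenance tags and
rediscovers calls from first principles; the Fisher oracle enumerates the
hypergeometric distribution with exact integer arithmetic; the HGVS applier
reconstructs the mutant protein from the emitted description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from math import comb

from Bio.SeqUtils import seq1

from agscan.models import revcomp

# ---------------------------------------------------------------------------
# brute-force AG scan


def brute_ag_offsets(seq: str, require_yag: bool = False) -> list[int]:
    out = []
    for i in range(len(seq)):
        for j in range(len(seq)):
            if j == i + 1 and seq[i] == "A" and seq[j] == "G":
                if require_yag:
                    if i > 0 and seq[i - 1] in ("C", "T"):
                        out.append(i)
                else:
                    out.append(i)
    return out


# ---------------------------------------------------------------------------
# exhaustive/no-AG probability


def enumerate_prob_ag(n: int) -> float:
    from itertools import product

    hits = sum(1 for s in product("ACGT", repeat=n) if "AG" in "".join(s))
    return hits / 4 ** n


# ---------------------------------------------------------------------------
# exact Fisher by hypergeometric enumeration


def fisher_enumeration(a: int, b: int, c: int, d: int,
                       alternative: str = "two-sided") -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    if alternative == "greater":
        return sum(pmf(x) for x in xs if x >= a)
    if alternative == "less":
        return sum(pmf(x) for x in xs if x <= a)
    return sum(pmf(x) for x in xs if pmf(x) <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# full-rebuild AG-gain oracle


@dataclass
class OracleCall:
    a_pos: int
    g_pos: int
    zone: str
    bp_dist: int
    acc_dist: int
    yag: bool


def oracle_detect(chrom_seq: str, intron, bp1: int, bp2, core_pos: int,
                  ref_core: str, alt_core: str) -> list[OracleCall]:
    """Rediscover AG-gain calls by rebuilding the whole mutant chromosome.

    Every mutant base carries a provenance tag (its reference genomic
    coordinate, or None for substituted/inserted bases); zones, distances and
    rejections are all derived from the tags, with no shift arithmetic.
    """
    i0 = core_pos - 1
    bases = list(chrom_seq[:i0]) + list(alt_core) + list(chrom_seq[i0 + len(ref_core):])
    tags = (list(range(1, core_pos))
            + [None] * len(alt_core)
            + list(range(core_pos + len(ref_core), len(chrom_seq) + 1)))

    # mutant intron = mutant bases between the (unedited) intron bounds
    try:
        lo = tags.index(intron.start)
        hi = tags.index(intron.end)
    except ValueError:
        # an intron boundary base was edited: the scanner's not-intronic /
        # terminal checks also refuse such variants
        return []
    mut = "".join(bases[lo : hi + 1])
    mtags = tags[lo : hi + 1]
    if intron.strand == "-":
        mut = revcomp(mut)
        mtags = mtags[::-1]

    wt = chrom_seq[intron.start - 1 : intron.end]
    if intron.strand == "-":
        wt = revcomp(wt)

    n = len(mut)

    def tag_offset(genomic: int):
        try:
            return mtags.index(genomic) - n
        except ValueError:
            return None

    # rejection: BP nucleotide or the terminal 3 nt edited away, or any
    # edited/inserted base landing inside the terminal 3 nt (acceptor-
    # disrupting variants are out of scope for an AG-*gain* scanner)
    terminal = [intron.genomic(o) for o in (-3, -2, -1)]
    bps_genomic = [intron.genomic(bp1)] + ([intron.genomic(bp2)] if bp2 else [])
    if any(tag_offset(g) is None for g in terminal + bps_genomic):
        return []
    if any(mtags[i] is None for i in range(max(0, n - 3), n)):
        return []

    wt_ag = {i - len(wt) for i in range(len(wt) - 1) if wt[i : i + 2] == "AG"}
    bp1_off = tag_offset(intron.genomic(bp1))
    bp2_off = tag_offset(intron.genomic(bp2)) if bp2 else None

    calls = []
    for i in range(n - 1):
        if mut[i : i + 2] != "AG":
            continue
        a = i - n
        if a in wt_ag:
            continue
        edited = mtags[i] is None or mtags[i + 1] is None
        junction = (mtags[i] is not None and mtags[i + 1] is not None
                    and abs(mtags[i + 1] - mtags[i]) != 1)
        if not (edited or junction):
            continue
        g = a + 1
        if g > -4:
            continue
        if a >= bp1_off + 1:
            zone, anchor = "ZONE 1", bp1_off
        elif bp2_off is not None and a >= bp2_off + 1 and g <= bp1_off - 1:
            zone, anchor = "ZONE 2", bp2_off
        else:
            continue
        calls.append(OracleCall(a, g, zone, a - anchor, -g - 1,
                                i > 0 and mut[i - 1] in "CT"))
    return sorted(calls, key=lambda c: c.a_pos)


# ---------------------------------------------------------------------------
# HGVS p. applier


_AA = r"(?:[A-Z][a-z]{2})"
_RX = {
    "ins": re.compile(rf"^p\.({_AA})(\d+)_({_AA})(\d+)ins((?:{_AA})+)(\*?)$"),
    "del": re.compile(rf"^p\.({_AA})(\d+)(?:_({_AA})(\d+))?del$"),
    "delins": re.compile(rf"^p\.({_AA})(\d+)(?:_({_AA})(\d+))?delins((?:{_AA})+)$"),
    "fs": re.compile(rf"^p\.({_AA})(\d+)({_AA})fs\*(\d+|\?)$"),
    "ter": re.compile(rf"^p\.({_AA})(\d+)\*$"),
}


def _one(three: str) -> str:
    return "".join(seq1(three[i : i + 3]) for i in range(0, len(three), 3))


def apply_hgvs(wt: str, hgvs: str):
    """Reconstruct the mutant protein from an HGVS p. string.

    Returns the full mutant sequence, or for frameshifts a dict of checkable
    constraints; None for non-reconstructable forms (p.?).
    """
    if hgvs == "p.(=)":
        return wt
    if hgvs == "p.0?":
        return ""
    if hgvs == "p.?":
        return None
    m = _RX["ins"].match(hgvs)
    if m:
        x, i, y, j, ins, star = m.groups()
        i, j = int(i), int(j)
        assert j == i + 1 and wt[i - 1] == _one(x) and wt[j - 1] == _one(y)
        return wt[:i] + _one(ins) if star else wt[:i] + _one(ins) + wt[i:]
    m = _RX["delins"].match(hgvs)
    if m:
        x, i, y, j, ins = m.groups()
        i = int(i)
        j = int(j) if j else i
        assert wt[i - 1] == _one(x) and (y is None or wt[j - 1] == _one(y))
        return wt[: i - 1] + _one(ins) + wt[j:]
    m = _RX["del"].match(hgvs)
    if m:
        x, i, y, j = m.groups()
        i = int(i)
        j = int(j) if j else i
        assert wt[i - 1] == _one(x) and (y is None or wt[j - 1] == _one(y))
        return wt[: i - 1] + wt[j:]
    m = _RX["ter"].match(hgvs)
    if m:
        x, i = m.groups()
        i = int(i)
        assert wt[i - 1] == _one(x)
        return wt[: i - 1]
    m = _RX["fs"].match(hgvs)
    if m:
        x, i, y, nstop = m.groups()
        i = int(i)
        return {"pos": i, "wt_aa": _one(x), "mut_aa": _one(y),
                "stop": None if nstop == "?" else int(nstop)}
    raise AssertionError(f"unparseable HGVS: {hgvs}")


def check_hgvs_roundtrip(wt: str, mut: str, hgvs: str) -> None:
    got = apply_hgvs(wt, hgvs)
    if got is None:
        return
    if isinstance(got, dict):
        i = got["pos"]
        assert wt[: i - 1] == mut[: i - 1], hgvs
        assert wt[i - 1] == got["wt_aa"] and mut[i - 1] == got["mut_aa"], hgvs
        if got["stop"] is not None:
            assert len(mut) == i + got["stop"] - 2, hgvs
        return
    assert got == mut, f"{hgvs}: applied={got!r} expected={mut!r}"


# ---------------------------------------------------------------------------
# fixture mirroring (reverse-complement the world)


def flip_fixture(fixture):
    """Reverse-complement the genome and remap every annotation and variant."""
    from agscan.simulate import Fixture

    L = len(fixture.genome_seq)

    def fpos(p: int) -> int:
        return L - p + 1

    transcripts = []
    for t in fixture.transcripts:
        transcripts.append(replace(
            t,
            strand="-" if t.strand == "+" else "+",
            exons=[(fpos(e), fpos(s)) for s, e in t.exons],
            cds_start=fpos(t.cds_end) if t.cds_end is not None else None,
            cds_end=fpos(t.cds_start) if t.cds_start is not None else None,
        ))
    variants = []
    for pv in fixture.variants:
        variants.append(replace(
            pv,
            pos=fpos(pv.pos + len(pv.ref) - 1),
            ref=revcomp(pv.ref),
            alt=revcomp(pv.alt),
            truth=dict(pv.truth),
        ))
    flipped = Fixture(
        spec=fixture.spec, chrom=fixture.chrom,
        genome_seq=revcomp(fixture.genome_seq),
        transcripts=transcripts, introns=[], bp_rows=list(fixture.bp_rows),
        canonical_ids=list(fixture.canonical_ids), variants=variants,
    )
    from agscan.annotation_db import extract_introns

    for t in transcripts:
        flipped.introns.extend(extract_introns(t))
    return flipped
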
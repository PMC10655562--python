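"""Zone delineation and reference-genome sequence statistics.

Three intervals are defined per intron, in 3'-anchored coordinates on the
transcribed strand (last intron base = -1):

* zone 1, ``[BP1+1, -4]`` — the stretch between the acceptor-proximal
  branchpoint and the acceptor, excluding the invariant terminal 3 nt; this
  is the polypyrimidine tract, where AG dinucleotides are strongly depleted.
* zone 2, ``[BP2+1, BP1-1]`` — between the two ranked branchpoints, present
  only for multi-BP introns.
* zone 3 — a fixed 30-nt control window immediately 5' of the BP anchor
  (the first BP for single-BP introns, else the second), ``[anchor-30, anchor-1]``.

The high-risk interval ``[BP1+8, -4]`` is the AG/YAG-depleted core of zone 1.
"""

from __future__ import annotations

from .models import BranchpointRecord, IntronModel, IntronZones, revcomp


def delineate_zones(intron: IntronModel, bp_records: list[BranchpointRecord]) -> IntronZones:
    """Build the zone intervals of one intron from its ranked branchpoints.

    Requires at least one rank-1 BP.  ``high_risk`` is None when BP1+8 > -4
    (branchpoint too close to the acceptor to leave room).
    """
    ranked = {r.rank: r.offset for r in bp_records if r.rank in (1, 2)}
    if 1 not in ranked:
        raise ValueError(f"{intron.key}: no rank-1 branchpoint; intron skipped")
    bp1 = ranked[1]
    bp2 = ranked.get(2)
    if bp2 is not None and bp2 >= bp1:
        raise ValueError(f"{intron.key}: BP2 {bp2} not 5' of BP1 {bp1}")

    zone1 = (bp1 + 1, -4) if bp1 + 1 <= -4 else None
    zone2 = None
    if bp2 is not None and bp2 + 1 <= bp1 - 1:
        zone2 = (bp2 + 1, bp1 - 1)
    anchor = bp1 if bp2 is None else bp2
    zone3 = (anchor - 30, anchor - 1)
    high_risk = (bp1 + 8, -4) if bp1 + 8 <= -4 else None
    return IntronZones(bp1=bp1, bp2=bp2, zone1=zone1, zone2=zone2, zone3=zone3,
                       high_risk=high_risk)


def zone_sequence(genome, intron: IntronModel, zone: tuple[int, int]) -> tuple[str, bool]:
    """Transcribed-strand sequence of a 3'-anchored interval of an intron.

    Returns ``(seq, truncated)``; the interval is clipped to the intron's 5'
    end when it extends beyond it (short introns), with ``truncated`` set.
    """
    lo, hi = zone
    if lo > hi or hi > -1:
        raise ValueError(f"invalid zone {zone}")
    truncated = lo < -intron.length
    lo = max(lo, -intron.length)
    if intron.strand == "+":
        gs, ge = intron.genomic(lo), intron.genomic(hi)
        seq = str(genome[intron.chrom][gs - 1 : ge]).upper()
    else:
        gs, ge = intron.genomic(hi), intron.genomic(lo)
        seq = revcomp(str(genome[intron.chrom][gs - 1 : ge]).upper())
    return seq, truncated


def pyrimidine_content(seq: str) -> float:
    """Fraction of pyrimidines (C/T) in an A/C/G/T string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return (seq.count("C") + seq.count("T")) / len(seq)


def scan_natural_ag(seq: str, require_yag: bool = False) -> list[int]:
    """0-based offsets of the A of every AG occurrence in ``seq``.

    With ``require_yag`` only occurrences preceded by a pyrimidine count; an
    AG starting at offset 0 has no preceding base and is never a YAG.
    """
    if not seq:
        raise ValueError("empty sequence")
    hits = []
    for i in range(len(seq) - 1):
        if seq[i] == "A" and seq[i + 1] == "G":
            if require_yag and (i == 0 or seq[i - 1] not in "CT"):
                continue
            hits.append(i)
    return hits


def ag_depletion_stat(frac_with_ag: float, frac_within_7: float) -> float:
    """Fraction of introns carrying an AG beyond BP+7: p(AG) * (1 - p(within 7 nt))."""
    for x in (frac_with_ag, frac_within_7):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"fraction {x} outside [0, 1]")
    return frac_with_ag * (1.0 - frac_within_7)


def prob_at_least_one_ag(n: int, base_probs: dict[str, float] | None = None) -> float:
    """Probability that an i.i.d. random n-mer contains at least one AG.

    Uses the linear recurrence on the no-AG probability
    ``t(k+1) = t(k) - pA*pG*t(k-1)`` (equivalently a 2-state transfer matrix
    on "last base is A"), exact up to float rounding.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    probs = base_probs or {b: 0.25 for b in "ACGT"}
    total = sum(probs.get(b, 0.0) for b in "ACGT")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"base probabilities sum to {total}, not 1")
    pa, pg = probs.get("A", 0.0), probs.get("G", 0.0)
    t_prev, t_cur = 1.0, 1.0  # t(0), t(1)
    for _ in range(1, n):
        t_prev, t_cur = t_cur, t_cur - pa * pg * t_prev
    return 1.0 - t_cur


def pair_map(dot_bracket: str) -> dict[int, int]:
    """Base-pair partner map from a dot-bracket string; raises if unbalanced."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure: unclosed '('")
    return pairs


def ag_concealment(seq: str, dot_bracket: str, ag_offset: int) -> bool:
    """Whether both bases of the AG at ``ag_offset`` are paired within ``seq``.

    The structure must be a balanced dot-bracket of the same length; partners
    are by construction inside the sequence.
    """
    if len(seq) != len(dot_bracket):
        raise ValueError("sequence and structure lengths differ")
    if not (0 <= ag_offset < len(seq) - 1) or seq[ag_offset : ag_offset + 2] != "AG":
        raise ValueError(f"offset {ag_offset} does not point at an AG")
    pairs = pair_map(dot_bracket)
    return ag_offset in pairs and ag_offset + 1 in pairs


def zone_stats_row(genome, intron: IntronModel, zones: IntronZones,
                   fold=None) -> dict:
    """Per-intron atlas row: zone intervals, lengths, Y content, natural AG/YAG.

    ``fold`` is an optional callable ``seq -> dot_bracket`` used to judge AG
    concealment in zone 1 (see :mod:`agscan.folding`).
    """
    row: dict = {
        "transcript_id": intron.transcript_id,
        "intron_index": intron.intron_index,
        "intron_length": intron.length,
        "bp1": zones.bp1,
        "bp2": zones.bp2 if zones.bp2 is not None else ".",
    }
    for name, zone in (("zone1", zones.zone1), ("zone2", zones.zone2),
                       ("zone3", zones.zone3)):
        if zone is None:
            row.update({f"{name}": ".", f"{name}_len": 0, f"{name}_pyrimidine": ".",
                        f"{name}_ag": "", f"{name}_yag": ""})
            continue
        seq, truncated = zone_sequence(genome, intron, zone)
        ag = scan_natural_ag(seq) if len(seq) > 1 else []
        yag = scan_natural_ag(seq, require_yag=True) if len(seq) > 1 else []
        row.update({
            f"{name}": f"[{zone[0]},{zone[1]}]" + ("*" if truncated else ""),
            f"{name}_len": len(seq),
            f"{name}_pyrimidine": round(pyrimidine_content(seq), 4) if seq else ".",
            f"{name}_ag": ",".join(str(zone[0] + i) for i in ag),
            f"{name}_yag": ",".join(str(zone[0] + i) for i in yag),
        })
    if fold is not None and zones.zone1 is not None:
        seq, _ = zone_sequence(genome, intron, zones.zone1)
        offsets = scan_natural_ag(seq) if len(seq) > 1 else []
        if offsets:
            structure = fold(seq)
            row["zone1_ag_concealed"] = ",".join(
                "YES" if ag_concealment(seq, structure, i) else "NO" for i in offsets
            )
        else:
            row["zone1_ag_concealed"] = ""
    return row
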
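"""Protein-level products of the two principal missplicing scenarios.

For an AG-gain call the two outcomes modelled are (i) use of a new acceptor
at the created AG, which splices the ``acc_dist`` 3'-terminal nucleotides of
the mutated intron into the mRNA, and (ii) complete skipping of the next
exon.  Products are translated with the standard code from the annotated
start codon (which may sit in any exon) to the first stop, and described
with minimal HGVS p. nomenclature.

No attempt is made to predict which scenario dominates, nor to model NMD,
cryptic-site use or intron retention.
"""

from __future__ import annotations

from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .models import (AgGainCall, IntronModel, MatureTranscript, ProteinOutcome,
                     TranscriptModel, revcomp)


def _exon_segment(transcript: TranscriptModel, genome, i: int):
    s, e = transcript.exons[i]
    raw = str(genome[transcript.chrom][s - 1 : e]).upper()
    if transcript.strand == "+":
        return (f"exon{i + 1}", raw, list(range(s, e + 1)))
    return (f"exon{i + 1}", revcomp(raw), list(range(e, s - 1, -1)))


def assemble_wild_type(transcript: TranscriptModel, genome) -> MatureTranscript:
    segments = [_exon_segment(transcript, genome, i) for i in range(transcript.n_exons)]
    return MatureTranscript(scenario="wild-type", segments=segments)


def assemble_new_acceptor_transcript(transcript: TranscriptModel, intron: IntronModel,
                                     call: AgGainCall, genome) -> MatureTranscript:
    """Upstream exons + retained mutated-intron tail (acc_dist nt) + downstream exons."""
    tail = call.alt_intron_seq[-call.acc_dist:]
    assert len(tail) == call.acc_dist
    segments = []
    for i in range(transcript.n_exons):
        if i == intron.intron_index:  # first exon downstream of the intron
            segments.append((f"retained_IVS{intron.intron_index}", tail,
                             [None] * len(tail)))
        segments.append(_exon_segment(transcript, genome, i))
    return MatureTranscript(scenario="new-acceptor", segments=segments)


def assemble_exon_skip_transcript(transcript: TranscriptModel, intron: IntronModel,
                                  genome) -> MatureTranscript:
    """Mature transcript omitting the exon immediately downstream of the intron."""
    skipped = intron.intron_index  # 0-based index of exon intron_index+1
    if skipped >= transcript.n_exons:
        raise ValueError(f"{intron.key}: no downstream exon to skip")
    segments = [_exon_segment(transcript, genome, i)
                for i in range(transcript.n_exons) if i != skipped]
    mature = MatureTranscript(scenario="exon-skip", segments=segments)
    start_g = transcript.start_codon_genomic()
    if start_g is not None and mature.mature_index(start_g) is None:
        mature.start_codon_status = "ablated"
    return mature


def translate_cds(mature: MatureTranscript, transcript: TranscriptModel) -> ProteinOutcome:
    """Translate from the annotated start codon to the first stop.

    Sets ``transcript_ablation`` when the start codon is absent from the
    mature transcript, ``stop_in_insertion`` when the stop codon overlaps
    retained intronic sequence, and ``stop_lost`` when translation runs off
    the transcript without a stop.
    """
    start_g = transcript.start_codon_genomic()
    if start_g is None:
        return ProteinOutcome(scenario=mature.scenario, protein="", hgvs_p="p.?",
                              transcript_ablation=True)
    s_idx = mature.mature_index(start_g)
    if s_idx is None:
        mature.start_codon_status = "ablated"
        return ProteinOutcome(scenario=mature.scenario, protein="", hgvs_p="p.0?",
                              transcript_ablation=True)
    cds = mature.sequence[s_idx:]
    cds = cds[: len(cds) // 3 * 3]
    aa = str(Seq(cds).translate())
    stop_at = aa.find("*")
    has_stop = stop_at >= 0
    protein = aa[:stop_at] if has_stop else aa
    stop_in_insertion = False
    if has_stop:
        for k in range(3):
            if mature.segment_label(s_idx + 3 * stop_at + k).startswith("retained"):
                stop_in_insertion = True
                break
    return ProteinOutcome(
        scenario=mature.scenario,
        protein=protein,
        hgvs_p="",
        stop_in_insertion=stop_in_insertion,
        stop_lost=not has_stop,
    )


# ---------------------------------------------------------------------------
# HGVS p. nomenclature

def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _seq3(seq: str) -> str:
    return "".join(_aa3(a) for a in seq)


def hgvs_protein(wt: str, mut: str, *, frameshift: bool = False,
                 stop_in_insertion: bool = False, transcript_ablation: bool = False,
                 has_stop: bool = True) -> str:
    """Minimal HGVS p. description turning ``wt`` into ``mut``.

    Handles in-frame insertions (with a trailing ``*`` when the insertion
    carries a stop), in-frame deletions and delins, frameshifts (``fs*N``),
    nonsense truncations, start-codon loss (``p.0?``) and identity
    (``p.(=)``).  Proteins are one-letter strings without terminal ``*``.
    """
    if transcript_ablation:
        return "p.0?"
    if wt == mut:
        return "p.(=)"
    p = 0
    while p < len(wt) and p < len(mut) and wt[p] == mut[p]:
        p += 1

    if frameshift:
        if p == len(mut):
            # first frameshifted codon is already a stop
            return f"p.{_aa3(wt[p])}{p + 1}*" if p < len(wt) else f"p.*{p + 1}ext*?"
        n = (len(mut) - p + 1) if has_stop else "?"
        if p >= len(wt):  # frameshift past the WT terminus (stop-lost extension)
            return f"p.*{len(wt) + 1}ext*{n}"
        return f"p.{_aa3(wt[p])}{p + 1}{_aa3(mut[p])}fs*{n}"

    if stop_in_insertion and p < len(wt) and mut[p:]:
        # in-frame insertion terminated by a stop inside the inserted segment
        return (f"p.{_aa3(wt[p - 1])}{p}_{_aa3(wt[p])}{p + 1}"
                f"ins{_seq3(mut[p:])}*") if p > 0 else "p.?"

    s = 0
    while (s < len(wt) - p and s < len(mut) - p
           and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]):
        s += 1
    del_seg = wt[p : len(wt) - s]
    ins_seg = mut[p : len(mut) - s]

    if del_seg and not ins_seg:
        if s == 0 and has_stop and p == len(mut):
            # truncation: new junction codon is a stop
            return f"p.{_aa3(wt[p])}{p + 1}*"
        if not has_stop:
            return "p.?"
        if len(del_seg) == 1:
            return f"p.{_aa3(del_seg)}{p + 1}del"
        return f"p.{_aa3(del_seg[0])}{p + 1}_{_aa3(del_seg[-1])}{p + len(del_seg)}del"
    if ins_seg and not del_seg:
        if p == 0 or p >= len(wt):
            return "p.?"
        return f"p.{_aa3(wt[p - 1])}{p}_{_aa3(wt[p])}{p + 1}ins{_seq3(ins_seg)}"
    if del_seg and ins_seg:
        if len(del_seg) == 1:
            return f"p.{_aa3(del_seg)}{p + 1}delins{_seq3(ins_seg)}"
        return (f"p.{_aa3(del_seg[0])}{p + 1}_{_aa3(del_seg[-1])}"
                f"{p + len(del_seg)}delins{_seq3(ins_seg)}")
    return "p.(=)"  # pragma: no cover


# ---------------------------------------------------------------------------
# scenario drivers

def predict_new_acceptor(transcript: TranscriptModel, intron: IntronModel,
                         call: AgGainCall, genome, wt_protein: str) -> ProteinOutcome:
    mature = assemble_new_acceptor_transcript(transcript, intron, call, genome)
    out = translate_cds(mature, transcript)
    out.frameshift = (not out.transcript_ablation) and call.acc_dist % 3 != 0
    out.in_frame = not out.frameshift
    out.hgvs_p = out.hgvs_p or hgvs_protein(
        wt_protein, out.protein,
        frameshift=out.frameshift,
        stop_in_insertion=out.stop_in_insertion,
        transcript_ablation=out.transcript_ablation,
        has_stop=not out.stop_lost,
    )
    return out


def predict_exon_skip(transcript: TranscriptModel, intron: IntronModel,
                      genome, wt_protein: str) -> ProteinOutcome:
    mature = assemble_exon_skip_transcript(transcript, intron, genome)
    out = translate_cds(mature, transcript)
    coding = _coding_overlap(transcript, intron.intron_index)
    out.frameshift = (not out.transcript_ablation) and coding % 3 != 0
    out.in_frame = not out.frameshift
    out.hgvs_p = out.hgvs_p or hgvs_protein(
        wt_protein, out.protein,
        frameshift=out.frameshift,
        transcript_ablation=out.transcript_ablation,
        has_stop=not out.stop_lost,
    )
    return out


def _coding_overlap(transcript: TranscriptModel, skipped_exon_index: int) -> int:
    """Number of coding (CDS-overlapping) nt in the skipped exon."""
    if transcript.cds_start is None:
        return 0
    s, e = transcript.exons[skipped_exon_index]
    lo = max(s, transcript.cds_start)
    hi = min(e, transcript.cds_end)
    return max(0, hi - lo + 1)
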
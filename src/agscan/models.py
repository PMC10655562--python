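"""Domain types for intron-level splice-acceptor analysis.

Coordinate conventions
----------------------
External formats (GTF, VCF) are 1-based inclusive on the plus strand.
Inside an intron, positions are expressed as negative *3'-anchored offsets*
on the transcribed strand: the last intron base (the G of the canonical
terminal AG) is -1, the second-to-last (the A) is -2, and so on up to
-length at the intron's 5' end.  Branchpoints, zones and created-AG
coordinates all live in this frame, which mirrors the ACC-k / BP+k idiom
used throughout the splicing literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One protein-coding transcript: exons in transcription order plus CDS span.

    ``exons`` are 1-based inclusive genomic ``(start, end)`` intervals ordered
    5'→3' in transcription direction, i.e. by decreasing genomic coordinate on
    the minus strand.  ``cds_start``/``cds_end`` bound the annotated coding
    span genomically (min/max, strand-agnostic); ``None`` when not annotated.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon {s}-{e} inverted")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not ordered in transcription direction"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def start_codon_genomic(self) -> Optional[int]:
        """Genomic coordinate of the first base of the start codon."""
        if self.cds_start is None:
            return None
        return self.cds_start if self.strand == "+" else self.cds_end


@dataclass
class IntronModel:
    """One intron of one transcript, with a 3'-anchored coordinate accessor."""

    transcript_id: str
    intron_index: int  # 1-based IVS number in transcription direction
    chrom: str
    strand: str
    start: int  # genomic 1-based inclusive
    end: int
    acceptor_is_ag: bool = True  # reference intron ends ...AG on transcribed strand

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError(
                f"{self.key}: intron length {self.length} < 4 "
                "(cannot hold terminal AG plus flanks)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.transcript_id}_IVS{self.intron_index}"

    def genomic(self, offset: int) -> int:
        """Genomic coordinate of 3'-anchored ``offset`` (-length..-1)."""
        if not (-self.length <= offset <= -1):
            raise ValueError(f"{self.key}: offset {offset} outside [-{self.length},-1]")
        if self.strand == "+":
            return self.end + offset + 1
        return self.start - offset - 1

    def offset_of(self, genomic_pos: int) -> int:
        """3'-anchored offset of a genomic coordinate inside the intron."""
        if not (self.start <= genomic_pos <= self.end):
            raise ValueError(f"{self.key}: position {genomic_pos} not in intron")
        if self.strand == "+":
            return genomic_pos - self.end - 1
        return self.start - genomic_pos - 1


@dataclass
class BranchpointRecord:
    """A branchpoint nucleotide as a negative 3'-anchored intron offset.

    ``rank`` 1 is the BP closest to the acceptor, 2 the next closest.
    Offsets are restricted to the [-100, -3] acceptor-proximal window.
    """

    transcript_id: str
    intron_index: int
    offset: int
    rank: int = 0  # 0 = unranked (kept but unused for zones)

    def __post_init__(self) -> None:
        if not (-100 <= self.offset <= -3):
            raise ValueError(f"BP offset {self.offset} outside [-100, -3]")


@dataclass
class IntronZones:
    """The three analysis intervals of one intron, 3'-anchored, inclusive.

    zone1   [BP1+1, -4]                   — BP to acceptor, minus the terminal 3 nt
    zone2   [BP2+1, BP1-1]                — between the two ranked BPs (may be absent)
    zone3   [anchor-30, anchor-1]         — 30-nt control window 5' of the BP anchor
    high_risk [BP1+8, -4]                 — AG/YAG-depleted core of zone 1 (may be empty)
    """

    bp1: int
    bp2: Optional[int]
    zone1: Optional[tuple[int, int]]
    zone2: Optional[tuple[int, int]]
    zone3: tuple[int, int]
    high_risk: Optional[tuple[int, int]]

    @property
    def scan_extent(self) -> tuple[int, int]:
        """5'-most to 3'-most offset in which a created AG is reportable."""
        lo = self.zone2[0] if self.zone2 else self.zone1[0]
        return (lo, -4)


@dataclass
class NormalizedVariant:
    """A single-ALT variant in minimal representation.

    ``pos``/``ref``/``alt`` keep the usual VCF convention (one anchor base for
    indels).  ``core_pos``/``ref_core``/``alt_core`` are fully trimmed: no
    shared prefix or suffix; for a pure insertion ``ref_core == ""`` and the
    inserted bases go between ``core_pos - 1`` and ``core_pos``.
    All alleles are plus-strand.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_id: str
    core_pos: int
    ref_core: str
    alt_core: str
    source: str = ""

    @property
    def var_type(self) -> str:
        nr, na = len(self.ref_core), len(self.alt_core)
        if nr == 1 and na == 1:
            return "snv"
        if na == 0:
            return f"{nr} nt-deletion"
        if nr == 0:
            return f"{na} nt-insertion"
        return "complex"

    @property
    def net_change(self) -> int:
        return len(self.alt_core) - len(self.ref_core)


@dataclass
class AgGainCall:
    """One detected AG-gain event in one intron of one transcript.

    ``a_pos``/``g_pos`` are 3'-anchored offsets of the created AG measured on
    the mutated intron (counting back from its unchanged 3' end); ``bp_dist``
    is anchored to the zone's own BP in the same ALT frame.
    """

    variant: NormalizedVariant
    transcript_id: str
    intron_index: int
    gene_symbol: str
    zone: str  # "ZONE 1" or "ZONE 2"
    a_pos: int
    g_pos: int
    mechanism: str
    yag: bool
    bp_dist: int
    acc_dist: int
    high_risk: bool
    score: int = 0
    canonical: bool = False
    noncanonical_acceptor: bool = False
    alt_intron_seq: str = field(default="", repr=False)

    @property
    def transcript_ivs(self) -> str:
        return f"{self.transcript_id}_IVS{self.intron_index}"


@dataclass
class MatureTranscript:
    """A spliced mRNA as ordered segments with genomic provenance.

    Each segment is ``(label, sequence, genomic_positions)`` where
    ``genomic_positions`` is a list of genomic coordinates per base (None for
    bases retained from the intron under the new-acceptor scenario, whose
    coordinates live in the mutated allele).
    """

    scenario: str  # "wild-type" | "new-acceptor" | "exon-skip"
    segments: list[tuple[str, str, list[Optional[int]]]]
    start_codon_status: str = "intact"  # intact | ablated | unknown

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq, _ in self.segments)

    def mature_index(self, genomic_pos: int) -> Optional[int]:
        """Mature-mRNA index of a genomic coordinate, or None if absent."""
        i = 0
        for _, seq, gpos in self.segments:
            for j, g in enumerate(gpos):
                if g == genomic_pos:
                    return i + j
            i += len(seq)
        return None

    def segment_label(self, mature_idx: int) -> str:
        i = 0
        for label, seq, _ in self.segments:
            if i <= mature_idx < i + len(seq):
                return label
            i += len(seq)
        raise IndexError(mature_idx)


@dataclass
class ProteinOutcome:
    """Predicted protein product of one missplicing scenario."""

    scenario: str
    protein: str  # one-letter, no terminal '*'
    hgvs_p: str
    in_frame: bool = True
    frameshift: bool = False
    stop_in_insertion: bool = False
    transcript_ablation: bool = False
    stop_lost: bool = False
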
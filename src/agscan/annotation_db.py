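"""Parse genome annotation inputs into validated intron-level records.

Gene models come from a GENCODE-dialect GTF (parsed with gffutils), filtered
to protein-coding / basic / confidence-level 1-2 transcripts.  Branchpoints
are supplied externally, either as a 3-column offset TSV
(transcript_id, intron_index, offset) or a 6-column BED whose name field is
``transcript|intron|rank``; they are mapped into the [-100, -3] window
upstream of each acceptor and ranked by proximity to it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
from intervaltree import IntervalTree

from .models import BranchpointRecord, IntronModel, TranscriptModel

log = logging.getLogger(__name__)

GTF_FILTERS = {
    "transcript_type": "protein_coding",
    "tag": "basic",
    "levels": ("1", "2"),
}


def strip_version(transcript_id: str) -> str:
    """Drop a trailing .N version suffix from a transcript ID."""
    base, _, ver = transcript_id.partition(".")
    return base if ver.replace("_", "").isdigit() or ver == "" else transcript_id


def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def load_gene_models(gtf_path: str, filters: dict | None = None) -> list[TranscriptModel]:
    """Load transcripts from a GENCODE-dialect GTF, applying biotype/tag/level filters.

    Returns transcripts with exons ordered in transcription direction and the
    CDS span located from CDS (and start_codon, when present) records.
    Transcripts with zero exons are skipped with a warning.
    """
    filters = {**GTF_FILTERS, **(filters or {})}
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line-level failures
        raise ValueError(f"malformed GTF {gtf_path}: {exc}") from exc

    transcripts: list[TranscriptModel] = []
    for t in db.features_of_type("transcript"):
        biotype = _attr(t, "transcript_type", "transcript_biotype")
        if biotype != filters["transcript_type"]:
            continue
        tags = t.attributes.get("tag", [])
        if filters["tag"] not in tags:
            continue
        level = _attr(t, "level")
        if level not in filters["levels"]:
            continue
        tid = _attr(t, "transcript_id")
        exons = [(e.start, e.end) for e in db.children(t, featuretype="exon")]
        if not exons:
            warnings.warn(f"transcript {tid} has zero exons; skipped")
            continue
        exons.sort()
        if t.strand == "-":
            exons.reverse()
        cds = [(c.start, c.end) for c in db.children(t, featuretype="CDS")]
        cds += [(c.start, c.end) for c in db.children(t, featuretype="start_codon")]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=_attr(t, "gene_name") or _attr(t, "gene_id") or ".",
                chrom=t.seqid,
                strand=t.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts


def extract_introns(transcript: TranscriptModel) -> list[IntronModel]:
    """Derive introns (numbered 1..n-1 in transcription direction) from exons.

    A single-exon transcript yields an empty list.
    """
    introns: list[IntronModel] = []
    for i, ((s1, e1), (s2, e2)) in enumerate(
        zip(transcript.exons, transcript.exons[1:]), start=1
    ):
        if transcript.strand == "+":
            start, end = e1 + 1, s2 - 1
        else:
            start, end = e2 + 1, s1 - 1
        introns.append(
            IntronModel(
                transcript_id=transcript.transcript_id,
                intron_index=i,
                chrom=transcript.chrom,
                strand=transcript.strand,
                start=start,
                end=end,
            )
        )
    return introns


BP_WINDOW = (-100, -3)


def load_branchpoints(
    bp_path: str, introns: Iterable[IntronModel]
) -> list[BranchpointRecord]:
    """Read a branchpoint table and rank BPs per intron by acceptor proximity.

    Accepts a 3-column TSV ``transcript_id<TAB>intron_index<TAB>offset`` (offset
    negative, 3'-anchored) or a 6-column BED with name ``transcript|intron|rank``
    whose interval is the 1-bp BP locus.  BPs outside [-100, -3], on the wrong
    strand, or in unknown introns are skipped with a warning.  Surviving BPs
    are re-ranked deterministically by (offset descending, input order); ranks
    1 and 2 feed zone building, the rest are kept unranked.
    """
    by_key = {(i.transcript_id, i.intron_index): i for i in introns}
    raw: dict[tuple[str, int], list[tuple[int, int]]] = {}

    with open(bp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) >= 6 and "|" in fields[3]:
                chrom, start0, end, name, _score, strand = fields[:6]
                tid, idx_s = name.split("|")[:2]
                key = (strip_version(tid), int(idx_s))
                intron = by_key.get(key)
                if intron is None:
                    warnings.warn(f"{bp_path}:{lineno}: BP in unknown intron {name}")
                    continue
                if strand != intron.strand or chrom != intron.chrom:
                    warnings.warn(f"{bp_path}:{lineno}: BP strand/chrom mismatch")
                    continue
                gpos = int(end)  # BED half-open: end == 1-based position
                if not (intron.start <= gpos <= intron.end):
                    warnings.warn(f"{bp_path}:{lineno}: BP not inside intron {name}")
                    continue
                offset = intron.offset_of(gpos)
            elif len(fields) >= 3:
                tid, idx_s, off_s = fields[:3]
                key = (strip_version(tid), int(idx_s))
                if key not in by_key:
                    warnings.warn(f"{bp_path}:{lineno}: BP in unknown intron {tid}_IVS{idx_s}")
                    continue
                offset = int(off_s)
            else:
                raise ValueError(f"{bp_path}:{lineno}: unrecognised BP row: {line!r}")
            if not (BP_WINDOW[0] <= offset <= BP_WINDOW[1]):
                log.debug("BP offset %d outside %s; discarded", offset, BP_WINDOW)
                continue
            raw.setdefault(key, []).append((offset, lineno))

    records: list[BranchpointRecord] = []
    for key, offs in raw.items():
        # closest to the acceptor (largest offset) first; input order breaks ties
        ordered = sorted(set(offs), key=lambda t: (-t[0], t[1]))
        seen: set[int] = set()
        rank = 0
        for offset, _ in ordered:
            if offset in seen:
                continue
            seen.add(offset)
            rank += 1
            records.append(
                BranchpointRecord(key[0], key[1], offset, rank=rank if rank <= 2 else 0)
            )
    return records


def select_canonical(
    transcripts: Iterable[TranscriptModel], mane_list: Iterable[str]
) -> list[TranscriptModel]:
    """Mark transcripts found in a MANE-style ID list (versions stripped) canonical."""
    wanted = {strip_version(t.strip()) for t in mane_list if t.strip()}
    marked = []
    for t in transcripts:
        t.is_canonical = strip_version(t.transcript_id) in wanted
        if t.is_canonical:
            marked.append(t)
    if wanted and not marked:
        warnings.warn(
            "no transcript matched the canonical list; canonical mode would be "
            "empty — consider all-transcript mode"
        )
    return marked


@dataclass
class IntronDB:
    """Validated intron-level database: transcripts, introns, ranked BPs."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    introns: dict[tuple[str, int], IntronModel] = field(default_factory=dict)
    branchpoints: dict[tuple[str, int], list[BranchpointRecord]] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        gtf_path: str,
        bp_path: str,
        canonical_path: Optional[str] = None,
        genome=None,
        filters: dict | None = None,
    ) -> "IntronDB":
        db = cls()
        for t in load_gene_models(gtf_path, filters=filters):
            db.transcripts[t.transcript_id] = t
            for intron in extract_introns(t):
                db.introns[(t.transcript_id, intron.intron_index)] = intron
        for rec in load_branchpoints(bp_path, db.introns.values()):
            db.branchpoints.setdefault((rec.transcript_id, rec.intron_index), []).append(rec)
        if canonical_path:
            with open(canonical_path) as fh:
                select_canonical(db.transcripts.values(), fh)
        if genome is not None:
            db.flag_noncanonical_acceptors(genome)
        db._index()
        return db

    def _index(self) -> None:
        self._trees = {}
        for intron in self.introns.values():
            tree = self._trees.setdefault(intron.chrom, IntervalTree())
            tree.addi(intron.start, intron.end + 1, intron)

    def flag_noncanonical_acceptors(self, genome) -> None:
        """Check each intron's reference terminal dinucleotide; warn-and-keep non-AG."""
        from .zones import zone_sequence  # local import to avoid a cycle

        for intron in self.introns.values():
            tail = zone_sequence(genome, intron, (-2, -1))[0]
            if tail != "AG":
                intron.acceptor_is_ag = False
                warnings.warn(
                    f"{intron.key}: reference acceptor dinucleotide is {tail!r}, "
                    "not AG (non-canonical acceptor; kept, calls will be flagged)"
                )

    def ranked_bps(self, intron: IntronModel) -> list[BranchpointRecord]:
        recs = self.branchpoints.get((intron.transcript_id, intron.intron_index), [])
        return sorted([r for r in recs if r.rank in (1, 2)], key=lambda r: r.rank)

    def introns_overlapping(self, chrom: str, start: int, end: int) -> list[IntronModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda i: (i.transcript_id, i.intron_index))
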
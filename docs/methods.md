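# Methods

## Coordinate model

All intron-level reasoning uses 3'-anchored offsets on the transcribed
strand: the last intron base (the G of the canonical terminal AG) is −1,
so an offset −k means "k bases upstream of the exon boundary". GTF and VCF
coordinates are 1-based inclusive plus-strand externally; conversion
happens once, at the intron boundary, and round-trips exactly (a property
test checks the bijection per intron and invariance of all offsets under
reverse-complementing the entire fixture world). Branchpoints are inputs,
not predictions: rows outside the [−100, −3] acceptor-proximal window are
discarded, and per intron the surviving offsets are ranked by proximity to
the acceptor (ties broken by input order), with ranks 1–2 feeding zone
construction.

## Zones

- zone 1 = [BP1+1, −4]; its length is therefore −4 − BP1 (22 nt for the
  modal BP at −26).
- zone 2 = [BP2+1, BP1−1], only for multi-BP introns.
- zone 3 = the 30-nt window [anchor−30, anchor−1], where the anchor is the
  single BP or the second BP. "30 nt upstream of BP−1" is ambiguous about
  endpoints; we take the reading that yields exactly 30 nt abutting the BP.
- high-risk = [BP1+8, −4]; empty when BP1+8 > −4 (exact arithmetic:
  empty iff BP1 ≥ −11).

Zone sequences extending past a short intron's 5' end are truncated and
flagged rather than refused.

## Calling rule

A variant is first normalised (multi-allelic split, shared prefix/suffix
trimmed; a fully trimmed "core" with no anchor base drives all sequence
logic). Edits touching the branchpoint nucleotide or the intron's terminal
3 nt are refused with reason codes (`BP-variant`, `canonical-ACC variant`):
those disrupt existing signals rather than gain an AG, and belong to other
scanners.

The created-AG set is defined as

> AG occurrences of the ALT intron minus AG occurrences of the REF intron,
> both in 3'-end-anchored coordinates, restricted to occurrences that
> overlap the edited bases (or the deletion junction).

End-anchoring is what makes the rule behave for indels: positions 3' of the
edit are unchanged, so a deletion that shortens a run while preserving a
junction AG cancels out of the set difference and is *not* a gain, while a
genuine junction join survives. Distances are measured on the mutated
intron — BP offsets 5' of the edit are shifted by the net length change —
because splice-site choice operates on the mutant pre-mRNA. A created AG is
reported when its G lies at or 5' of −4 and its A past the zone's BP
anchor; zone-2 calls anchor BP_DIST to the second BP and are never
high-risk. One row is emitted per created AG locus per transcript-intron.

The production scanner works on an intron *suffix* window (zone extent plus
the indel length change plus margin); the test suite holds it equal to an
independently written oracle that rebuilds the entire mutated chromosome
with per-base provenance tags, on ≥10,000 random variants per run.

## Score

The 1–5 priority score is additive: 1 for any zone-1/2 gain, +1 zone 1,
+1 high-risk, +1 YAG (pyrimidine before the created AG), +1 ACC_DIST ≤ 17,
clamped to [1, 5]. The factor set is a package design choice calibrated to
three published anchors: the range 1–5, a maximal worked case (high-risk
YAG gain 6 nt from the acceptor scoring 5), and the recommendation that
high-risk calls with score ≥ 3 are the promising candidates. Weights are
overridable (`ScanOptions.weights`); the 17-nt acceptor-proximity threshold
mirrors the cohort observation that 95% of pathogenic gains lie ≤ 17 nt
from the acceptor. The score is monotone in every factor by construction
(tested exhaustively).

## Protein outcomes

Two products are predicted per call and neither is asserted to dominate:

- **new acceptor**: upstream exons + the ACC_DIST 3'-terminal nucleotides
  of the *mutated* intron + downstream exons. Frameshift iff
  ACC_DIST mod 3 ≠ 0.
- **exon skip**: the exon immediately downstream of the intron is removed.
  Frameshift iff its CDS-overlapping length mod 3 ≠ 0; skipping the exon
  holding the start codon is reported as gross transcript ablation
  (`p.0?`, no downstream-ATG rescue is attempted); skipping the terminal
  exon loses the stop codon and is flagged `stop_lost`, reported as `p.?`.

Translation uses the standard code from the annotated start codon (which
may sit in exon ≥ 2) to the first stop; a stop codon overlapping retained
intronic sequence sets `stop_in_insertion` — the AG-gain = stop-gain
coincidence, frequent because intron tails are mostly YAG and TAG is a stop.
HGVS p. strings are minimal descriptions derived from a prefix/suffix
diff of wild-type vs mutant protein: in-frame insertions (`ins...`, with a
trailing `*` when the insertion carries the stop), deletions, delins when a
codon-split junction changes a residue, nonsense (`p.Xn*`), and frameshifts
(`p.XnYfs*N`, `*?` when no stop is reached). Every emitted description is
re-applied to the wild-type protein in tests and must reproduce the mutant.
Selenocysteine and non-standard codes are unsupported.

## Cohort statistics

Fisher's exact test is computed exactly. The YAG-enrichment analysis
(new-acceptor vs other validated gains) uses the one-sided (greater) tail,
which is the computation that reproduces the published p = 0.0122 for the
229/29 vs 72/20 table; the two-sided point-probability value for the same
table is 0.0217, and both alternatives are exposed and verified against an
integer hypergeometric enumeration. Allele-frequency classes are singleton
(AC = 1, taking precedence), common (MAF ≥ 1%, boundary inclusive), else
rare. Distance-window shares use BP_DIST ≥ 8 and ACC_DIST ≤ 17, boundaries
inclusive as printed.

## RNA-structure concealment

Whether a natural zone-1 AG is "concealed" is judged on a dot-bracket
structure: both the A and the G must be paired, with partners inside the
zone sequence (pairing with flanking sequence is deliberately not modelled;
requiring within-zone partners is the stricter reading). Folding is
pluggable: the bundled default is a Nussinov-style maximum-base-pairing
folder (Watson–Crick + GU, minimum hairpin loop 3, deterministic
traceback); an external MFE program (RNAfold) can be substituted, and
published concealment percentages depend on the folding engine used, so
only the concealment judgement — not any particular percentage — is
guaranteed here.

## Synthetic fixtures

The generator emulates the intron architecture the method assumes: 3–5-exon
protein-coding genes on both strands (60–120-nt exons, 80–140-nt introns),
a branchpoint planted at −26 (the cohort modal offset; −31 added as a
second BP where zone-2 cases are requested), zone-1 bases drawn with
pyrimidine probability 0.76 (the reported zone-1 median), reference zones
scrubbed of AG (the depletion the method exploits), and canonical GT/AG
intron ends with a pyrimidine at −3. Planted variants are specified by
mechanism class and target BP distance; the generator rewrites the minimal
set of reference bases needed, then back-checks each plant by locally
mutating the sequence and re-deriving the gained AG. Truth tables carry the
expected Box-style annotations plus an IVS-style transcript-frame notation
alongside genomic coordinates, because allele-notation mismatches between
the two frames are a known failure mode on minus-strand genes.

What passing these tests does **not** show: real introns have variable BP
positions and multiplicities, non-canonical acceptors, alternative
transcripts sharing introns, and base composition far from i.i.d.; the
genome-wide percentages reported for the real genome (natural-AG rates,
pyrimidine medians, cohort shares) require the real genome, annotation and
BP database and are not reproduced at fixture scale — only the operations
that compute them are verified.

## Problem sizes and numerics

Default verification scales, chosen to keep the whole suite fast while
exercising every code path: oracle equivalence on 10,000 random variants
over a 6-gene fixture; generator/scanner closure over 100 seeds;
exhaustive enumeration cross-checks up to n = 8 (4^8 sequences). The no-AG
probability uses the exact linear recurrence t(k+1) = t(k) − pA·pG·t(k−1)
(a 2-state transfer matrix on "last base is A"), so no simulation error is
involved; base-probability vectors must sum to 1 within 1e−9. Fisher
comparisons against the enumeration oracle use 1e−9 absolute tolerance;
point-probability ties in the two-sided rule are guarded at relative
1e−12. Row ordering of scan output is deterministic (coordinate, then
transcript, then acceptor distance), and all generator outputs are
byte-identical for a fixed seed.

## Known limitations

No NMD prediction, no choice between the two missplicing scenarios, no
cryptic-site or intron-retention products, no AG-loss detection, no BP
discovery, single GTF dialect (GENCODE-style), and introns whose reference
acceptor is not AG (U12-type) are kept but flagged rather than modelled.
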
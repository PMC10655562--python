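# agscan

Genome-wide detection and annotation of intronic **AG-gain variants** —
SNVs and micro-indels whose ALT allele creates an AG dinucleotide between
the splicing **branchpoint (BP)** and the **canonical splice acceptor
(ACC)** of an intron.

## Why

During 3' splice-site selection, U2AF35 scans downstream of the branchpoint
for the first AG; the stretch from the BP to the acceptor (the
polypyrimidine tract) is therefore strongly depleted of AG in the reference
genome, especially from BP+8 onward. A variant that introduces an AG into
this zone can be recognised prematurely, producing a new acceptor site (the
intronic nucleotides 3' of the created G are spliced into the mRNA) or
complete skipping of the next exon. Such variants are routinely missed by
pipelines focused on coding regions and essential splice sites. `agscan`
pinpoints them from ordinary VCFs, and is aimed at human geneticists
prioritising candidate variants in disease cohorts.

## Model and annotations

Intron positions are counted back from the acceptor on the transcribed
strand (last intron base = −1). With BP1 the branchpoint closest to the
acceptor and BP2 the next closest:

- **zone 1** = [BP1+1, ACC−4], **zone 2** = [BP2+1, BP1−1],
  **zone 3** = the 30 nt 5' of the BP anchor (control region);
- a created AG at (a, a+1) gets **BP_DIST** = a − BP (on the mutated
  intron) and **ACC_DIST** = −(a+1) − 1, the retained-intron length if the
  new acceptor is used;
- **high-risk** = zone-1 gains with BP_DIST ≥ 8 (the [BP+8, ACC−4] core,
  where natural AG/YAG are nearly absent);
- **YAG** = the created AG is preceded by a pyrimidine (a stronger acceptor
  mimic);
- **score** (1–5) = 1 + zone 1 + high-risk + YAG + (ACC_DIST ≤ 17).

Mechanism classes: `snv-new-A`, `snv-new-G`, `del-junction` (a deletion
joins a distant A and G), `ins-contains-AG`, `ins-junction` (a G/A inserted
next to a preexisting A/G), and `complex`. For every call the package also
predicts the protein products of the two principal missplicing outcomes
(new acceptor; skipping of the next exon) with HGVS p. nomenclature.

## Worked example

The package ships a seeded fixture generator, so the whole workflow runs
without downloads:

```sh
agscan simulate --seed 7 --outdir demo
agscan scan --vcf demo/variants.vcf --genome demo/genome.fa \
    --gtf demo/genes.gtf --bp demo/bp.tsv \
    --canonical-list demo/canonical.txt --out demo/scan.tsv
```

`demo/scan.tsv` (selected columns):

```
        ID       VAR_TYPE  TRANSCRIPT_IVS AGAIN_ZONE AGAIN_YAG  AGAIN_BP_DIST  AGAIN_ACC_DIST AGAIN_HIGHRISK  AGAIN_SCORE                  HGVS_NEW_ACC   HGVS_EXON_SKIP
 p_snvA_hr            snv ENSTTGENE1_IVS1     ZONE 1       YES             16               8            YES            5               p.Asp26Glyfs*13  p.Asp26Glufs*20
 p_snvG_hr            snv ENSTTGENE1_IVS2     ZONE 1        NO             10              14            YES            4               p.Lys60Serfs*12 p.Lys60_Ala97del
p_snvA_low            snv ENSTTGENE1_IVS3     ZONE 1       YES              5              19             NO            3               p.Ala98Profs*20   p.Ala98Asnfs*?
     p_del  2 nt-deletion ENSTTGENE1_IVS4     ZONE 1       YES              9              13            YES            5               p.Thr130Serfs*?        p.Ser129*
   p_insAG 3 nt-insertion ENSTTGENE2_IVS1     ZONE 1       YES             12              15            YES            5 p.Val22_Val23insThrSerLeuLeu*  p.Val23Tyrfs*21
```

Reading the first row: the SNV creates an AG 16 nt downstream of the
branchpoint and 8 nt upstream of the acceptor, inside the high-risk core
(score 5). If the new acceptor is used, 8 intronic nucleotides (not a
multiple of 3) enter the mRNA and the protein frameshifts after Asp26 with
a stop 13 codons later; if the next exon is skipped instead, a different
frameshift results. Variants touching the branchpoint itself or the
canonical acceptor AG are refused with reason codes, since they belong to
BP-variant / acceptor-variant scanners, not an AG-*gain* scanner.
`agscan stats --scan-tsv demo/scan.tsv --out demo/stats.json` then
summarises zones, mechanisms, score and distance histograms, and (when
AC/AN columns are present) singleton/rare/common allele-frequency classes.
For prioritisation, restrict to `--high-risk-only --score-min 3`.

`agscan zones` writes a per-intron atlas (zone intervals, pyrimidine
content, naturally occurring AG/YAG, and optionally whether each natural AG
is concealed inside a predicted RNA stem).

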
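# evadx

A stepwise genetic-diagnosis toolkit for **SLC26A4-related enlarged
vestibular aqueduct (EVA)**, the most common inner-ear malformation in
children with sensorineural hearing loss. EVA and Pendred syndrome are
autosomal-recessive: a molecular diagnosis requires **two** pathogenic
*SLC26A4* alleles in trans (M2); patients with one (M1) or none (M0) after
routine exonic small-variant testing need additional stages to find the
missing alleles — multi-exon deletions invisible to SNV calling and deep
intronic variants that disrupt splicing.

`evadx` implements each of those stages as a library module with a thin CLI,
plus a synthetic-data generator so the entire pipeline is testable without
any sequencing data:

| module | what it does |
|---|---|
| `evadx.genemodel` | transcript model, HGVS c./g. mapping with intronic offsets (`c.304+941`), closed / breakpoint-exclusive interval arithmetic |
| `evadx.simulate` | synthetic locus, amplicon panel, trio depth matrices, long reads, cDNAs, and the cohort genotype / ACMG evidence tables as fixtures |
| `evadx.cnv` | amplicon read-depth CNV calling: normalisation to 10 Mbp/sample, cohort-median ratios, robust-z state calling, exon-range segmentation, trio inheritance |
| `evadx.breakpoints` | split-read deletion breakpoint resolution from 1–6 kb long reads, with microhomology left-alignment and VCF export |
| `evadx.splice` | pseudoexon (Alu exonization) consequence prediction: reading frame, protein consequence, premature-stop/NMD flag, RT-PCR product sizing |
| `evadx.acmg` | ACMG/AMP classification engine (PVS1, PS3, PM2, point-scaled PM3, PP3, PP4) with the standard combining rules |
| `evadx.report` | trio-phased genotype assembly, M0/M1/M2 diagnostic status, cohort yield and screening arithmetic |

## The core methods

**CNV from amplicon depths.** Mean depth $d_{sa}$ of sample $s$ over
amplicon $a$ is normalised so each sample's total data amount
$\sum_a d_{sa}\,\ell_a$ equals $10^7$ bp, then converted to ratios
$r_{sa} = d_{sa}/\mathrm{median}_s(d_{sa})$ against the cohort median
(with per-sample median-of-ratios recentering). States are assigned by
thresholds (CN0 < 0.2 ≤ CN1 < 0.7 ≤ CN2 < 1.3 ≤ CN≥3) gated by a robust
z-score ($1.4826\cdot\mathrm{MAD}$, $|z|\ge 3$), and adjacent same-state
amplicons merge into exon-range calls annotated with trio inheritance.

**Breakpoints from long reads.** A read spanning a deletion splits into a
reference prefix and suffix; exact k-mer anchors plus a bounded-mismatch
split scan locate the junction, left-aligned across any microhomology. The
consensus call reports the deletion length under both coordinate
conventions (closed, end−start).

**Pseudoexon consequence.** An exonized intronic segment of length $L$ is
in frame iff $L \equiv 0 \pmod 3$; a stop-free in-frame insertion adds
$L/3$ residues, otherwise the transcript is flagged as a premature
termination / nonsense-mediated-decay candidate. RT-PCR product sizes for
the wild-type and mutant cDNAs differ by exactly $L$.

**ACMG with PM3 points.** In-trans observations score 1.0 (confirmed),
0.5 (homozygous) and 0.5 (phase unknown) points; PM3 escalates to
Supporting/Moderate/Strong/VeryStrong at 0.5/1/2/4 points. Criteria at
their effective strengths are combined by the standard ACMG rules into
Pathogenic / Likely Pathogenic / VUS.

## Worked example

```bash
evadx simulate-cohort --out demo/cohort --seed 17
evadx call-cnv --depths demo/cohort/depths.tsv --panel demo/cohort/panel.bed \
               --ped demo/cohort/trios.ped --out demo/calls
head -4 demo/calls/cnv_calls.tsv
```

```
sample     chrom  start      end        exons      state  mean_ratio  z      n_amplicons  low_confidence  inheritance
3312024-1  chr7   107300790  107303893  Exons 1–3  CN1    0.536       -4.67  6            False           maternal
3312024-M  chr7   107300790  107303893  Exons 1–3  CN1    0.527       -4.75  6            False           unknown
3312061-1  chr7   107300790  107303893  Exons 1–3  CN1    0.551       -4.50  6            False           maternal
```

Proband 3312024-1 carries a heterozygous Exons 1–3 deletion (depth ratio
≈ 0.5 over all six member amplicons) transmitted from the mother, who shows
the same call. Cohort-level reporting:

```bash
evadx report --out demo/report
# diagnosed 9/13 (69%); 7 probands carry an exonic deletion
```

and the deep-intronic consequence prediction:

```bash
evadx annotate-splice --out demo/splice.json
# "consequence": "in_frame_insertion", "inserted_residues": 42,
# "length_difference": 126, "splice_sites_ok": true
```

The 126-bp exonized Alu segment in intron 3 is an in-frame insertion of 42
amino acids; RT-PCR across the exon 3/4 junction shows two products 126 bp
apart in a heterozygous carrier.

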
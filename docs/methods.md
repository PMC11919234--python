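# Methods

This note documents the models, parameter choices and numerical conventions
behind `evadx`, and what the synthetic-data generator does and does not
emulate.

## Coordinate model

All genomic positions are 1-based. The canonical interval convention is
*closed* (length = end − start + 1), the norm for GRCh37 clinical
reporting; a *breakpoint-exclusive* tag (length = end − start) is also
representable because published deletion coordinate pairs mix the two
conventions — the Exons 1–3 pairs are consistent with inclusive lengths
(7666, 3152 bp) while the Exons 5–6 and Exons 9–10 pairs are consistent
with end − start (1845, 4979 bp). We do not guess which convention any
given pair intends: breakpoint consensus calls report the length under
both.

HGVS c. mapping supports `c.N`, `c.N+M`, `c.N-M`. An intronic offset is
only valid from an exon-boundary base and must fit inside the adjacent
intron. `g_to_c` returns the nearest-boundary representation (donor side
wins ties), so `g_to_c ∘ c_to_g` is the identity for exonic positions and
for intronic offsets within the nearer half of their intron. Minus-strand
mapping is implemented and tested on toy models although the packaged
locus is plus-strand.

### The packaged locus fixture

The real GRCh37 exon coordinates of *SLC26A4* are not reproduced here; the
packaged model (`data/slc26a4_synthetic_transcript.json`, explicitly
synthetic) is a 21-exon plus-strand gene constructed to satisfy every
containment relation the analysis depends on:

- exon 3 ends at c.304, so c.304+941 lies in intron 3;
- exon 9 starts at c.919, exon 12 at c.1264, exon 14 ends at c.1614, so
  the catalogued intronic variants sit on real boundaries;
- exons 1–3, 5–6 and 9–10 fall inside the corresponding published deletion
  windows, with the 3152-bp window clipping exon 3 partially;
- the CDS (c.1–2343) is divisible by 3, giving a 780-residue protein.

A user-supplied GFF3 (exon + CDS features, single transcript) overrides
the fixture everywhere a model is accepted.

## Synthetic-data generator

The generator produces every input the pipeline consumes. All randomness
derives from one integer seed; each stage uses a deterministic substream
(`SeedSequence([seed, crc32(stage)])`), so stages are independently
reproducible and identical seeds give byte-identical outputs.

**Locus reference.** Bases are uniform random, then landmarks are stamped:
canonical AG/GT dinucleotides at every intron boundary and around the
pseudoexon, ATG/TAA at the CDS ends, and the reference alleles of all
catalogued variants. Premature stop codons are scrubbed from the wild-type
CDS and from the pseudoexon insertion frame (including hybrid junction
codons), so the planted 126-bp segment is stop-free — whether the real
exonized segment is stop-free is asserted by its reported in-frame
42-residue insertion but its sequence is not public, so user-supplied
sequences are *flagged*, not assumed, stop-free.

**Amplicon panel.** Two amplicons per exon (configurable) with a 10-bp
flank, mirroring a multiplex-PCR design at the published panel's
granularity; the real panel's coordinates are not public.

**Depth model.** For sample *s* and amplicon *a*,

    depth[s,a] ~ NB(mean = mu0 · t_s · e_a · CN[s,a]/2,  size = r)

with amplicon efficiency `e_a ~ logNormal(0, 0.4)` shared across samples
(multiplex-PCR amplicons differ strongly but reproducibly in yield),
sample throughput `t_s ~ logNormal(0, 0.2)`, and `mu0` chosen so a diploid
unit-throughput sample totals `mean_total_bases = 1e7` bp — the fixed
total the normalisation stage assumes. The NB size parameter defaults to
`r = 200` (per-amplicon depth CV of ≈ 8 % at panel-typical depth), a
mid-range value for well-behaved amplicon panels; `r = inf` gives the
Poisson limit. An amplicon is lost from an allele whenever the deletion
overlaps it at all (a clipped amplicon cannot amplify), so a
partial-exon deletion shows the same amplicon footprint as the full-exon
event — deliberately matching the fact that depth analysis reports
amplicon-resolution ranges and breakpoint refinement is a separate stage.
Homozygous-deletion amplicons default to depth 0, with an optional
contamination fraction.

What the generator does **not** emulate: GC and length-dependent coverage
bias, PCR chimeras, FASTQ-level reads with quality strings, indel
sequencing errors (long-read errors are substitution-only so the
breakpoint oracle stays exact), and real population allele frequencies.
Passing tests therefore demonstrate correctness of the *methods* under a
plausible noise model, not performance on real instrument data.

**Trios.** Planted events specify the proband's zygosity and parental
origin; carrier parents are planted automatically, so truth tables are
Mendelian-consistent by construction. De novo events are supported.

**Long reads.** Fragment lengths uniform on 1–6 kb (the SMRT shear
range), uniform start positions on the chosen haplotype, substitution
errors at the requested rate.

## CNV calling

Normalisation rescales each sample so Σ depth·length = 10⁷ bp. Ratios are
taken against the cohort median per amplicon (≥ 3 samples; configurable
reference vector), then **recentred by each sample's median ratio**:
fixed-total normalisation necessarily inflates every ratio of a deletion
carrier because its denominator lost the deleted bases; median-of-ratios
recentering (standard in depth-based CNV analysis) removes that shift
whenever fewer than half the amplicons are affected. Without it, hom-
deletion carriers showed spurious single-amplicon CN≥3 calls at ratio
≈ 1.3.

State thresholds are midpoints between copy-number expectations —
CN0 < 0.2, CN1 < 0.7, CN≥3 ≥ 1.3 — with a robust z-gate: non-diploid
states need |z| ≥ 3, where z uses 1.4826·MAD across samples (zero
deviation ⇒ z = 0 even when MAD = 0). Gated-out amplicons are flagged
*suspect* rather than discarded.

Segmentation forms maximal runs of adjacent amplicons sharing a
ratio-implied state and emits a run only if **at least one member passed
the z-gate**. Rationale: the gate is applied per amplicon, so a single
underpowered amplicon inside a genuine six-amplicon event would otherwise
split the call and destroy exon-range-exact recovery; conversely an
isolated suspect amplicon still yields no call. Single-amplicon calls are
flagged low-confidence. Duplication states are called although the
studied cohort contained none, keeping the gain side of the method
testable.

Inheritance: a proband CN1 call matching a parental CN1 call over the
same exon range is paternal/maternal; proband CN0 with both parents CN1
is homozygous-biparental; genotyped parents without support gives de
novo; ungenotyped parents give unknown.

Measured on 100 simulated 13-trio cohorts at the defaults above
(seeds 0–99), exon-range-exact recall is ≈ 0.999 and precision ≈ 0.98 for
planted CN0/CN1 events; both are asserted ≥ 0.95 in the acceptance tests.

## Breakpoint resolution

Anchoring is exact k-mer seeding (k = 20) from both read ends plus a
bounded-mismatch split scan — no affine-gap alignment, which is adequate
because simulated long-read errors are substitutions only. With prefix
anchor p and suffix anchor q, the junction index i minimises
mismatches(read[:i] vs ref) + mismatches(read[i:] vs ref); the leftmost
minimum is taken, which is exactly left-alignment across junction
microhomology (the count of equivalent minima is reported as the
microhomology length). Candidates need ≥ 30 bp (`min_anchor`) on each
side and a best split within a 2 % mismatch budget; fully matching reads
return none. Consensus takes the modal left-aligned interval; a tie
between modes is an error listing both, never a silent choice. VCF export
is sequence-resolved (POS = anchor base, REF = anchor + deleted sequence)
with a symbolic `<DEL>` fallback when the deletion abuts the contig
start. An exhaustive two-segment-decomposition oracle verifies the
resolver on references ≤ 5 kb in the test suite.

## Pseudoexon consequence

Insertion length L is in frame iff L mod 3 = 0. The junction phase is
derived from the CDS coordinate of the upstream exon's last base (for the
fixture's intron 3: 304 coding bases ⇒ phase 1). Protein consequences are
determined by brute-force translation of the mutant CDS, distinguishing
in-frame stop-free insertion (L/3 residues), in-frame insertion with an
internal stop, and frameshift with the first downstream premature
termination codon; any premature stop sets the NMD-candidate flag.
Splice-site validation checks the canonical AG (acceptor) / GT (donor)
dinucleotides immediately outside the included segment and warns — does
not fail — on non-canonical context. External splice predictors are
consumed as annotation values only, never computed. RT-PCR sizing
requires each primer (forward on the sense strand, reverse complement of
the reverse primer) to occur exactly once per transcript; the product
spans the two primer 5′ ends inclusive.

## ACMG engine

Pathogenic-side criteria only; benign tiers are out of scope, so the
classification floor is VUS. PM2 applies at Moderate when the variant is
absent or below 7 × 10⁻⁵ in the relevant (sub)population and at
Supporting below 7 × 10⁻⁴, the hearing-loss-specific cut-offs. PM3 uses
the ClinGen SVI point scale — 1.0 per confirmed in-trans observation, 0.5
per homozygote, 0.5 per phase-unknown observation, escalating at
0.5/1/2/4 points; no per-variant cap is applied to phase-unknown points
(caps vary between scheme versions; the weights and thresholds are
arguments). PP3 uses REVEL > 0.7 for missense and dbscSNV ADA > 0.957
(community default) for splice-region variants; PS3 strength comes from
the stated functional-evidence level. Combining follows the standard ACMG
rules with ≥-semantics throughout, which makes the verdict monotone:
adding or upgrading evidence can never downgrade it.

Classifying the packaged 13-variant evidence table reproduces 12/13
published verdicts. The discrepant row shares its exact criteria shape
{PM2, PM3_Strong, PP3, PP4} with another row that is printed with the
*other* class; the engine yields Likely Pathogenic for both and surfaces
the mismatch in its concordance report rather than special-casing either
row. Similarly, one canonical-splice variant with two confirmed in-trans
observations is printed at default PM3 (Moderate) where the point scale
gives Strong; the engine follows the points (the final class is
unaffected) and the divergence is asserted explicitly in the tests.

## Reporting

Trio phasing assigns a proband's het variant to the parental allele that
carries it; variants present in both parents or in neither stay unphased
(with Mendelian/de-novo warnings), and unphased variants count toward M1
at most, since in-trans configuration cannot be established. A homozygous
variant, or a CN0 call with biparental CN1 support, fills both alleles.
Two variants on one parental allele remain one allele. M2 requires a
Pathogenic or Likely Pathogenic variant on *each* parental allele; VUS
never counts. Yield percent is rounded half-up (9/13 → 69 %); screening
frequency is reported in per-mille to two decimals.

Two genotype-table alleles have no evidence row in the published
classification table: c.919-2A>G (a canonical splice-acceptor founder
variant with long-established pathogenicity) and c.2168A>G. The fixture
classification map assumes Pathogenic and Likely Pathogenic respectively,
each emitting a warning, because the genotype table counts both as
diagnostic alleles; callers can override either via the `extra` argument.
CNV-stage alleles are labelled by exon range without a base-pair length —
depth analysis cannot resolve breakpoints, so base-pair lengths belong to
the breakpoint stage.

## Problem sizes and tolerances

The acceptance tests run 100 simulated 13-trio cohorts for CNV recovery
(seeds 0–99, ~4 s total) and 550 reads per deletion geometry per error
rate for breakpoint recovery (~40× junction coverage). Depth-model
sanity checks use 200-replicate means against the forward model (3 SE
bands); the ratio-≈-0.5 check allows ±0.02 for the small-sample median
bias analysed above. Floating-point conservation checks use 10⁻⁶
relative tolerance.

## Known limitations

- The locus, panel and noise model are synthetic; thresholds (0.2/0.7/1.3,
  |z| ≥ 3) were chosen from copy-number expectations, not tuned on real
  panel data.
- The breakpoint resolver assumes one deletion per read and substitution
  errors only; indel-rich real long reads would need gapped anchoring.
- Only simple HGVS descriptors are parsed; multi-isoform transcript
  selection is out of scope.
- Benign-side ACMG criteria and the full PVS1 decision tree are not
  implemented.
- NMD is a boolean candidacy flag, not a quantitative efficiency model.
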
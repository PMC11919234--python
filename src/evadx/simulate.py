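"""Synthetic-data generator for the SLC26A4 diagnostic pipeline.

Every input the pipeline consumes can be produced here with the statistical
structure the analysis assumes: a synthetic locus reference with canonical
splice contexts and a plantable pseudoexon, a multiplex-PCR amplicon panel,
per-amplicon trio depth matrices (negative-binomial counting noise on top of
lognormal amplicon efficiency and sample throughput), long reads spanning
deletion alleles, wild-type/mutant cDNA pairs for the RT-PCR assay, and the
published cohort genotype and ACMG-evidence tables as structured fixtures.

All randomness flows from a single integer seed through per-stage
sub-streams, so each stage is independently reproducible.

The locus model and reference sequence are synthetic stand-ins constructed
to reproduce the published containment relations (deletion windows vs exon
groups, c.304+941 inside intron 3); they are not the real GRCh37 annotation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acmg import EvidenceProfile
from .cnv import Amplicon, AmpliconPanel, DepthMatrix
from .genemodel import (
    CoordinateError,
    CPosition,
    FIXTURE_TAG,
    GenomicInterval,
    LocusReference,
    TranscriptModel,
    c_to_g,
    cdna_sequence,
    load_transcript,
    parse_c_notation,
)
from .pedigree import Pedigree
from .splice import PseudoexonEvent, apply_pseudoexon, junction_phase

# ---------------------------------------------------------------------------
# locus constants (synthetic coordinates consistent with the packaged model)

REFERENCE_WINDOW = (107_299_000, 107_346_500)
CHROM = "chr7"

#: the 126-bp exonized segment in intron 3 containing the c.304+941 position
PSEUDOEXON_ACCEPTOR = 107_304_761
PSEUDOEXON_DONOR = 107_304_886
PSEUDOEXON_INTRON = 3

#: deleted segments (closed intervals) for the four published geometries
DELETION_INTERVALS: dict[str, GenomicInterval] = {
    "Exons 1–3 deletion (7666 bp)": GenomicInterval(CHROM, 107_300_016, 107_307_681),
    "Exons 1–3 deletion (3152 bp)": GenomicInterval(CHROM, 107_300_698, 107_303_849),
    "Exons 5–6 deletion (1845 bp)": GenomicInterval(CHROM, 107_314_218, 107_316_062),
    "Exons 9–10 deletion (4979 bp)": GenomicInterval(CHROM, 107_329_304, 107_334_282),
}

#: small variants: c. position notation, reference/alternate allele, class
SNV_DEFS: dict[str, tuple[str, str, str, str]] = {
    "c.279T>A": ("c.279", "T", "A", "missense"),
    "c.281C>T": ("c.281", "C", "T", "missense"),
    "c.304+941C>T": ("c.304+941", "C", "T", "intronic_splice"),
    "c.946G>T": ("c.946", "G", "T", "nonsense"),
    "c.919-2A>G": ("c.919-2", "A", "G", "canonical_splice"),
    "c.1264-6T>G": ("c.1264-6", "T", "G", "intronic_splice"),
    "c.1315G>A": ("c.1315", "G", "A", "missense"),
    "c.1547dup": ("c.1547", "T", "TT", "frameshift"),
    "c.1614+1G>A": ("c.1614+1", "G", "A", "canonical_splice"),
    "c.1667A>G": ("c.1667", "A", "G", "missense"),
    "c.2168A>G": ("c.2168", "A", "G", "missense"),
}

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage substream of the master seed (deterministic counter split)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def fixture_pseudoexon_event() -> PseudoexonEvent:
    return PseudoexonEvent(
        PSEUDOEXON_INTRON, PSEUDOEXON_ACCEPTOR, PSEUDOEXON_DONOR, CHROM
    )


# ---------------------------------------------------------------------------
# reference sequence


def simulate_reference(
    seed: int = 0,
    model: Optional[TranscriptModel] = None,
    window: tuple[int, int] = REFERENCE_WINDOW,
) -> LocusReference:
    """Random locus sequence with the biological landmarks planted.

    Stamps canonical AG/GT dinucleotides at every intron boundary and around
    the pseudoexon, an ATG start and TAA stop for the CDS, the reference
    alleles of all catalogued small variants, and scrubs premature stop
    codons from the wild-type CDS and from the pseudoexon insertion frame so
    the exonized segment is stop-free (an in-frame 42-residue insertion).
    """
    model = model or load_transcript(FIXTURE_TAG)
    rng = _rng(seed, "reference")
    start, end = window
    n = end - start + 1
    seq = list(_BASES[rng.integers(0, 4, size=n)])
    protected: set[int] = set()

    def stamp(gpos: int, base: str, protect: bool = True) -> None:
        seq[gpos - start] = base
        if protect:
            protected.add(gpos)

    # canonical splice contexts for the real introns
    for i, ex in enumerate(model.exons):
        if i > 0:
            stamp(ex.start - 2, "A")
            stamp(ex.start - 1, "G")
        if i < model.n_exons - 1:
            stamp(ex.end + 1, "G")
            stamp(ex.end + 2, "T")
    # CDS start / stop codons (c. coordinates)
    c_len = model.cds_end - model.cds_start + 1
    for off, b in enumerate("ATG"):
        stamp(c_to_g(model, CPosition(1 + off)), b)
    for off, b in enumerate("TAA"):
        stamp(c_to_g(model, CPosition(c_len - 2 + off)), b)
    # pseudoexon splice context
    stamp(PSEUDOEXON_ACCEPTOR - 2, "A")
    stamp(PSEUDOEXON_ACCEPTOR - 1, "G")
    stamp(PSEUDOEXON_DONOR + 1, "G")
    stamp(PSEUDOEXON_DONOR + 2, "T")
    # reference alleles of catalogued variants
    for c_notation, ref, _alt, _cls in SNV_DEFS.values():
        stamp(c_to_g(model, parse_c_notation(c_notation)), ref)

    genome = lambda: LocusReference(CHROM, start, "".join(seq))  # noqa: E731

    # scrub premature stops from the wild-type CDS (keep the real stop)
    cdna = cdna_sequence(model, genome())
    c2g = {c: c_to_g(model, CPosition(c)) for c in range(1, c_len + 1)}
    for codon_start in range(1, c_len - 3, 3):
        codon = cdna[
            model.cds_start + codon_start - 2 : model.cds_start + codon_start + 1
        ].upper()
        if codon in _STOPS:
            for off in range(3):
                g = c2g[codon_start + off]
                if g not in protected:
                    stamp(g, "C", protect=False)
                    break
    # scrub stops from the pseudoexon insertion frame (incl. hybrid codons)
    phase = junction_phase(model, PSEUDOEXON_INTRON)
    cdna = cdna_sequence(model, genome())
    _, hi = model.exon_cdna_bounds(PSEUDOEXON_INTRON)
    ins_len = PSEUDOEXON_DONOR - PSEUDOEXON_ACCEPTOR + 1
    for j in range(-phase, ins_len, 3):
        bases, ins_positions = [], []
        for off in range(3):
            k = j + off
            if k < 0:
                bases.append(cdna[hi + k])  # upstream exon base
            elif k < ins_len:
                g = PSEUDOEXON_ACCEPTOR + k
                bases.append(seq[g - start])
                ins_positions.append(g)
            else:
                bases.append(cdna[hi + (k - ins_len)])  # downstream exon base
        if "".join(bases).upper() in _STOPS:
            for g in ins_positions:
                if g not in protected:
                    stamp(g, "C", protect=False)
                    break
    return genome()


# ---------------------------------------------------------------------------
# amplicon panel


def default_panel(
    model: Optional[TranscriptModel] = None,
    per_exon: int = 2,
    flank: int = 10,
) -> AmpliconPanel:
    """Two amplicons per exon (configurable), each with a small flank."""
    model = model or load_transcript(FIXTURE_TAG)
    amps: list[Amplicon] = []
    letters = "abcdefgh"
    exons = sorted(model.exons, key=lambda e: e.start)
    index_of = {id(e): i + 1 for i, e in enumerate(model.exons)}
    for ex in exons:
        i = index_of[id(ex)]
        cuts = np.linspace(ex.start, ex.end + 1, per_exon + 1).astype(int)
        for j in range(per_exon):
            s = int(cuts[j]) - (flank if j == 0 else 0)
            e = int(cuts[j + 1]) - 1 + (flank if j == per_exon - 1 else 0)
            amps.append(
                Amplicon(
                    f"e{i:02d}{letters[j]}",
                    GenomicInterval(model.chrom, s, e),
                    f"exon{i}",
                )
            )
    panel = AmpliconPanel(amps)
    assert panel.covers_all_exons(model)
    return panel


# ---------------------------------------------------------------------------
# cohort specification & truth


@dataclass(frozen=True)
class PlantedEvent:
    """One planted variant in one trio.

    ``origin`` is "paternal", "maternal", "de_novo" or "biparental" (the
    last meaning both parents are heterozygous carriers and the proband is
    homozygous; only valid with zygosity "hom").
    """

    family: str
    kind: str  # "deletion" | "snv"
    allele: str  # deletion label or variant id
    zygosity: str = "het"  # proband zygosity
    origin: str = "paternal"

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "snv"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.origin not in ("paternal", "maternal", "de_novo", "biparental"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if (self.zygosity == "hom") != (self.origin == "biparental"):
            raise ValueError("hom zygosity requires biparental origin and vice versa")

    @property
    def interval(self) -> Optional[GenomicInterval]:
        return DELETION_INTERVALS.get(self.allele)


@dataclass
class CohortSpec:
    """Forward-model parameters for a trio cohort.

    ``mean_total_bases`` (default 1e7 bp) matches the fixed total data
    amount the depth normalisation assumes; ``depth_dispersion`` is the
    negative-binomial size parameter (larger = less overdispersed;
    ``inf`` = Poisson); ``efficiency_sd`` is the log-scale SD of the
    amplicon-specific amplification efficiency shared across samples;
    ``throughput_sd`` the log-scale SD of per-sample sequencing yield.
    """

    n_trios: int
    panel: AmpliconPanel
    planted_events: list[PlantedEvent] = field(default_factory=list)
    mean_total_bases: float = 1e7
    depth_dispersion: float = 200.0
    efficiency_sd: float = 0.4
    throughput_sd: float = 0.2
    contamination: float = 0.0  # residual depth fraction on CN0 amplicons
    seed: int = 0
    families: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if not self.depth_dispersion > 0:
            raise ValueError("depth_dispersion must be > 0")
        fams = self.family_ids()
        unknown = {e.family for e in self.planted_events} - set(fams)
        if unknown:
            raise ValueError(f"events reference unknown families: {unknown}")

    def family_ids(self) -> list[str]:
        if self.families is not None:
            if len(self.families) != self.n_trios:
                raise ValueError("families length must equal n_trios")
            return self.families
        return [f"F{i + 1:02d}" for i in range(self.n_trios)]

    def sample_ids(self) -> list[str]:
        out = []
        for fam in self.family_ids():
            out.extend([f"{fam}-1", f"{fam}-F", f"{fam}-M"])
        return out

    def pedigree(self) -> Pedigree:
        ped = Pedigree()
        for fam in self.family_ids():
            ped.add_trio(fam, f"{fam}-1", f"{fam}-F", f"{fam}-M")
        return ped


@dataclass(frozen=True)
class TruthEvent:
    sample: str
    kind: str
    allele: str
    zygosity: str  # this sample's zygosity
    origin: str  # proband origin, or "carrier" for a parent

    @property
    def interval(self) -> Optional[GenomicInterval]:
        return DELETION_INTERVALS.get(self.allele)


@dataclass
class TruthTable:
    """Simulation ground truth: per-amplicon copy number + planted variants."""

    copy_number: pd.DataFrame  # samples x amplicons, ints in {0,1,2,3}
    events: list[TruthEvent]

    def expected_calls(
        self, panel: AmpliconPanel, model: TranscriptModel
    ) -> set[tuple[str, str, int, int]]:
        """(sample, state, first_exon, last_exon) tuples implied by truth CN."""
        from .genemodel import exons_overlapped

        out: set[tuple[str, str, int, int]] = set()
        order = panel.ids
        for sample in self.copy_number.index:
            row = self.copy_number.loc[sample]
            i = 0
            while i < len(order):
                cnval = row[order[i]]
                if cnval == 2:
                    i += 1
                    continue
                j = i
                while j + 1 < len(order) and row[order[j + 1]] == cnval:
                    j += 1
                members = order[i : j + 1]
                ivs = [panel[a].interval for a in members]
                iv = GenomicInterval(
                    ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)
                )
                er = exons_overlapped(model, iv)
                state = {0: "CN0", 1: "CN1", 3: "CN>=3"}[int(cnval)]
                if er is not None:
                    out.add((sample, state, er.first_exon, er.last_exon))
                i = j + 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "copy_number": {
                s: self.copy_number.loc[s].to_dict() for s in self.copy_number.index
            },
            "events": [
                {
                    "sample": e.sample,
                    "kind": e.kind,
                    "allele": e.allele,
                    "zygosity": e.zygosity,
                    "origin": e.origin,
                }
                for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        cn = pd.DataFrame.from_dict(payload["copy_number"], orient="index")
        events = [TruthEvent(**e) for e in payload["events"]]
        return cls(cn, events)


def _carriers(event: PlantedEvent, fam: str) -> list[tuple[str, int, str]]:
    """(sample, n alleles, zygosity) for each carrier in the trio."""
    child, father, mother = f"{fam}-1", f"{fam}-F", f"{fam}-M"
    if event.origin == "biparental":
        return [(child, 2, "hom"), (father, 1, "het"), (mother, 1, "het")]
    if event.origin == "paternal":
        return [(child, 1, "het"), (father, 1, "het")]
    if event.origin == "maternal":
        return [(child, 1, "het"), (mother, 1, "het")]
    return [(child, 1, "het")]  # de novo


def simulate_depth_matrix(spec: CohortSpec) -> tuple[DepthMatrix, TruthTable]:
    """Forward-model per-amplicon mean depths for a trio cohort.

    depth[s, a] ~ NB(mean = mu0 * throughput[s] * eff[a] * CN[s, a] / 2),
    with mu0 chosen so that a diploid sample with unit throughput totals
    ``mean_total_bases`` of data. Identical seeds give identical matrices.
    """
    panel = spec.panel
    samples = spec.sample_ids()
    amp_ids = panel.ids
    A, S = len(amp_ids), len(samples)
    lengths = panel.lengths.to_numpy(dtype=float)
    sample_idx = {s: i for i, s in enumerate(samples)}
    amp_idx = {a: i for i, a in enumerate(amp_ids)}

    cn = np.full((S, A), 2, dtype=int)
    events: list[TruthEvent] = []
    for ev in spec.planted_events:
        fam = ev.family
        if ev.kind == "deletion":
            iv = ev.interval
            if iv is None:
                raise ValueError(f"unknown deletion allele {ev.allele!r}")
            hit = [amp_idx[a] for a in panel.overlapping(iv)]
            if not hit:
                raise ValueError(
                    f"deletion {ev.allele} overlaps no panel amplicon"
                )
            for sample, nalleles, zyg in _carriers(ev, fam):
                cn[sample_idx[sample], hit] -= nalleles
                events.append(
                    TruthEvent(
                        sample,
                        "deletion",
                        ev.allele,
                        zyg,
                        ev.origin if sample.endswith("-1") else "carrier",
                    )
                )
        else:
            for sample, _n, zyg in _carriers(ev, fam):
                events.append(
                    TruthEvent(
                        sample,
                        "snv",
                        ev.allele,
                        zyg,
                        ev.origin if sample.endswith("-1") else "carrier",
                    )
                )
    if (cn < 0).any():
        raise ValueError("overlapping deletions drove copy number below 0")

    rng = _rng(spec.seed, "depth")
    eff = rng.lognormal(0.0, spec.efficiency_sd, size=A)
    throughput = rng.lognormal(0.0, spec.throughput_sd, size=S)
    mu0 = spec.mean_total_bases / float((eff * lengths).sum())
    mean = (
        mu0
        * throughput[:, None]
        * eff[None, :]
        * (cn / 2.0 + spec.contamination * (cn == 0))
    )
    if np.isinf(spec.depth_dispersion):
        depth = rng.poisson(mean).astype(float)
    else:
        r = spec.depth_dispersion
        p = r / (r + mean)
        depth = rng.negative_binomial(r, p).astype(float)
    dm = DepthMatrix(
        pd.DataFrame(depth, index=samples, columns=amp_ids), panel.lengths
    )
    truth = TruthTable(
        pd.DataFrame(cn, index=samples, columns=amp_ids), events
    )
    return dm, truth


# ---------------------------------------------------------------------------
# long reads


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    haplotype_start: int  # 0-based start on the (deletion) haplotype
    spans_junction: bool
    deletion: Optional[GenomicInterval]
    n_errors: int


def simulate_long_reads(
    reference: LocusReference,
    deletion: Optional[GenomicInterval],
    n_reads: int,
    read_len_range: tuple[int, int] = (1000, 6000),
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Reads sampled from the (optionally deletion-bearing) haplotype.

    Fragment lengths are uniform over ``read_len_range`` (the 1–6 kb shear
    range of the long-read protocol); errors are substitutions only, at
    ``error_rate`` per base. Reads from a deletion haplotype omit the
    deleted segment; the per-read truth records whether the read spans the
    novel junction.
    """
    if deletion is not None:
        hap = reference.without(deletion)  # raises if outside the window
        junction = deletion.start - reference.offset
    else:
        hap, junction = reference.seq, None
    lo, hi = read_len_range
    if len(hap) < lo:
        raise ValueError("haplotype shorter than the minimum read length")
    rng = _rng(seed, "reads")
    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    for i in range(n_reads):
        L = int(rng.integers(lo, hi + 1))
        L = min(L, len(hap))
        start = int(rng.integers(0, len(hap) - L + 1))
        read = list(hap[start : start + L])
        k = int(rng.binomial(L, error_rate)) if error_rate > 0 else 0
        if k:
            for pos in rng.choice(L, size=k, replace=False):
                alternatives = [b for b in "ACGT" if b != read[pos]]
                read[pos] = alternatives[int(rng.integers(0, 3))]
        rid = f"read{i:05d}"
        spans = junction is not None and start < junction < start + L
        reads.append((rid, "".join(read)))
        truth.append(ReadTruth(rid, start, spans, deletion, k))
    return reads, truth


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# transcripts


def simulate_transcripts(
    model: Optional[TranscriptModel] = None,
    pseudoexon: Optional[PseudoexonEvent] = None,
    genome: Optional[LocusReference] = None,
    seed: int = 0,
) -> dict[str, str]:
    """Wild-type (and, with a pseudoexon, mutant) cDNA sequences.

    The mutant cDNA is the wild-type with the pseudoexon sequence spliced in
    at the host-intron junction; ``len(mutant) - len(wildtype)`` equals the
    pseudoexon length.
    """
    model = model or load_transcript(FIXTURE_TAG)
    genome = genome if genome is not None else simulate_reference(seed, model)
    wt = cdna_sequence(model, genome)
    if pseudoexon is None:
        return {"wildtype": wt}
    consequence = apply_pseudoexon(model, pseudoexon, genome)
    return {"wildtype": wt, "mutant": consequence.mutant_cdna}


def fixture_rtpcr_primers(
    model: Optional[TranscriptModel] = None,
    genome: Optional[LocusReference] = None,
    seed: int = 0,
) -> tuple[str, str]:
    """Primer pair flanking the exon 3 / exon 4 junction of the fixture cDNA.

    Forward primer: a 20-mer inside exon 3; reverse primer: reverse
    complement of a 22-mer inside exon 4.
    """
    from Bio.Seq import Seq

    model = model or load_transcript(FIXTURE_TAG)
    genome = genome if genome is not None else simulate_reference(seed, model)
    wt = cdna_sequence(model, genome)
    _, hi = model.exon_cdna_bounds(PSEUDOEXON_INTRON)
    fwd = wt[hi - 71 : hi - 51]
    rev = str(Seq(wt[hi + 54 : hi + 76]).reverse_complement())
    return fwd, rev


# ---------------------------------------------------------------------------
# VCF output for planted small variants


def write_snv_vcf(
    path: str | Path,
    spec: CohortSpec,
    truth: TruthTable,
    model: Optional[TranscriptModel] = None,
) -> None:
    """Planted small variants as a multi-sample VCF 4.2 with trio genotypes."""
    model = model or load_transcript(FIXTURE_TAG)
    samples = spec.sample_ids()
    by_allele: dict[str, dict[str, str]] = {}
    for ev in truth.events:
        if ev.kind != "snv":
            continue
        gt = "1/1" if ev.zygosity == "hom" else "0/1"
        by_allele.setdefault(ev.allele, {})[ev.sample] = gt
    records = []
    for allele, gts in by_allele.items():
        c_notation, ref, alt, _cls = SNV_DEFS[allele]
        g = c_to_g(model, parse_c_notation(c_notation))
        records.append((g, allele, ref, alt, gts))
    records.sort()
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM},length=159138663>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for g, allele, ref, alt, gts in records:
        cols = [gts.get(s, "0/0") for s in samples]
        lines.append(
            f"{CHROM}\t{g}\t{allele}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snv_vcf(path: str | Path) -> list[dict]:
    """Parse a small-variant VCF into records with per-sample genotypes."""
    from pysam import VariantFile

    out = []
    with VariantFile(str(path)) as vf:
        for rec in vf:
            gts = {}
            for s in rec.samples:
                alleles = rec.samples[s]["GT"]
                gts[s] = sum(1 for a in alleles if a not in (0, None))
            out.append(
                {
                    "id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else None,
                    "genotypes": gts,
                }
            )
    return out


# ---------------------------------------------------------------------------
# published-table fixtures


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    paternal: Optional[str]
    maternal: Optional[str]

    def alleles(self) -> list[str]:
        return [a for a in (self.paternal, self.maternal) if a]


_PATIENTS: list[tuple[str, Optional[str], Optional[str]]] = [
    ("3310066-1", None, None),
    ("3310615-1", None, None),
    ("3312024-1", "c.279T>A", "Exons 1–3 deletion (7666 bp)"),
    ("3312051-1", None, None),
    ("3312061-1", "c.1264-6T>G", "Exons 1–3 deletion (7666 bp)"),
    ("3312177-1", "c.919-2A>G", "Exons 5–6 deletion (1845 bp)"),
    ("3312180-1", "Exons 1–3 deletion (7666 bp)", "c.1667A>G"),
    ("3312189-1", "Exons 9–10 deletion (4979 bp)", "c.1614+1G>A"),
    ("3312285-1", "Exons 5–6 deletion (1845 bp)", "Exons 5–6 deletion (1845 bp)"),
    ("3312305-1", "c.304+941C>T", "c.946G>T"),
    ("3312396-1", "c.1315G>A", "c.304+941C>T"),
    ("3312635-1", "c.2168A>G", None),
    ("3312757-1", "Exons 1–3 deletion (3152 bp)", "c.919-2A>G"),
]


def _profile(
    vid: str,
    vclass: str,
    freq: Optional[float],
    functional: Optional[str],
    counts: tuple[int, int, int],
    printed: tuple[str, ...],
    printed_class: str,
    revel: Optional[float] = None,
    ada: Optional[float] = None,
    subpop: str = "",
) -> EvidenceProfile:
    return EvidenceProfile(
        variant_id=vid,
        variant_class=vclass,
        frequency=freq,
        frequency_subpop=subpop,
        functional_level=functional,
        confirmed_in_trans=counts[0],
        homozygous=counts[1],
        phase_unknown=counts[2],
        revel=revel,
        dbscsnv_ada=ada,
        phenotype_specific=True,
        printed_criteria=printed,
        printed_classification=printed_class,
    )


def _evidence_profiles() -> list[EvidenceProfile]:
    P, LP = "Pathogenic", "Likely Pathogenic"
    return [
        _profile("c.279T>A", "missense", None, "Strong", (4, 0, 4),
                 ("PM2", "PS3", "PM3_VeryStrong", "PP4"), P),
        _profile("c.281C>T", "missense", 0.00005437, None, (1, 0, 6),
                 ("PM2", "PM3_VeryStrong", "PP3", "PP4"), P,
                 revel=0.8, subpop="East Asian"),
        _profile("c.304+941C>T", "intronic_splice", 0.00001594, "Moderate",
                 (7, 0, 0), ("PM2", "PS3_Moderate", "PM3_VeryStrong", "PP4"), P),
        _profile("c.946G>T", "nonsense", None, None, (2, 0, 6),
                 ("PVS1", "PM2", "PM3_VeryStrong", "PP4"), P),
        _profile("c.1264-6T>G", "intronic_splice", None, None, (1, 0, 0),
                 ("PM2", "PP3", "PM3", "PP4"), LP, ada=0.993789),
        _profile("c.1315G>A", "missense", 0.00002, None, (2, 0, 0),
                 ("PM2", "PM3_Strong", "PP3", "PP4"), LP, revel=0.8),
        _profile("c.1547dup", "frameshift", 0.000272, None, (2, 0, 5),
                 ("PVS1", "PM2_Supporting", "PM3_VeryStrong", "PP4"), P,
                 subpop="East Asian"),
        _profile("c.1614+1G>A", "canonical_splice", 0.00001, None, (2, 0, 0),
                 ("PVS1", "PM3", "PM2", "PP4"), P),
        _profile("c.1667A>G", "missense", 0.00001594, None, (0, 4, 2),
                 ("PM2", "PM3_Strong", "PP3", "PP4"), P, revel=0.8),
        _profile("Exons 1–3 deletion (7666 bp)", "exonic_deletion", None, None,
                 (5, 0, 0), ("PVS1", "PM2", "PM3_VeryStrong", "PP4"), P),
        _profile("Exons 1–3 deletion (3152 bp)", "exonic_deletion", None, None,
                 (1, 0, 0), ("PVS1", "PM2", "PM3", "PP4"), P),
        _profile("Exons 5–6 deletion (1845 bp)", "exonic_deletion", None, None,
                 (4, 0, 0), ("PVS1", "PM2", "PM3_VeryStrong", "PP4"), P),
        _profile("Exons 9–10 deletion (4979 bp)", "exonic_deletion", None, None,
                 (1, 0, 0), ("PVS1", "PM2", "PM3", "PP4"), P),
    ]


def build_table_fixtures() -> tuple[list[PatientRecord], list[EvidenceProfile]]:
    """The 13-proband genotype table and 13-variant evidence table.

    Structured encodings of the published cohort genotypes (paternal /
    maternal allele per proband) and the ACMG evidence supporting each
    variant. The c.2168A>G allele appears in the genotype table but has no
    evidence row; downstream code treats it as present-but-unclassified
    unless a classification is supplied.
    """
    patients = [PatientRecord(*row) for row in _PATIENTS]
    return patients, _evidence_profiles()


def table2_cohort_spec(
    panel: Optional[AmpliconPanel] = None, seed: int = 17, **kwargs
) -> CohortSpec:
    """A 13-trio cohort spec planting every allele of the genotype table."""
    panel = panel or default_panel()
    patients, _ = build_table_fixtures()
    events: list[PlantedEvent] = []
    for pat in patients:
        fam = pat.patient_id.rsplit("-", 1)[0]
        if (
            pat.paternal is not None
            and pat.paternal == pat.maternal
            and pat.paternal in DELETION_INTERVALS
        ):
            events.append(
                PlantedEvent(fam, "deletion", pat.paternal, "hom", "biparental")
            )
            continue
        for allele, origin in (
            (pat.paternal, "paternal"),
            (pat.maternal, "maternal"),
        ):
            if allele is None:
                continue
            kind = "deletion" if allele in DELETION_INTERVALS else "snv"
            events.append(PlantedEvent(fam, kind, allele, "het", origin))
    families = [p.patient_id.rsplit("-", 1)[0] for p in patients]
    return CohortSpec(
        n_trios=len(patients),
        panel=panel,
        planted_events=events,
        seed=seed,
        families=families,
        **kwargs,
    )
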
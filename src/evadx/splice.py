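"""Pseudoexon (intronic exonization) consequence prediction.

A deep intronic variant can create a splice site that turns part of an
intron — here a partial Alu element — into a novel exon spliced between its
flanking exons. This module models that event: reading-frame analysis of the
inserted segment, construction of the mutant transcript and its protein
consequence, canonical splice-dinucleotide checks, and RT-PCR product-size
prediction for the wild-type/mutant cDNA pair a heterozygous carrier yields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .genemodel import (
    CoordinateError,
    GenomicInterval,
    LocusReference,
    TranscriptModel,
    cdna_sequence,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PseudoexonEvent:
    """An exonized intronic segment.

    ``acceptor`` and ``donor`` are the genomic positions of the first and
    last included base (closed interval, + strand orientation of the locus);
    ``intron_index`` is the 1-based index of the host intron (intron i lies
    between exons i and i+1).
    """

    intron_index: int
    acceptor: int
    donor: int
    chrom: str = "chr7"

    def __post_init__(self) -> None:
        if self.donor < self.acceptor:
            raise ValueError("donor position before acceptor")

    @property
    def length(self) -> int:
        return self.donor - self.acceptor + 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.acceptor, self.donor)

    @property
    def in_frame(self) -> bool:
        return self.length % 3 == 0


@dataclass(frozen=True)
class FrameConsequence:
    in_frame: bool
    inserted_residues: Optional[int]  # length/3 when in frame and stop-free
    introduces_stop: bool

    @property
    def frameshift(self) -> bool:
        return not self.in_frame


def frame_consequence(
    length: int,
    sequence: Optional[str] = None,
    junction_phase: int = 0,
) -> FrameConsequence:
    """Reading-frame consequence of inserting ``length`` bases at a junction.

    ``junction_phase`` is the number of bases of the interrupted codon
    already emitted before the insertion point (0, 1 or 2). When a sequence
    is supplied, codons falling fully inside the insertion are scanned for
    stops in the junction frame (a stop implies premature termination and a
    nonsense-mediated-decay candidate transcript).
    """
    if length < 1:
        raise ValueError("insertion length must be >= 1")
    if junction_phase not in (0, 1, 2):
        raise ValueError("junction_phase must be 0, 1 or 2")
    in_frame = length % 3 == 0
    introduces_stop = False
    if sequence is not None:
        if len(sequence) != length:
            raise ValueError("sequence length disagrees with length argument")
        start = (3 - junction_phase) % 3
        for i in range(start, length - 2, 3):
            if sequence[i : i + 3].upper() in STOP_CODONS:
                introduces_stop = True
                break
    residues = length // 3 if in_frame and not introduces_stop else None
    return FrameConsequence(in_frame, residues, introduces_stop)


@dataclass
class SpliceCheck:
    ok: bool
    warnings: list[str]


def validate_splice_sites(
    event: PseudoexonEvent, genome: LocusReference
) -> SpliceCheck:
    """Check canonical AG acceptor / GT donor context around a pseudoexon.

    The intronic AG must end immediately 5' of the included segment and GT
    must start immediately 3' of it. Non-canonical context is a warning (the
    event may still be real), coordinates outside the genome are an error.
    """
    if not genome.covers(event.acceptor - 2, event.donor + 2):
        raise CoordinateError(
            f"pseudoexon {event.interval} +/-2 bp outside reference window"
        )
    warnings: list[str] = []
    acc = genome.subseq(event.acceptor - 2, event.acceptor - 1).upper()
    don = genome.subseq(event.donor + 1, event.donor + 2).upper()
    if acc != "AG":
        warnings.append(f"non-canonical acceptor context {acc} (expected AG)")
    if don != "GT":
        warnings.append(f"non-canonical donor context {don} (expected GT)")
    return SpliceCheck(ok=not warnings, warnings=warnings)


@dataclass
class TranscriptConsequence:
    """Mutant transcript plus its predicted protein-level consequence."""

    wildtype_cdna: str
    mutant_cdna: str
    event: PseudoexonEvent
    consequence: str  # in_frame_insertion | insertion_ptc | frameshift_ptc | frameshift_no_ptc
    inserted_residues: Optional[int]
    ptc_codon: Optional[int]  # 1-based codon index of the premature stop
    nmd_candidate: bool

    @property
    def length_difference(self) -> int:
        return len(self.mutant_cdna) - len(self.wildtype_cdna)


def _insert_index(model: TranscriptModel, intron_index: int) -> int:
    """cDNA index (0-based) at which the pseudoexon sequence is inserted."""
    _, hi = model.exon_cdna_bounds(intron_index)
    return hi  # insert after the last base of the upstream exon


def apply_pseudoexon(
    model: TranscriptModel,
    event: PseudoexonEvent,
    genome: LocusReference,
) -> TranscriptConsequence:
    """Splice a pseudoexon into the transcript and call the consequence.

    The mutant cDNA carries the event sequence between the flanking exons.
    The protein consequence is determined by brute-force translation of the
    mutant CDS: an in-frame, stop-free insertion of length/3 residues; an
    in-frame insertion carrying a premature stop; or a frameshift with the
    position of the first downstream premature termination codon.
    """
    if not 1 <= event.intron_index < model.n_exons:
        raise ValueError(f"model has no intron {event.intron_index}")
    intron = model.intron_interval(event.intron_index)
    if not intron.contains(event.interval):
        raise ValueError(
            f"pseudoexon {event.interval} not contained in intron "
            f"{event.intron_index} ({intron}); events overlapping exons are invalid"
        )
    wt = cdna_sequence(model, genome)
    ins = genome.extract(event.interval)
    if model.strand == "-":
        ins = str(Seq(ins).reverse_complement())
    k = _insert_index(model, event.intron_index)
    mut = wt[:k] + ins + wt[k:]

    wt_protein = _translate_cds(wt, model.cds_start)
    mut_protein = _translate_cds(mut, model.cds_start)
    in_frame = event.length % 3 == 0
    expected = len(wt_protein) + event.length // 3

    if in_frame and len(mut_protein) == expected:
        consequence = "in_frame_insertion"
        residues: Optional[int] = event.length // 3
        ptc: Optional[int] = None
    elif in_frame:
        consequence = "insertion_ptc"
        residues, ptc = None, len(mut_protein) + 1
    else:
        residues = None
        if len(mut_protein) * 3 + 3 <= len(mut) - model.cds_start + 1:
            consequence, ptc = "frameshift_ptc", len(mut_protein) + 1
        else:
            consequence, ptc = "frameshift_no_ptc", None
    return TranscriptConsequence(
        wildtype_cdna=wt,
        mutant_cdna=mut,
        event=event,
        consequence=consequence,
        inserted_residues=residues,
        ptc_codon=ptc,
        nmd_candidate=ptc is not None,
    )


def _translate_cds(cdna: str, cds_start: int) -> str:
    """Translate from the CDS start to the first stop (excluded)."""
    cds = cdna[cds_start - 1 :]
    cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate(to_stop=True))
    return prot


def junction_phase(model: TranscriptModel, intron_index: int) -> int:
    """Bases of the interrupted codon already emitted at the intron junction."""
    _, hi = model.exon_cdna_bounds(intron_index)
    coding_bases = hi - model.cds_start + 1
    if coding_bases < 0:
        raise ValueError("junction upstream of CDS start")
    return coding_bases % 3


def rtpcr_products(
    transcripts: dict[str, str],
    forward_primer: str,
    reverse_primer: str,
) -> dict[str, int]:
    """Predicted RT-PCR product size per transcript, in bp.

    The forward primer must match the transcript sense strand and the
    reverse primer the antisense strand (i.e. its reverse complement occurs
    in the transcript), each exactly once; the product runs from the 5' end
    of the forward site to the 5' end of the reverse site inclusive. For a
    heterozygous wild-type + pseudoexon pair the two product sizes differ by
    exactly the pseudoexon length.
    """
    fwd = forward_primer.upper()
    rev_rc = str(Seq(reverse_primer.upper()).reverse_complement())
    sizes: dict[str, int] = {}
    for name, seq in transcripts.items():
        s = seq.upper()
        for primer, label in ((fwd, "forward"), (rev_rc, "reverse")):
            n = s.count(primer)
            if n == 0:
                raise ValueError(f"{label} primer absent from transcript {name}")
            if n > 1:
                raise ValueError(
                    f"{label} primer maps {n} times in transcript {name}"
                )
        start = s.find(fwd)
        end = s.find(rev_rc) + len(rev_rc)  # one past the reverse 5' end
        if end <= start:
            raise ValueError(
                f"primer orientation inconsistent on transcript {name}"
            )
        sizes[name] = end - start
    return sizes
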
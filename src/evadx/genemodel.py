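"""Transcript/genome coordinate model for the SLC26A4 locus.

Provides the transcript model (exon structure + CDS), HGVS-style c./g.
coordinate mapping including intronic offsets (``c.304+941``), closed-interval
arithmetic, and exon-overlap queries used by the CNV and breakpoint stages.

Coordinate conventions
----------------------
Genomic positions are 1-based. The canonical interval convention is *closed*
(both endpoints included, length = end - start + 1), the norm in GRCh37
clinical reporting. A *breakpoint-exclusive* convention (length = end - start)
is representable via the ``convention`` tag because published deletion
coordinates mix both; report output emits lengths under both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "GenomicInterval",
    "CPosition",
    "TranscriptModel",
    "ExonOverlap",
    "GffParseError",
    "InvariantError",
    "CoordinateError",
    "load_transcript",
    "c_to_g",
    "g_to_c",
    "interval_length",
    "exons_overlapped",
    "FIXTURE_TAG",
]

FIXTURE_TAG = "slc26a4_fixture"


class GffParseError(ValueError):
    """Raised when a GFF3 file cannot be parsed; names the offending line."""


class InvariantError(ValueError):
    """Raised when a transcript model violates its structural invariants."""


class CoordinateError(ValueError):
    """Raised for invalid c./g. coordinate conversions."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based genomic interval.

    ``convention`` is ``"closed"`` (both ends included) or
    ``"breakpoint-exclusive"`` (length counted as ``end - start``).
    """

    chrom: str
    start: int
    end: int
    convention: str = "closed"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvariantError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.convention not in ("closed", "breakpoint-exclusive"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def length(self) -> int:
        return interval_length(self)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CPosition:
    """HGVS-style coding position: c.<exonic_base> or c.<exonic_base>±<offset>.

    ``intron_offset`` 0 means exonic; a positive offset counts into the intron
    after the donor (``c.304+941``), a negative one before the acceptor
    (``c.919-2``).
    """

    exonic_base: int
    intron_offset: int = 0

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return f"c.{self.exonic_base}"
        return f"c.{self.exonic_base}{self.intron_offset:+d}"


@dataclass(frozen=True)
class ExonOverlap:
    """Contiguous 1-based exon index range hit by an interval."""

    first_exon: int
    last_exon: int
    first_partial: bool
    last_partial: bool

    @property
    def label(self) -> str:
        if self.first_exon == self.last_exon:
            return f"Exon {self.first_exon}"
        return f"Exons {self.first_exon}–{self.last_exon}"


@dataclass
class TranscriptModel:
    """Exon structure of one transcript with CDS bounds in c. coordinates.

    Exons are listed in transcript (5'→3') order: ascending genomic
    coordinates on the + strand, descending on the − strand.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvariantError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise InvariantError("transcript has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise InvariantError("exons span multiple chromosomes")
            if self.strand == "+" and b.start <= a.end:
                raise InvariantError(
                    f"exons overlap or are unsorted: {a} then {b} on + strand"
                )
            if self.strand == "-" and b.end >= a.start:
                raise InvariantError(
                    f"exons overlap or are unsorted: {a} then {b} on - strand"
                )
        self._cum = []
        c = 1
        for ex in self.exons:
            self._cum.append(c)
            c += interval_length(ex)
        if not (1 <= self.cds_start <= self.cds_end <= self.cdna_length):
            raise InvariantError("CDS bounds outside cDNA")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise InvariantError("CDS length not divisible by 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cdna_length(self) -> int:
        last = self._cum[-1] + interval_length(self.exons[-1]) - 1
        return last

    def exon_cdna_bounds(self, i: int) -> tuple[int, int]:
        """(first, last) cDNA coordinate of 1-based exon ``i``."""
        ex = self.exons[i - 1]
        return self._cum[i - 1], self._cum[i - 1] + interval_length(ex) - 1

    def intron_length(self, i: int) -> int:
        """Length of the intron following 1-based exon ``i``."""
        if not 1 <= i < self.n_exons:
            raise CoordinateError(f"no intron after exon {i}")
        a, b = self.exons[i - 1], self.exons[i]
        if self.strand == "+":
            return b.start - a.end - 1
        return a.start - b.end - 1

    def intron_interval(self, i: int) -> GenomicInterval:
        a, b = self.exons[i - 1], self.exons[i]
        if self.strand == "+":
            return GenomicInterval(self.chrom, a.end + 1, b.start - 1)
        return GenomicInterval(self.chrom, b.end + 1, a.start - 1)


def interval_length(iv: GenomicInterval) -> int:
    """Length of an interval under its convention tag."""
    if iv.convention == "closed":
        return iv.end - iv.start + 1
    return iv.end - iv.start


def _fixture_model() -> TranscriptModel:
    ref = resources.files("evadx.data") / "slc26a4_synthetic_transcript.json"
    payload = json.loads(ref.read_text())
    exons = [
        GenomicInterval(payload["chrom"], s, e) for s, e in payload["exons"]
    ]
    return TranscriptModel(
        transcript_id=payload["transcript_id"],
        chrom=payload["chrom"],
        strand=payload["strand"],
        exons=exons,
        cds_start=payload["cds_start"],
        cds_end=payload["cds_end"],
    )


def load_transcript(source: str | Path) -> TranscriptModel:
    """Load a transcript model from a GFF3 file or the packaged fixture tag.

    ``source`` may be the tag ``"slc26a4_fixture"`` (a synthetic 21-exon
    SLC26A4-like model packaged with evadx) or a path to a GFF3 file with
    ``exon`` and ``CDS`` features for a single transcript.
    """
    if str(source) == FIXTURE_TAG:
        return _fixture_model()
    return _parse_gff3(Path(source))


def _parse_gff3(path: Path) -> TranscriptModel:
    """Minimal single-transcript GFF3 reader (exon + CDS features)."""
    exon_rows: list[tuple[str, int, int, str]] = []
    cds_rows: list[tuple[int, int]] = []
    tid = path.stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if ftype == "exon":
                exon_rows.append((chrom, start, end, strand))
            elif ftype == "CDS":
                cds_rows.append((start, end))
            for kv in attrs.split(";"):
                if kv.startswith(("transcript_id=", "Parent=")):
                    tid = kv.split("=", 1)[1]
    if not exon_rows:
        raise GffParseError(f"{path}: no exon features found")
    chroms = {r[0] for r in exon_rows}
    strands = {r[3] for r in exon_rows}
    if len(chroms) != 1 or len(strands) != 1:
        raise GffParseError(f"{path}: exons span multiple chromosomes/strands")
    chrom, strand = chroms.pop(), strands.pop()
    exon_rows.sort(key=lambda r: r[1], reverse=(strand == "-"))
    exons = [GenomicInterval(chrom, s, e) for _, s, e, _ in exon_rows]
    model = _with_cds(tid, chrom, strand, exons, cds_rows)
    return model


def _with_cds(
    tid: str,
    chrom: str,
    strand: str,
    exons: list[GenomicInterval],
    cds_rows: list[tuple[int, int]],
) -> TranscriptModel:
    # map genomic CDS extent onto cDNA coordinates; no CDS features → whole
    # transcript treated as coding (toy-model convenience)
    cdna_len = sum(e.end - e.start + 1 for e in exons)
    if not cds_rows:
        cds_start, cds_end = 1, cdna_len - (cdna_len % 3)
        if cds_end == 0:
            raise GffParseError("transcript shorter than one codon")
        model = TranscriptModel(tid, chrom, strand, exons, cds_start, cds_end)
        return model
    gmin = min(s for s, _ in cds_rows)
    gmax = max(e for _, e in cds_rows)
    model = TranscriptModel(tid, chrom, strand, exons, 1, 3)  # provisional
    c_lo = g_to_c(model, gmin)
    c_hi = g_to_c(model, gmax)
    if c_lo.intron_offset or c_hi.intron_offset:
        raise GffParseError("CDS boundary falls inside an intron")
    lo, hi = sorted((c_lo.exonic_base, c_hi.exonic_base))
    return TranscriptModel(tid, chrom, strand, exons, lo, hi)


def _locate(model: TranscriptModel, tpos: int) -> int:
    """1-based exon index containing cDNA coordinate ``tpos``."""
    if not 1 <= tpos <= model.cdna_length:
        raise CoordinateError(
            f"cDNA position {tpos} outside transcript "
            f"(length {model.cdna_length})"
        )
    for i in range(model.n_exons, 0, -1):
        if tpos >= model._cum[i - 1]:
            return i
    raise AssertionError("unreachable")


def c_to_g(model: TranscriptModel, pos: CPosition) -> int:
    """Map an HGVS c. position (with optional intronic offset) to genomic.

    Intronic offsets are only valid from an exon-boundary base and must fit
    inside the adjacent intron.
    """
    tpos = pos.exonic_base + model.cds_start - 1
    i = _locate(model, tpos)
    lo, hi = model.exon_cdna_bounds(i)
    ex = model.exons[i - 1]
    off = pos.intron_offset
    if off == 0:
        d = tpos - lo
        return ex.start + d if model.strand == "+" else ex.end - d
    if off > 0:
        if tpos != hi:
            raise CoordinateError(
                f"{pos}: +offset requires the last base of an exon "
                f"(exon {i} ends at c.{hi - model.cds_start + 1})"
            )
        if i == model.n_exons:
            raise CoordinateError(f"{pos}: no intron after the last exon")
        if off > model.intron_length(i):
            raise CoordinateError(
                f"{pos}: offset {off} exceeds intron {i} length "
                f"{model.intron_length(i)}"
            )
        return ex.end + off if model.strand == "+" else ex.start - off
    # off < 0
    if tpos != lo:
        raise CoordinateError(
            f"{pos}: -offset requires the first base of an exon "
            f"(exon {i} starts at c.{lo - model.cds_start + 1})"
        )
    if i == 1:
        raise CoordinateError(f"{pos}: no intron before the first exon")
    if -off > model.intron_length(i - 1):
        raise CoordinateError(
            f"{pos}: offset {off} exceeds intron {i - 1} length "
            f"{model.intron_length(i - 1)}"
        )
    return ex.start + off if model.strand == "+" else ex.end - off


def g_to_c(model: TranscriptModel, gpos: int) -> CPosition:
    """Map a genomic position to its nearest-exon HGVS c. representation.

    Intronic positions anchor to the closer exon boundary (donor side wins
    ties), the standard HGVS convention.
    """

    def to_c(tpos: int, off: int = 0) -> CPosition:
        return CPosition(tpos - model.cds_start + 1, off)

    for i, ex in enumerate(model.exons, start=1):
        if ex.start <= gpos <= ex.end:
            lo, _ = model.exon_cdna_bounds(i)
            d = gpos - ex.start if model.strand == "+" else ex.end - gpos
            return to_c(lo + d)
    for i in range(1, model.n_exons):
        intron = model.intron_interval(i)
        if intron.start <= gpos <= intron.end:
            up, down = model.exons[i - 1], model.exons[i]
            if model.strand == "+":
                d_don = gpos - up.end
                d_acc = down.start - gpos
            else:
                d_don = up.start - gpos
                d_acc = gpos - down.end
            _, hi_up = model.exon_cdna_bounds(i)
            lo_down, _ = model.exon_cdna_bounds(i + 1)
            if d_don <= d_acc:
                return to_c(hi_up, d_don)
            return to_c(lo_down, -d_acc)
    raise CoordinateError(
        f"genomic position {gpos} outside transcript span of "
        f"{model.transcript_id}"
    )


def exons_overlapped(
    model: TranscriptModel, iv: GenomicInterval
) -> Optional[ExonOverlap]:
    """Exon index range overlapped by a genomic interval, with partial flags.

    Returns ``None`` when the interval misses every exon (e.g. intergenic or
    fully intronic). The result is strand-agnostic: indices are transcript
    exon numbers regardless of genomic orientation of the query.
    """
    if iv.chrom != model.chrom:
        return None
    hit: list[int] = []
    partial: dict[int, bool] = {}
    for i, ex in enumerate(model.exons, start=1):
        if ex.overlaps(iv):
            hit.append(i)
            partial[i] = not iv.contains(ex)
    if not hit:
        return None
    first, last = min(hit), max(hit)
    if hit != list(range(first, last + 1)):
        # cannot happen for sorted non-overlapping exons and one interval
        raise AssertionError("non-contiguous exon overlap")
    return ExonOverlap(first, last, partial[first], partial[last])


@dataclass
class LocusReference:
    """A reference sequence window anchored to genomic coordinates.

    ``offset`` is the 1-based genomic position of ``seq[0]``; lookups and
    slices use genomic coordinates (closed intervals).
    """

    chrom: str
    offset: int
    seq: str

    @property
    def end(self) -> int:
        return self.offset + len(self.seq) - 1

    def covers(self, start: int, end: int) -> bool:
        return self.offset <= start and end <= self.end

    def base(self, gpos: int) -> str:
        if not self.covers(gpos, gpos):
            raise CoordinateError(
                f"position {gpos} outside reference window "
                f"{self.chrom}:{self.offset}-{self.end}"
            )
        return self.seq[gpos - self.offset]

    def subseq(self, start: int, end: int) -> str:
        """Closed-interval genomic slice."""
        if not self.covers(start, end):
            raise CoordinateError(
                f"{self.chrom}:{start}-{end} outside reference window "
                f"{self.chrom}:{self.offset}-{self.end}"
            )
        return self.seq[start - self.offset : end - self.offset + 1]

    def extract(self, iv: GenomicInterval) -> str:
        return self.subseq(iv.start, iv.end)

    def without(self, iv: GenomicInterval) -> str:
        """Sequence of the haplotype carrying ``iv`` as a deletion."""
        if not self.covers(iv.start, iv.end):
            raise CoordinateError(f"deletion {iv} outside reference window")
        return (
            self.seq[: iv.start - self.offset]
            + self.seq[iv.end - self.offset + 1 :]
        )


def cdna_sequence(model: TranscriptModel, genome: LocusReference) -> str:
    """Wild-type cDNA: exon sequences concatenated in transcript order."""
    from Bio.Seq import Seq

    parts = []
    for ex in model.exons:
        s = genome.extract(ex)
        if model.strand == "-":
            s = str(Seq(s).reverse_complement())
        parts.append(s)
    return "".join(parts)


def parse_c_notation(text: str) -> CPosition:
    """Parse ``c.N``, ``c.N+M`` or ``c.N-M`` (position part only)."""
    body = text[2:] if text.startswith("c.") else text
    for sign in ("+", "-"):
        # search from index 1 so a leading '-' of rare upstream notation
        # would not split; upstream positions are out of scope anyway
        k = body.find(sign, 1)
        if k != -1:
            return CPosition(int(body[:k]), int(body[k:]))
    return CPosition(int(body))
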
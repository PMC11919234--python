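"""Deletion breakpoint resolution from long reads over a locus.

Each read is decomposed into a reference prefix and suffix segment via exact
k-mer seed anchoring with bounded-mismatch split refinement (substitution
errors only — no affine gap alignment). A read whose two anchors are
colinear with a reference gap and no read gap yields a breakpoint candidate;
microhomology at the junction makes the split ambiguous, and candidates are
left-aligned (lowest deleted coordinates), matching VCF normalisation
practice. A consensus call aggregates concordant candidates and reports the
deletion length under both the closed and the breakpoint-exclusive
conventions, since published coordinate pairs mix the two.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genemodel import GenomicInterval, LocusReference

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 30
DEFAULT_SEED_K = 20
DEFAULT_MAX_MISMATCH_RATE = 0.02


@dataclass(frozen=True)
class BreakpointCandidate:
    """A per-read deletion candidate, left-aligned across microhomology."""

    read_id: str
    left_flank_end: int  # genomic position of last matched base before gap
    right_flank_start: int  # genomic position of first matched base after gap
    deleted: GenomicInterval  # closed interval of deleted bases
    microhomology: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.deleted.length < 1:
            raise ValueError("deleted length must be >= 1")


def _find_seed(read: str, ref: str, k: int, from_end: bool) -> Optional[int]:
    """Reference index aligned to read[0] (or read[-1] - (L-1) shift).

    Scans read k-mers from the chosen end until one hits the reference
    exactly; returns the implied reference index of the read's first base.
    """
    L = len(read)
    span = range(L - k, -1, -1) if from_end else range(0, L - k + 1)
    for j in span:
        pos = ref.rfind(read[j : j + k]) if from_end else ref.find(read[j : j + k])
        if pos != -1:
            return pos - j
    return None


def find_gap(
    read: str,
    reference: str | LocusReference,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    seed_k: int = DEFAULT_SEED_K,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "read",
) -> Optional[BreakpointCandidate]:
    """Locate a single deletion junction within one read, or ``None``.

    Returns ``None`` for fully matching reads (no deletion spanned), for
    reads whose anchors are shorter than ``min_anchor``, and for reads whose
    best split exceeds the mismatch budget (the reason is logged).
    """
    if isinstance(reference, LocusReference):
        offset, ref, chrom = reference.offset, reference.seq, reference.chrom
    else:
        offset, ref, chrom = 1, reference, "ref"
    read = read.upper()
    ref = ref.upper()
    L = len(read)
    if L == 0 or not ref:
        raise ValueError("read and reference must be non-empty")
    if L < 2 * min_anchor:
        logger.debug("%s: read shorter than two anchors", read_id)
        return None
    p = _find_seed(read, ref, seed_k, from_end=False)
    q_start = _find_seed(read, ref, seed_k, from_end=True)
    if p is None or q_start is None:
        logger.debug("%s: no exact %d-mer anchor found", read_id, seed_k)
        return None
    if p < 0 or q_start + L > len(ref):
        logger.debug("%s: anchor extends past reference edge", read_id)
        return None
    gap = q_start - p  # reference bases skipped between the two alignments
    if gap <= 0:
        return None  # fully matching read (or non-deletion structure)

    r = np.frombuffer(read.encode(), dtype=np.uint8)
    a = np.frombuffer(ref.encode(), dtype=np.uint8)
    pre_mm = np.concatenate(([0], np.cumsum(r != a[p : p + L])))
    suf_arr = r != a[q_start : q_start + L]
    suf_mm = np.concatenate(([0], np.cumsum(suf_arr[::-1])))[::-1]
    # total[i]: mismatches with a prefix of length i and suffix read[i:]
    total = pre_mm + suf_mm  # i = 0..L
    lo, hi = min_anchor, L - min_anchor  # allowed prefix lengths
    window = total[lo : hi + 1]
    if window.size == 0:
        logger.debug("%s: anchors shorter than min_anchor=%d", read_id, min_anchor)
        return None
    best = int(window.min())
    if best > max_mismatch_rate * L:
        logger.debug(
            "%s: best split has %d mismatches (> %.0f%% of %d bp)",
            read_id,
            best,
            100 * max_mismatch_rate,
            L,
        )
        return None
    rel = int(np.argmin(window))  # leftmost minimum -> left-aligned deletion
    i = lo + rel  # read prefix length
    run = 0
    while rel + run + 1 < window.size and window[rel + run + 1] == best:
        run += 1
    del_start0 = p + i  # 0-based first deleted reference base
    deleted = GenomicInterval(
        chrom, del_start0 + offset, del_start0 + gap - 1 + offset
    )
    return BreakpointCandidate(
        read_id=read_id,
        left_flank_end=del_start0 - 1 + offset,
        right_flank_start=del_start0 + gap + offset,
        deleted=deleted,
        microhomology=run,
        mismatches=best,
    )


class ConsensusTieError(ValueError):
    """Two breakpoint intervals are supported by equally many reads."""


@dataclass
class ConsensusCall:
    deleted: GenomicInterval
    length_closed: int
    length_exclusive: int  # end - start of the flanking-base coordinate pair
    support: int
    n_candidates: int
    discordant: list[BreakpointCandidate]

    @property
    def flanking_pair(self) -> tuple[int, int]:
        """(last retained base before, first retained base after) the gap."""
        return (self.deleted.start - 1, self.deleted.end + 1)


def consensus(candidates: Sequence[BreakpointCandidate]) -> ConsensusCall:
    """Modal left-aligned deletion interval over per-read candidates.

    Raises :class:`ConsensusTieError` when two intervals tie for the mode
    (no silent choice); discordant reads are reported alongside the call.
    """
    if not candidates:
        raise ValueError("no breakpoint candidates supplied")
    counts = Counter((c.deleted.chrom, c.deleted.start, c.deleted.end) for c in candidates)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        a, b = ranked[0][0], ranked[1][0]
        raise ConsensusTieError(
            f"tie between {a[0]}:{a[1]}-{a[2]} and {b[0]}:{b[1]}-{b[2]} "
            f"({ranked[0][1]} reads each)"
        )
    (chrom, start, end), support = ranked[0]
    modal = GenomicInterval(chrom, start, end)
    discordant = [
        c
        for c in candidates
        if (c.deleted.chrom, c.deleted.start, c.deleted.end) != (chrom, start, end)
    ]
    return ConsensusCall(
        deleted=modal,
        length_closed=modal.length,
        length_exclusive=(end + 1) - (start - 1),
        support=support,
        n_candidates=len(candidates),
        discordant=discordant,
    )


@dataclass
class VcfDeletion:
    chrom: str
    pos: int
    ref: str
    alt: str
    svlen: int
    symbolic: bool
    end: int

    def line(self) -> str:
        info = f"SVTYPE=DEL;END={self.end};SVLEN={self.svlen}"
        return f"{self.chrom}\t{self.pos}\t.\t{self.ref}\t{self.alt}\t.\tPASS\t{info}"


def to_vcf(call: ConsensusCall, reference: LocusReference) -> VcfDeletion:
    """Sequence-resolved VCF deletion record for a consensus call.

    POS is the base before the deletion; REF is that base plus the deleted
    sequence; ALT is the anchor base. A deletion starting at the contig
    start has no left anchor and falls back to a symbolic ``<DEL>`` record.
    """
    d = call.deleted
    if d.start <= reference.offset:
        return VcfDeletion(
            chrom=d.chrom,
            pos=d.start,
            ref=reference.base(d.start),
            alt="<DEL>",
            svlen=-call.length_closed,
            symbolic=True,
            end=d.end,
        )
    anchor = reference.base(d.start - 1)
    return VcfDeletion(
        chrom=d.chrom,
        pos=d.start - 1,
        ref=anchor + reference.subseq(d.start, d.end),
        alt=anchor,
        svlen=-call.length_closed,
        symbolic=False,
        end=d.end,
    )


def write_vcf(
    records: Sequence[VcfDeletion], path: str | Path, contig_length: int = 200_000_000
) -> None:
    chroms = sorted({r.chrom for r in records})
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    ]
    lines += [f"##contig=<ID={c},length={contig_length}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines += [r.line() for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidates_tsv(
    candidates: Sequence[BreakpointCandidate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tchrom\tdel_start\tdel_end\tlength\t"
            "microhomology\tmismatches\n"
        )
        for c in candidates:
            d = c.deleted
            fh.write(
                f"{c.read_id}\t{d.chrom}\t{d.start}\t{d.end}\t{d.length}\t"
                f"{c.microhomology}\t{c.mismatches}\n"
            )


def resolve_deletion(
    reads: Sequence[tuple[str, str]],
    reference: LocusReference,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> tuple[ConsensusCall, list[BreakpointCandidate]]:
    """find_gap over all reads, then consensus over the candidates."""
    candidates = [
        c
        for rid, seq in reads
        if (c := find_gap(seq, reference, min_anchor=min_anchor, read_id=rid))
        is not None
    ]
    return consensus(candidates), candidates
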
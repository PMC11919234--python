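"""Amplicon read-depth CNV analysis for a multiplex-PCR panel.

The method: per-sample mean depths over each amplified region are normalised
to a fixed total data amount (10 Mbp by default), compared across the cohort
as per-amplicon ratios against a reference profile (cohort median by
default), thresholded into copy-number states with a robust z-score gate,
segmented into exon-range calls, and annotated with trio inheritance.

Thresholds default to midpoints between copy-number expectations
(ratio 0.5 for one copy, 1.0 for two, 1.5 for three): CN0 < 0.2,
CN1 in [0.2, 0.7), CN2 in [0.7, 1.3), CN>=3 at >= 1.3, with non-diploid
states additionally requiring |z| >= 3 against the cohort spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genemodel import (
    ExonOverlap,
    GenomicInterval,
    TranscriptModel,
    exons_overlapped,
)
from .pedigree import Pedigree

CN0, CN1, CN2, CN3 = "CN0", "CN1", "CN2", "CN>=3"
_STATES = (CN0, CN1, CN2, CN3)

#: paternal/maternal/de-novo annotation values
INHERITANCES = ("paternal", "maternal", "de_novo", "homozygous_biparental", "unknown")


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    interval: GenomicInterval
    exon_label: str

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class AmpliconPanel:
    """Ordered list of amplified regions tiling the transcript's exons."""

    amplicons: list[Amplicon]

    def __post_init__(self) -> None:
        ivs = [a.interval for a in self.amplicons]
        for a, b in zip(ivs, ivs[1:]):
            if (a.chrom, a.start) > (b.chrom, b.start):
                raise ValueError("panel amplicons must be coordinate-sorted")

    @property
    def ids(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons]

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(
            [a.length for a in self.amplicons], index=self.ids, name="length"
        )

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def overlapping(self, iv: GenomicInterval) -> list[str]:
        return [a.amplicon_id for a in self.amplicons if a.interval.overlaps(iv)]

    def covers_all_exons(self, model: TranscriptModel) -> bool:
        return all(
            any(a.interval.overlaps(ex) for a in self.amplicons)
            for ex in model.exons
        )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a in self.amplicons:
                iv = a.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                    f"{a.amplicon_id}\t0\t+\t{a.exon_label}\n"
                )

    @classmethod
    def read_bed(cls, path: str | Path) -> "AmpliconPanel":
        amps = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start0, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start0 + 1}-{end}"
                label = f[6] if len(f) > 6 else ""
                amps.append(
                    Amplicon(name, GenomicInterval(chrom, start0 + 1, end), label)
                )
        return cls(amps)


@dataclass
class DepthMatrix:
    """Samples x amplicons mean-depth table with amplicon lengths."""

    depth: pd.DataFrame  # rows: samples, columns: amplicon ids
    lengths: pd.Series  # indexed by amplicon id, bp

    def __post_init__(self) -> None:
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("negative depths")
        if list(self.depth.columns) != list(self.lengths.index):
            raise ValueError("depth columns inconsistent with amplicon lengths")

    @property
    def samples(self) -> list[str]:
        return list(self.depth.index)

    @property
    def amplicons(self) -> list[str]:
        return list(self.depth.columns)

    def total_bases(self) -> pd.Series:
        """Per-sample total data amount: sum of depth x amplicon length."""
        return (self.depth * self.lengths).sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.depth.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path, panel: AmpliconPanel) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df[panel.ids], panel.lengths)


@dataclass
class RatioResult:
    ratios: pd.DataFrame
    z: pd.DataFrame
    reference: pd.Series
    masked: list[str]


@dataclass
class CnvCall:
    """A contiguous-amplicon copy-number call at exon-range resolution."""

    sample: str
    interval: GenomicInterval
    exon_range: Optional[ExonOverlap]
    state: str
    mean_ratio: float
    z: float
    n_amplicons: int
    amplicon_ids: tuple[str, ...]
    low_confidence: bool = False
    inheritance: str = "unknown"

    @property
    def exon_label(self) -> str:
        return self.exon_range.label if self.exon_range else "intergenic"


def normalize(dm: DepthMatrix, target_total: float = 1e7) -> DepthMatrix:
    """Scale each sample so its total data amount equals ``target_total`` bp.

    Mirrors the panel normalisation that assumes a fixed 10 Mbp of data per
    sample, removing per-sample throughput differences before comparison.
    """
    totals = dm.total_bases()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total depth: {', '.join(zero.index)}"
        )
    scaled = dm.depth.mul(target_total / totals, axis=0)
    return DepthMatrix(scaled, dm.lengths)


def ratios(
    norm_dm: DepthMatrix, reference: Optional[pd.Series] = None
) -> RatioResult:
    """Per-amplicon depth ratios against a reference profile, with robust z.

    ``reference`` defaults to the cohort median depth per amplicon (requires
    >= 3 samples). Amplicons whose reference is zero are masked (NaN ratios)
    and reported in ``masked`` rather than silently dropped. z-scores use
    1.4826 x MAD across samples; an amplicon with zero spread gets z = 0 for
    on-median samples and +/-inf otherwise.
    """
    depth = norm_dm.depth
    if reference is None:
        if len(depth) < 3:
            raise ValueError("cohort-median reference requires >= 3 samples")
        reference = depth.median(axis=0)
    reference = reference.reindex(depth.columns)
    masked = list(reference.index[(reference <= 0) | reference.isna()])
    ref_safe = reference.where(reference > 0)
    r = depth.div(ref_safe, axis=1)
    # median-of-ratios recentering: fixed-total normalisation inflates every
    # ratio of a deletion carrier (its denominator lost the deleted bases);
    # dividing by the per-sample median ratio removes that shift as long as
    # fewer than half of the amplicons are affected
    sample_med = r.median(axis=1)
    r = r.div(sample_med.where(sample_med > 0, 1.0), axis=0)
    med = r.median(axis=0)
    dev = r.sub(med, axis=1)
    mad = (r - med).abs().median(axis=0)
    scale = 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev.div(scale, axis=1)
    z = z.where(dev != 0, 0.0)
    return RatioResult(ratios=r, z=z, reference=reference, masked=masked)


DEFAULT_THRESHOLDS = (0.2, 0.7, 1.3)


@dataclass
class StateResult:
    """Per-amplicon states before and after the z-gate.

    ``raw`` holds the ratio-implied state; ``states`` the gated state (a
    non-CN2 raw state whose |z| misses ``min_z`` is downgraded to CN2 and
    flagged in ``suspect``). Segmentation uses the raw states but only emits
    runs containing gate-passing evidence, so a single underpowered amplicon
    inside a real event does not split the call.
    """

    states: pd.DataFrame
    raw: pd.DataFrame
    suspect: pd.DataFrame


def call_states(
    rr: RatioResult,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_z: float = 3.0,
) -> StateResult:
    """Threshold ratios into per-amplicon copy-number states.

    ``thresholds`` are the strictly increasing cut points (CN0 upper bound,
    CN1 upper bound, CN>=3 lower bound). A non-diploid state whose |z| falls
    below ``min_z`` is downgraded to CN2 and flagged suspect; masked
    amplicons are CN2 + suspect.
    """
    t0, t1, t2 = thresholds
    if not t0 < t1 < t2:
        raise ValueError("thresholds must be strictly increasing")
    r, z = rr.ratios, rr.z
    raw = pd.DataFrame(CN2, index=r.index, columns=r.columns)
    raw = raw.mask(r < t1, CN1).mask(r < t0, CN0).mask(r >= t2, CN3)
    gate = z.abs() >= min_z
    passed = raw.where((raw == CN2) | gate, CN2)
    suspect = (raw != CN2) & ~gate
    nan = r.isna()
    states = passed.mask(nan, CN2)
    raw = raw.mask(nan, CN2)
    suspect = suspect | nan
    return StateResult(states=states, raw=raw, suspect=suspect)


def segment(
    states: StateResult | pd.DataFrame,
    panel: AmpliconPanel,
    model: TranscriptModel,
    rr: Optional[RatioResult] = None,
) -> list[CnvCall]:
    """Merge maximal runs of adjacent same-state non-CN2 amplicons per sample.

    Runs are formed over the ratio-implied (raw) states; a run is emitted
    only if at least one member amplicon passed the z-gate, so isolated
    suspect amplicons yield no call while a suspect amplicon embedded in a
    gate-passing run is absorbed. Single-amplicon calls are flagged
    low-confidence. The call interval spans the member amplicons; the exon
    range comes from the transcript model.
    """
    if isinstance(states, pd.DataFrame):
        states = StateResult(states=states, raw=states, suspect=states != states)
    order = panel.ids
    calls: list[CnvCall] = []
    for sample in states.raw.index:
        row = states.raw.loc[sample]
        gated = states.states.loc[sample]
        i = 0
        while i < len(order):
            st = row[order[i]]
            if st == CN2:
                i += 1
                continue
            j = i
            while j + 1 < len(order) and row[order[j + 1]] == st:
                j += 1
            members = order[i : j + 1]
            if not any(gated[a] == st for a in members):
                i = j + 1  # all-suspect run: no gate-passing evidence
                continue
            ivs = [panel[a].interval for a in members]
            interval = GenomicInterval(
                ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)
            )
            if rr is not None:
                mean_ratio = float(rr.ratios.loc[sample, members].mean())
                zval = float(rr.z.loc[sample, members].mean())
            else:
                mean_ratio, zval = math.nan, math.nan
            calls.append(
                CnvCall(
                    sample=sample,
                    interval=interval,
                    exon_range=exons_overlapped(model, interval),
                    state=st,
                    mean_ratio=mean_ratio,
                    z=zval,
                    n_amplicons=len(members),
                    amplicon_ids=tuple(members),
                    low_confidence=len(members) == 1,
                )
            )
            i = j + 1
    return calls


def _range_key(call: CnvCall) -> tuple:
    er = call.exon_range
    if er is None:
        return (call.interval.start, call.interval.end)
    return (er.first_exon, er.last_exon)


def annotate_inheritance(
    calls: list[CnvCall], pedigree: Pedigree
) -> list[CnvCall]:
    """Assign trio inheritance to each proband call.

    A child CN1 call matching a parental CN1 call over the same exon range is
    paternal/maternal; child CN0 with both parents CN1 over that range is
    homozygous_biparental; a call with genotyped parents but no parental
    support is de_novo; missing parents leave inheritance unknown.
    """
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    present = set(by_sample)
    for c in calls:
        for s in (c.sample,):
            present.add(s)
    out: list[CnvCall] = []
    probands = set(pedigree.probands())
    genotyped = set(pedigree.samples())
    for call in calls:
        if call.sample not in probands:
            out.append(call)
            continue
        father, mother = pedigree.parents(call.sample)
        if father is None or mother is None:
            out.append(replace(call, inheritance="unknown"))
            continue

        def carrier(parent: Optional[str]) -> bool:
            if parent is None:
                return False
            return any(
                c.state in (CN0, CN1) and _range_key(c) == _range_key(call)
                for c in by_sample.get(parent, [])
            )

        pat, mat = carrier(father), carrier(mother)
        if call.state == CN0 and pat and mat:
            inh = "homozygous_biparental"
        elif pat and not mat:
            inh = "paternal"
        elif mat and not pat:
            inh = "maternal"
        elif not pat and not mat:
            inh = (
                "de_novo"
                if father in genotyped and mother in genotyped
                else "unknown"
            )
        else:
            inh = "unknown"
        out.append(replace(call, inheritance=inh))
    return out


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample": c.sample,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "exons": c.exon_label,
                "state": c.state,
                "mean_ratio": c.mean_ratio,
                "z": c.z,
                "n_amplicons": c.n_amplicons,
                "low_confidence": c.low_confidence,
                "inheritance": c.inheritance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "start",
            "end",
            "exons",
            "state",
            "mean_ratio",
            "z",
            "n_amplicons",
            "low_confidence",
            "inheritance",
        ],
    )


def write_calls_tsv(calls: list[CnvCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_calls_vcf(
    calls: list[CnvCall], path: str | Path, contig_length: int = 200_000_000
) -> None:
    """Symbolic VCF 4.2 records (SVTYPE=DEL/DUP, END, per-call CN FORMAT)."""
    cn_of = {CN0: 0, CN1: 1, CN3: 3}
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
    ]
    chroms = sorted({c.interval.chrom for c in calls})
    for ch in chroms:
        lines.append(f"##contig=<ID={ch},length={contig_length}>")
    samples = sorted({c.sample for c in calls})
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for c in calls:
        if c.state == CN2:
            continue
        svtype = "DUP" if c.state == CN3 else "DEL"
        svlen = c.interval.length if svtype == "DUP" else -c.interval.length
        info = f"SVTYPE={svtype};END={c.interval.end};SVLEN={svlen}"
        fmt = []
        for s in samples:
            fmt.append(str(cn_of[c.state]) if s == c.sample else ".")
        lines.append(
            f"{c.interval.chrom}\t{c.interval.start}\t.\tN\t<{svtype}>\t.\t"
            f"PASS\t{info}\tCN\t" + "\t".join(fmt)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def call_cnvs(
    dm: DepthMatrix,
    panel: AmpliconPanel,
    model: TranscriptModel,
    pedigree: Optional[Pedigree] = None,
    target_total: float = 1e7,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_z: float = 3.0,
    reference: Optional[pd.Series] = None,
) -> tuple[list[CnvCall], RatioResult]:
    """End-to-end convenience: normalize -> ratios -> states -> segment."""
    norm = normalize(dm, target_total)
    rr = ratios(norm, reference)
    sr = call_states(rr, thresholds, min_z)
    calls = segment(sr, panel, model, rr)
    if pedigree is not None:
        calls = annotate_inheritance(calls, pedigree)
    return calls, rr
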
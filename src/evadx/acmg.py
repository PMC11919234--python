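"""ACMG/AMP variant classification specialised for hearing-loss evidence.

Implements the pathogenic-side criteria used for SLC26A4 diagnostics —
PVS1 (null variant, loss-of-function mechanism), PS3 (functional studies,
strength-modifiable), PM2 (population rarity, with a Supporting tier),
PM3 (in-trans observations in a recessive disorder, point-scaled per the
ClinGen SVI scheme), PP3 (computational evidence: REVEL for missense,
dbscSNV ADA for splice-region) and PP4 (phenotype specificity) — plus the
standard ACMG combining rules over effective strengths.

Benign-side criteria are not implemented; the classification floor is VUS.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Strength",
    "Criterion",
    "EvidenceProfile",
    "Classification",
    "pm3_strength",
    "pm2_check",
    "structural_criteria",
    "evaluate_profile",
    "combine",
    "classify_table",
    "parse_criterion",
]


class Strength(enum.IntEnum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 4
    VERY_STRONG = 8

    @property
    def label(self) -> str:
        return {
            Strength.SUPPORTING: "Supporting",
            Strength.MODERATE: "Moderate",
            Strength.STRONG: "Strong",
            Strength.VERY_STRONG: "VeryStrong",
        }[self]


_DEFAULT_BY_PREFIX = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
}


def default_strength(code: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP"):
        if code.startswith(prefix):
            return _DEFAULT_BY_PREFIX[prefix]
    raise ValueError(f"unrecognised criterion code {code!r}")


@dataclass(frozen=True)
class Criterion:
    """One evidence criterion applied at an effective strength."""

    code: str
    strength: Optional[Strength] = None  # None -> default for the code prefix
    rationale: str = ""

    @property
    def effective_strength(self) -> Strength:
        return self.strength if self.strength is not None else default_strength(self.code)

    @property
    def label(self) -> str:
        if self.effective_strength == default_strength(self.code):
            return self.code
        return f"{self.code}_{self.effective_strength.label}"

    def __str__(self) -> str:
        return self.label


_LABEL_TO_STRENGTH = {s.label: s for s in Strength}


def parse_criterion(text: str) -> Criterion:
    """Parse labels like ``PM3_VeryStrong`` or ``PVS1``."""
    if "_" in text:
        code, mod = text.split("_", 1)
        if mod not in _LABEL_TO_STRENGTH:
            raise ValueError(f"unknown strength modifier {mod!r}")
        return Criterion(code, _LABEL_TO_STRENGTH[mod])
    return Criterion(text)


class Classification(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    VUS = "VUS"

    @property
    def rank(self) -> int:
        return {"VUS": 0, "Likely Pathogenic": 1, "Pathogenic": 2}[self.value]


NULL_CLASSES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "exonic_deletion"}
)
VARIANT_CLASSES = NULL_CLASSES | {"missense", "intronic_splice", "synonymous"}


@dataclass
class EvidenceProfile:
    """Structured evidence for one variant (one Table-style row)."""

    variant_id: str
    variant_class: str
    frequency: Optional[float] = None  # None = absent from population data
    frequency_subpop: str = ""
    functional_level: Optional[str] = None  # e.g. "Strong", "Moderate"
    confirmed_in_trans: int = 0
    homozygous: int = 0
    phase_unknown: int = 0
    revel: Optional[float] = None
    dbscsnv_ada: Optional[float] = None
    phenotype_specific: bool = False
    printed_criteria: tuple[str, ...] = ()
    printed_classification: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        for n in (self.confirmed_in_trans, self.homozygous, self.phase_unknown):
            if n < 0:
                raise ValueError("observation counts must be >= 0")
        if self.frequency is not None and not 0 <= self.frequency <= 1:
            raise ValueError("frequency must be in [0, 1] or None (absent)")


# ClinGen SVI point scale for in-trans observations
PM3_WEIGHTS = {"confirmed": 1.0, "homozygous": 0.5, "phase_unknown": 0.5}
PM3_THRESHOLDS = (
    (4.0, Strength.VERY_STRONG),
    (2.0, Strength.STRONG),
    (1.0, Strength.MODERATE),
    (0.5, Strength.SUPPORTING),
)


def pm3_strength(
    confirmed_in_trans: int,
    homozygous: int = 0,
    phase_unknown: int = 0,
    weights: dict[str, float] = PM3_WEIGHTS,
    thresholds: Sequence[tuple[float, Strength]] = PM3_THRESHOLDS,
) -> tuple[float, Optional[Strength]]:
    """Point-scaled PM3: in-trans observations in a recessive disorder.

    Points = 1.0 per confirmed-in-trans observation, 0.5 per homozygous
    observation, 0.5 per phase-unknown observation; strength escalates at
    0.5 (Supporting), 1 (Moderate), 2 (Strong), 4 (VeryStrong) points.
    No per-variant cap is applied to phase-unknown points.
    """
    if min(confirmed_in_trans, homozygous, phase_unknown) < 0:
        raise ValueError("counts must be >= 0")
    points = (
        weights["confirmed"] * confirmed_in_trans
        + weights["homozygous"] * homozygous
        + weights["phase_unknown"] * phase_unknown
    )
    for cut, strength in thresholds:
        if points >= cut:
            return points, strength
    return points, None


def pm2_check(
    freq: Optional[float],
    subpop_threshold: float = 7e-5,
    supporting_threshold: float = 7e-4,
) -> Optional[Criterion]:
    """PM2 per the hearing-loss frequency cut-offs.

    Absent, or below 7e-5 in the relevant (sub)population → PM2 at Moderate;
    below 7e-4 → PM2_Supporting; otherwise no criterion.
    """
    if not subpop_threshold < supporting_threshold:
        raise ValueError("thresholds must be increasing")
    if freq is None:
        return Criterion("PM2", rationale="absent from population databases")
    if freq < 0:
        raise ValueError("negative allele frequency")
    if freq < subpop_threshold:
        return Criterion(
            "PM2", rationale=f"allele frequency {freq:g} < {subpop_threshold:g}"
        )
    if freq < supporting_threshold:
        return Criterion(
            "PM2",
            Strength.SUPPORTING,
            rationale=f"allele frequency {freq:g} < {supporting_threshold:g}",
        )
    return None


REVEL_THRESHOLD = 0.7
ADA_THRESHOLD = 0.957


def structural_criteria(profile: EvidenceProfile) -> list[Criterion]:
    """Criteria read directly off the evidence profile (PVS1/PS3/PP3/PP4)."""
    crits: list[Criterion] = []
    if profile.variant_class in NULL_CLASSES:
        crits.append(
            Criterion(
                "PVS1",
                rationale="null variant in a gene where LOF is an "
                "established disease mechanism",
            )
        )
        if profile.revel is not None:
            _warnings.warn(
                f"{profile.variant_id}: REVEL score supplied for a "
                f"{profile.variant_class} variant; ignored",
                stacklevel=2,
            )
    if profile.functional_level is not None:
        strength = _LABEL_TO_STRENGTH[profile.functional_level]
        crits.append(
            Criterion("PS3", strength, rationale="validated functional studies")
        )
    if (
        profile.variant_class == "missense"
        and profile.revel is not None
        and profile.revel > REVEL_THRESHOLD
    ):
        crits.append(
            Criterion("PP3", rationale=f"REVEL score {profile.revel} > {REVEL_THRESHOLD}")
        )
    if (
        profile.variant_class == "intronic_splice"
        and profile.dbscsnv_ada is not None
        and profile.dbscsnv_ada > ADA_THRESHOLD
    ):
        crits.append(
            Criterion(
                "PP3",
                rationale=f"dbscSNV ADA score {profile.dbscsnv_ada} > {ADA_THRESHOLD}",
            )
        )
    if profile.phenotype_specific:
        crits.append(
            Criterion("PP4", rationale="phenotype highly specific for the gene")
        )
    return crits


def evaluate_profile(profile: EvidenceProfile) -> list[Criterion]:
    """Full criterion set for a profile: structural + PM2 + point-scaled PM3."""
    crits = structural_criteria(profile)
    pm2 = pm2_check(profile.frequency)
    if pm2 is not None:
        crits.append(pm2)
    points, strength = pm3_strength(
        profile.confirmed_in_trans, profile.homozygous, profile.phase_unknown
    )
    if strength is not None:
        crits.append(
            Criterion("PM3", strength, rationale=f"{points:g} in-trans points")
        )
    return crits


def combine(criteria: Iterable[Criterion]) -> Classification:
    """Combine pathogenic-side criteria at effective strengths.

    Standard ACMG combining rules; counting uses >= semantics so adding or
    upgrading evidence can never lower the verdict.
    """
    crits = list(criteria)
    codes = [c.code for c in crits]
    if len(codes) != len(set(codes)):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate criterion code(s): {', '.join(dup)}")
    vs = sum(c.effective_strength == Strength.VERY_STRONG for c in crits)
    s = sum(c.effective_strength == Strength.STRONG for c in crits)
    m = sum(c.effective_strength == Strength.MODERATE for c in crits)
    p = sum(c.effective_strength == Strength.SUPPORTING for c in crits)

    pathogenic = (
        vs >= 2
        or (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    if pathogenic:
        return Classification.PATHOGENIC
    likely = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    if likely:
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


def classify_profile(profile: EvidenceProfile) -> Classification:
    return combine(evaluate_profile(profile))


def classify_table(profiles: Sequence[EvidenceProfile]) -> pd.DataFrame:
    """Classify every profile and report concordance with printed verdicts.

    Discrepancies with a printed classification are flagged, never
    overridden: the engine's verdict stands alongside the printed one.
    """
    rows = []
    for prof in profiles:
        crits = evaluate_profile(prof)
        verdict = combine(crits)
        printed = prof.printed_classification
        rows.append(
            {
                "variant": prof.variant_id,
                "criteria": ",".join(c.label for c in crits),
                "classification": verdict.value,
                "printed_classification": printed,
                "concordant": (printed is None) or (verdict.value == printed),
            }
        )
    return pd.DataFrame(rows)
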
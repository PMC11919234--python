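"""Minimal PED (pre-MAKEPED) pedigree handling for trio cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

MISSING = "0"


@dataclass
class Pedigree:
    """family/individual/father/mother records from a 6-column PED file."""

    rows: list[tuple[str, str, str, str, str, str]] = field(default_factory=list)

    def add_trio(
        self, family: str, child: str, father: str, mother: str, sex: str = "0"
    ) -> None:
        self.rows.append((family, father, MISSING, MISSING, "1", "1"))
        self.rows.append((family, mother, MISSING, MISSING, "2", "1"))
        self.rows.append((family, child, father, mother, sex, "2"))

    def parents(self, individual: str) -> tuple[Optional[str], Optional[str]]:
        for _fam, iid, fa, mo, _sex, _ph in self.rows:
            if iid == individual:
                return (fa if fa != MISSING else None, mo if mo != MISSING else None)
        return (None, None)

    def probands(self) -> list[str]:
        return [r[1] for r in self.rows if r[2] != MISSING and r[3] != MISSING]

    def samples(self) -> list[str]:
        return [r[1] for r in self.rows]

    def family_of(self, individual: str) -> Optional[str]:
        for fam, iid, *_ in self.rows:
            if iid == individual:
                return fam
        return None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write("\t".join(row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Pedigree":
        ped = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise ValueError(
                        f"{path}:{lineno}: PED line has {len(fields)} fields, "
                        "expected 6"
                    )
                ped.rows.append(tuple(fields[:6]))  # type: ignore[arg-type]
        return ped
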
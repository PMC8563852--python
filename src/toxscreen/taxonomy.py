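"""The five severity-ordered hazard-category families and their labels.

Screening buckets every matched compound into one of five families, from
most to least severe:

    Acute toxic (GHS category 1-5)
  > Skin and eye irritant (category 1-2)
  > Eye irritant (category 1-2)
  > Skin irritant (category 1-2)
  > Potentially toxic (listed in a hazards database, no acute code found)

Within a family a lower GHS category number is more severe (category 1 is
the worst).  ``severity_rank`` maps (family, level) onto one total order so
"keep the highest toxicity" is a plain max everywhere downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Family(enum.Enum):
    ACUTE_TOXIC = "Acute toxic"
    SKIN_AND_EYE_IRRITANT = "Skin and eye irritant"
    EYE_IRRITANT = "Eye irritant"
    SKIN_IRRITANT = "Skin irritant"
    POTENTIALLY_TOXIC = "Potentially toxic"


# Per-family base rank; larger = more severe. Gaps leave room for levels.
_FAMILY_BASE = {
    Family.ACUTE_TOXIC: 50,
    Family.SKIN_AND_EYE_IRRITANT: 40,
    Family.EYE_IRRITANT: 30,
    Family.SKIN_IRRITANT: 20,
    Family.POTENTIALLY_TOXIC: 10,
}

_MAX_LEVEL = {
    Family.ACUTE_TOXIC: 5,
    Family.SKIN_AND_EYE_IRRITANT: 2,
    Family.EYE_IRRITANT: 2,
    Family.SKIN_IRRITANT: 2,
}


def severity_rank(family: Family, level: int | None) -> int:
    """Total severity order over (family, level); larger is more severe."""
    base = _FAMILY_BASE[family]
    if family is Family.POTENTIALLY_TOXIC:
        return base
    if level is None or not 1 <= level <= _MAX_LEVEL[family]:
        raise ValueError(f"invalid GHS level {level!r} for {family.value}")
    return base + (_MAX_LEVEL[family] - level)


def label(family: Family, level: int | None) -> str:
    """Display label, e.g. ``"Acute toxic 4"`` or ``"Potentially toxic"``."""
    if family is Family.POTENTIALLY_TOXIC:
        return family.value
    severity_rank(family, level)  # validate
    return f"{family.value} {level}"


def parse_label(text: str) -> tuple[Family, int | None]:
    """Inverse of :func:`label`; raises ValueError for unknown labels."""
    text = text.strip()
    if text == Family.POTENTIALLY_TOXIC.value:
        return Family.POTENTIALLY_TOXIC, None
    for fam in Family:
        prefix = fam.value + " "
        if text.startswith(prefix):
            level = int(text[len(prefix):])
            severity_rank(fam, level)  # validate
            return fam, level
    raise ValueError(f"unrecognized classification label {text!r}")


def rank_of_label(text: str) -> int:
    """Severity rank of a display label; 0 for blank/unknown text, so
    unclassified report rows sort last."""
    if not text or not text.strip():
        return 0
    try:
        fam, level = parse_label(text)
    except ValueError:
        return 0
    return severity_rank(fam, level)


@dataclass(frozen=True, order=False)
class ToxClassification:
    """A classification outcome: family, GHS level, and the hazard codes
    that produced it."""

    family: Family
    level: int | None
    evidence: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return label(self.family, self.level)

    @property
    def rank(self) -> int:
        return severity_rank(self.family, self.level)

    def __lt__(self, other: "ToxClassification") -> bool:
        return self.rank < other.rank
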
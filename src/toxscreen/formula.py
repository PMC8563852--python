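"""Molecular-formula canonicalization and exact formula matching.

Formulas coming out of assignment and the ones sitting in a toxic-compound
table rarely agree on element order ("C9H6O2" vs "H6C9O2"), so comparison
goes through a canonical key: the element-count map, rendered in Hill
notation (carbon first, hydrogen second, remaining elements alphabetical;
with no carbon, everything alphabetical).

Matching is exact on element counts.  The upstream assignment stage has
already resolved mass -> formula, so no mass-tolerance fallback exists
here; isomers sharing a formula are all retained as candidates because a
formula match carries no structural information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .elements import KNOWN_ELEMENTS

if TYPE_CHECKING:  # pragma: no cover
    from .io import AssignedFormula, ToxicTableEntry


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class FormulaKey:
    """Canonical identity of a molecular formula.

    ``canonical`` is the Hill-notation string; ``counts`` the element-count
    map.  ``format(parse(s))`` is the identity on canonical strings.
    """

    canonical: str
    counts: tuple[tuple[str, int], ...]

    @property
    def count_map(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_formula(text: str) -> FormulaKey:
    """Parse a molecular formula string into its canonical key.

    Element symbols are matched greedily, longest first, so "Cl" is chlorine
    rather than carbon followed by junk.  Repeated symbols accumulate:
    "CH3CH3" == "C2H6".

    Raises FormulaError on unknown symbols, explicit zero counts, or
    leftover characters.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(
                f"unparsable formula {text!r} at position {pos} ({text[pos:]!r})"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in KNOWN_ELEMENTS:
            # Greedy two-letter match may have swallowed a one-letter element
            # plus a lowercase stray; retry with the single letter.
            if len(symbol) == 2 and symbol[0] in KNOWN_ELEMENTS:
                raise FormulaError(
                    f"unknown element {symbol!r} in formula {text!r}"
                )
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"non-positive count {n} for element {symbol!r} in {text!r}"
            )
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return FormulaKey(canonical=hill_format(counts), counts=_freeze(counts))


def hill_format(counts: dict[str, int]) -> str:
    """Render an element-count map in Hill notation.

    Carbon first, hydrogen second, remaining elements alphabetically; if no
    carbon is present all elements sort alphabetically.  Count 1 elides the
    digit; zero counts are dropped.
    """
    live = {el: n for el, n in counts.items() if n != 0}
    if not live:
        raise FormulaError("empty element-count map")
    if any(n < 0 for n in live.values()):
        raise FormulaError(f"negative element count in {counts!r}")
    if "C" in live:
        order = ["C"] + (["H"] if "H" in live else [])
        order += sorted(el for el in live if el not in ("C", "H"))
    else:
        order = sorted(live)
    return "".join(f"{el}{live[el] if live[el] > 1 else ''}" for el in order)


def formula_key(counts: dict[str, int]) -> FormulaKey:
    """Build a FormulaKey directly from an element-count map."""
    return FormulaKey(canonical=hill_format(counts), counts=_freeze(counts))


def _freeze(counts: dict[str, int]) -> tuple[tuple[str, int], ...]:
    return tuple(sorted((el, n) for el, n in counts.items() if n != 0))


@dataclass(frozen=True)
class FormulaMatch:
    """One assigned formula together with every toxic-table candidate
    sharing its formula key (isomers all retained)."""

    assigned: "AssignedFormula"
    candidates: tuple["ToxicTableEntry", ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("FormulaMatch requires at least one candidate")


def match_formulas(
    assigned: list["AssignedFormula"],
    table: list["ToxicTableEntry"],
    ion_adjust: str | None = None,
) -> tuple[list[FormulaMatch], list["AssignedFormula"]]:
    """Match assigned formulas against the local toxic table.

    Returns ``(matches, unmatched)``; every assigned formula lands in
    exactly one of the two lists.  ``ion_adjust`` is for callers feeding raw
    ion formulas rather than neutral ones: "deprotonated" adds one H back
    ([M-H]- inputs), "protonated" removes one ([M+H]+ inputs); default is
    no adjustment, as assignment outputs neutral formulas.
    """
    index: dict[FormulaKey, list["ToxicTableEntry"]] = {}
    for entry in table:
        index.setdefault(entry.formula, []).append(entry)

    matches: list[FormulaMatch] = []
    unmatched: list["AssignedFormula"] = []
    for af in assigned:
        key = _adjusted_key(af.formula, ion_adjust)
        hits = index.get(key)
        if hits:
            matches.append(FormulaMatch(assigned=af, candidates=tuple(hits)))
        else:
            unmatched.append(af)
    return matches, unmatched


def _adjusted_key(key: FormulaKey, ion_adjust: str | None) -> FormulaKey:
    if ion_adjust is None:
        return key
    counts = key.count_map
    if ion_adjust == "deprotonated":
        counts["H"] = counts.get("H", 0) + 1
    elif ion_adjust == "protonated":
        if counts.get("H", 0) < 1:
            raise FormulaError(f"cannot remove H from {key.canonical}")
        counts["H"] -= 1
    else:
        raise ValueError(f"unknown ion_adjust {ion_adjust!r}")
    return formula_key(counts)
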
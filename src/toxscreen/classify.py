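"""Scan compound records for toxicity evidence and classify severity.

The chain per compound is:

1. ``scan_record`` — depth-first walk over the record's section tree,
   keeping sections whose heading contains a toxicity keyword ("toxic",
   "ghs", "hazard", "safety" by default) or a food-safety keyword
   ("food").  A record with no matching heading anywhere is routed to the
   "unchecked" bin.
2. ``extract_hazard_codes`` — pull every GHS hazard-statement code
   (H followed by exactly three digits) out of the retained toxicity
   sections.
3. ``classify`` — map the code set onto one of the five severity families,
   keeping the highest severity.

The acute-toxicity codes map onto GHS categories irrespective of exposure
route (oral H30x, dermal H31x, inhalation H33x collapse to one level,
since the screening labels carry no route).  H300-series codes that span
two GHS categories report the less extreme one.  Food-safety sections are
carried as evidence context but never change severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formula import FormulaMatch
from .io import ReportRow
from .records import (
    CompoundRecord,
    ProviderError,
    RecordNotFoundError,
    RecordSource,
    Section,
)
from .taxonomy import Family, ToxClassification, severity_rank

import csv
import re
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_TOX_KEYWORDS = ("toxic", "ghs", "hazard", "safety")
DEFAULT_FOOD_KEYWORDS = ("food",)

#: How many resolved identifiers to fetch per compound name.
DEFAULT_CID_CAP = 3

# any substring of H + exactly three digits (a fourth digit disqualifies)
_HAZARD_CODE = re.compile(r"H(\d{3})(?!\d)")

# GHS acute-toxicity hazard statements -> category level.
# Oral (H300-H303), dermal (H310-H313), inhalation (H330-H333).
# H300/H310/H330 each cover categories 1-2; the less extreme level (2)
# is reported.
ACUTE_CODE_LEVEL: dict[str, int] = {
    "H300": 2, "H310": 2, "H330": 2,
    "H301": 3, "H311": 3, "H331": 3,
    "H302": 4, "H312": 4, "H332": 4,
    "H303": 5, "H313": 5, "H333": 5,
}
SKIN_CODE_LEVEL: dict[str, int] = {"H315": 2}
EYE_CODE_LEVEL: dict[str, int] = {"H318": 1, "H319": 2}

MAPPED_CODES = frozenset(ACUTE_CODE_LEVEL) | frozenset(SKIN_CODE_LEVEL) | frozenset(EYE_CODE_LEVEL)


@dataclass(frozen=True)
class KeywordConfig:
    """Case-insensitive substring keywords that select record headings."""

    toxicity: tuple[str, ...] = DEFAULT_TOX_KEYWORDS
    food: tuple[str, ...] = DEFAULT_FOOD_KEYWORDS


@dataclass(frozen=True)
class RelevantFields:
    """Sections of one record whose headings matched the keyword config."""

    tox_sections: tuple[tuple[str, tuple[str, ...]], ...] = ()
    food_sections: tuple[tuple[str, tuple[str, ...]], ...] = ()

    @property
    def empty(self) -> bool:
        return not self.tox_sections and not self.food_sections


def scan_record(
    record: CompoundRecord, keywords: KeywordConfig | None = None
) -> RelevantFields:
    """Collect toxicity- and food-safety-related sections of a record.

    Depth-first traversal; a section is retained when its heading contains
    any configured keyword as a case-insensitive substring.  Children of a
    matching section are still traversed independently so nested hazard
    subsections are found wherever they sit.
    """
    kw = keywords or KeywordConfig()
    tox: list[tuple[str, tuple[str, ...]]] = []
    food: list[tuple[str, tuple[str, ...]]] = []

    def visit(section: Section) -> None:
        heading = section.heading.casefold()
        if any(k.casefold() in heading for k in kw.toxicity):
            tox.append((section.heading, section.content))
        if any(k.casefold() in heading for k in kw.food):
            food.append((section.heading, section.content))
        for child in section.children:
            visit(child)

    for sec in record.sections:
        visit(sec)
    return RelevantFields(tox_sections=tuple(tox), food_sections=tuple(food))


def extract_hazard_codes(fields: RelevantFields) -> set[str]:
    """All GHS hazard-statement codes (H + three digits) in the toxicity
    sections."""
    codes: set[str] = set()
    for _heading, content in fields.tox_sections:
        for line in content:
            codes.update("H" + m for m in _HAZARD_CODE.findall(line))
    return codes


def classify(codes: set[str]) -> ToxClassification:
    """Classify a hazard-code set into one of the five severity families.

    The result is the maximum severity over all per-code classifications;
    when both a skin-irritation and an eye-irritation code are present
    they combine into the "Skin and eye irritant" family at the more
    severe (lower) of the two category levels.  An empty code set means
    the compound sits in a hazards database but carries no mapped acute
    code: "Potentially toxic".  Unknown codes are ignored with a warning.
    """
    unknown = {c for c in codes if c not in MAPPED_CODES}
    if unknown:
        logger.warning("ignoring unmapped hazard codes: %s", sorted(unknown))
    known = codes - unknown

    best: ToxClassification | None = None

    def consider(family: Family, level: int | None, evidence: set[str]) -> None:
        nonlocal best
        cand = ToxClassification(family, level, tuple(sorted(evidence)))
        if best is None or cand.rank > best.rank:
            best = cand

    acute = {c: ACUTE_CODE_LEVEL[c] for c in known if c in ACUTE_CODE_LEVEL}
    if acute:
        top = min(acute.values())  # lower GHS category = more severe
        consider(Family.ACUTE_TOXIC, top, {c for c, l in acute.items() if l == top})

    skin = {c: SKIN_CODE_LEVEL[c] for c in known if c in SKIN_CODE_LEVEL}
    eye = {c: EYE_CODE_LEVEL[c] for c in known if c in EYE_CODE_LEVEL}
    if skin and eye:
        level = min(min(skin.values()), min(eye.values()))
        consider(Family.SKIN_AND_EYE_IRRITANT, level, set(skin) | set(eye))
    elif eye:
        level = min(eye.values())
        consider(Family.EYE_IRRITANT, level, {c for c, l in eye.items() if l == level})
    elif skin:
        level = min(skin.values())
        consider(Family.SKIN_IRRITANT, level, {c for c, l in skin.items() if l == level})

    if best is None:
        return ToxClassification(Family.POTENTIALLY_TOXIC, None, ())
    return best


@dataclass(frozen=True)
class CandidateOutcome:
    """Where one toxic-table candidate ended up after record retrieval."""

    name: str
    formula: str
    status: str  # classified | unchecked | unfound
    classification: ToxClassification | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("classified", "unchecked", "unfound"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "classified") != (self.classification is not None):
            raise ValueError("classification present iff status == 'classified'")


def classify_compound(
    match: FormulaMatch,
    provider: RecordSource,
    keywords: KeywordConfig | None = None,
    cid_cap: int = DEFAULT_CID_CAP,
) -> list[CandidateOutcome]:
    """Resolve, fetch and classify every candidate of a formula match.

    Per candidate: an unresolvable name is "unfound"; a record with no
    toxicity/food-safety sections is "unchecked"; otherwise the candidate
    is classified with the maximum severity over all fetched records (up
    to ``cid_cap`` identifiers).  Provider failures route the candidate to
    "unfound" with an error note — conservative, never fatal to the run.
    """
    outcomes: list[CandidateOutcome] = []
    for cand in match.candidates:
        formula = cand.formula.canonical
        try:
            cids = provider.resolve_name(cand.name)
        except ProviderError as exc:
            outcomes.append(
                CandidateOutcome(cand.name, formula, "unfound", note=f"provider error: {exc}")
            )
            continue
        if not cids:
            outcomes.append(CandidateOutcome(cand.name, formula, "unfound"))
            continue
        classifications: list[ToxClassification] = []
        any_relevant = False
        notes: list[str] = []
        for cid in cids[:cid_cap]:
            try:
                record = provider.fetch_record(cid)
            except RecordNotFoundError:
                notes.append(f"cid {cid} not found")
                continue
            except ProviderError as exc:
                notes.append(f"cid {cid} provider error: {exc}")
                continue
            fields = scan_record(record, keywords)
            if fields.empty:
                continue
            any_relevant = True
            classifications.append(classify(extract_hazard_codes(fields)))
        if classifications:
            best = max(classifications, key=lambda c: c.rank)
            outcomes.append(
                CandidateOutcome(cand.name, formula, "classified", classification=best)
            )
        elif any_relevant:  # pragma: no cover - classify always returns
            raise AssertionError("unreachable")
        elif notes and len(notes) == len(cids[:cid_cap]):
            outcomes.append(
                CandidateOutcome(cand.name, formula, "unfound", note="; ".join(notes))
            )
        else:
            outcomes.append(CandidateOutcome(cand.name, formula, "unchecked"))
    return outcomes


# ---------------------------------------------------------------------------
# Formatted merged-toxic report

FORMATTED_HEADER = ("category", "name", "classification", "evidence", "samples", "modes")


def format_toxic_report(rows: list[ReportRow], path: str | Path) -> Path:
    """Second formatting pass over the merged toxic table.

    Rows are grouped by the five category families in severity order, a
    ``category`` column names the family, and within a family rows sort by
    severity then name.  Deterministic: the same input always yields
    byte-identical output.
    """
    by_family: dict[Family, list[ReportRow]] = {fam: [] for fam in Family}
    for row in rows:
        fam = _family_of(row.classification)
        by_family[fam].append(row)

    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(FORMATTED_HEADER)
        for fam in sorted(Family, key=lambda f: -severity_rank(f, 1 if f is not Family.POTENTIALLY_TOXIC else None)):
            group = sorted(by_family[fam], key=lambda r: (-r.severity, r.name))
            for row in group:
                writer.writerow(
                    [fam.value, row.name, row.classification, row.evidence,
                     row.samples, row.modes]
                )
    return path


def _family_of(label_text: str) -> Family:
    from .taxonomy import parse_label

    try:
        fam, _ = parse_label(label_text)
        return fam
    except ValueError:
        return Family.POTENTIALLY_TOXIC
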
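"""Local matching of unfound compounds, and cross-mode/cross-sample merging.

Compounds whose names resolve nowhere are checked against a local table of
previously hand-curated records; anything still unfound goes back into the
unfound report to be added to that table later.

Each sample is run in both electrospray polarities, so per-mode rows are
first combined per sample, then per-sample rows merge across samples into
one report per kind (toxic, unfound, unchecked).  Merging is a union
(outer join) keyed on the normalized compound name: a merged report exists
to show everything any sample produced, so no sample's compounds are
dropped; an intersection view is available via ``how="inner"``.
Classification conflicts for the same compound resolve to the higher
severity with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .names import normalize_name
from .taxonomy import rank_of_label

logger = logging.getLogger(__name__)

FIVE_FAMILY_LABELS_HINT = "e.g. 'Acute toxic 4', 'Potentially toxic', or 'excluded'"


@dataclass(frozen=True)
class LocalRecordEntry:
    """One previously-resolved compound in the local record table."""

    name: str
    safety_class: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("local record name must be non-empty")
        if not self.safety_class.strip():
            raise ValueError(
                f"safety_class must be non-empty ({FIVE_FAMILY_LABELS_HINT})"
            )


@dataclass(frozen=True)
class CompoundPresence:
    """One compound's row in a combined or merged view.

    ``modes`` collects the ESI polarities it appeared in; ``samples`` maps
    each contributing sample id to its modes.
    """

    name: str
    classification: str = ""
    formula: str = ""
    evidence: str = ""
    note: str = ""
    modes: frozenset[str] = frozenset()
    samples: tuple[tuple[str, frozenset[str]], ...] = ()


@dataclass(frozen=True)
class MergedReport:
    kind: str  # toxic | unfound | unchecked
    rows: tuple[CompoundPresence, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("toxic", "unfound", "unchecked"):
            raise ValueError(f"bad merged-report kind {self.kind!r}")
        names = [normalize_name(r.name) for r in self.rows]
        if len(names) != len(set(names)):
            raise ValueError("merged report must have one row per compound name")


def match_local(
    unfound: list[str], table: list[LocalRecordEntry]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Match unfound compound names against the local record table.

    Name comparison is case-insensitive and stereo-prefix-normalized.
    Returns ``(found, still_unfound)`` where ``found`` pairs each matched
    name with its recorded safety class; every input name lands in exactly
    one of the two lists.
    """
    index: dict[str, LocalRecordEntry] = {}
    for entry in table:
        index.setdefault(normalize_name(entry.name), entry)
    found: list[tuple[str, str]] = []
    still: list[str] = []
    for name in unfound:
        hit = index.get(normalize_name(name))
        if hit is not None:
            found.append((name, hit.safety_class))
        else:
            still.append(name)
    return found, still


def _merge_two(a: CompoundPresence, b: CompoundPresence) -> CompoundPresence:
    """Union of two presence rows for the same normalized name."""
    if a.classification and b.classification and a.classification != b.classification:
        if rank_of_label(b.classification) > rank_of_label(a.classification):
            a, b = b, a
        logger.warning(
            "classification conflict for %r: keeping %r over %r",
            a.name, a.classification, b.classification,
        )
    elif not a.classification and b.classification:
        a, b = b, a
    samples: dict[str, frozenset[str]] = dict(a.samples)
    for sid, modes in b.samples:
        samples[sid] = samples.get(sid, frozenset()) | modes
    evidence = a.evidence
    if b.evidence and b.evidence != a.evidence:
        joined = sorted(set(filter(None, a.evidence.split(";"))) | set(b.evidence.split(";")))
        evidence = ";".join(joined)
    return replace(
        a,
        modes=a.modes | b.modes,
        samples=tuple(sorted(samples.items())),
        evidence=evidence,
        note=a.note or b.note,
    )


def combine_modes(
    pos: list[CompoundPresence], neg: list[CompoundPresence]
) -> list[CompoundPresence]:
    """Combine both ESI polarities of one sample into per-sample rows.

    Union by normalized compound name; a compound seen in both modes
    appears once with both mode flags.  Conflicting classifications keep
    the higher severity with a warning.  Output sorted by severity then
    name.
    """
    merged: dict[str, CompoundPresence] = {}
    for row in list(pos) + list(neg):
        key = normalize_name(row.name)
        merged[key] = _merge_two(merged[key], row) if key in merged else row
    return sorted(
        merged.values(), key=lambda r: (-rank_of_label(r.classification), r.name)
    )


def merge_samples(
    sample_outputs: dict[str, list[CompoundPresence]],
    kind: str,
    how: str = "outer",
) -> MergedReport:
    """Merge per-sample rows into one cross-sample report of the given kind.

    ``how="outer"`` (default) unions across samples; ``how="inner"`` keeps
    only compounds present in every sample.  Idempotent, commutative and
    associative over samples up to row order.
    """
    if not sample_outputs:
        raise ValueError("merge_samples requires at least one sample")
    if how not in ("outer", "inner"):
        raise ValueError(f"how must be outer|inner, got {how!r}")
    merged: dict[str, CompoundPresence] = {}
    seen_in: dict[str, set[str]] = {}
    for sid in sorted(sample_outputs):
        for row in sample_outputs[sid]:
            key = normalize_name(row.name)
            stamped = replace(row, samples=(*row.samples, (sid, row.modes)) if not any(
                s == sid for s, _ in row.samples) else row.samples)
            merged[key] = _merge_two(merged[key], stamped) if key in merged else stamped
            seen_in.setdefault(key, set()).add(sid)
    if how == "inner":
        all_ids = set(sample_outputs)
        merged = {k: v for k, v in merged.items() if seen_in[k] == all_ids}
    rows = tuple(
        sorted(merged.values(), key=lambda r: (-rank_of_label(r.classification), r.name))
    )
    return MergedReport(kind=kind, rows=rows, sample_ids=tuple(sorted(sample_outputs)))
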
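"""CSV interchange formats between toolchain stages, and the report files.

Three inputs flow through the screening stage:

* feature tables exported from peak picking, with the fixed column order
  ``row m/z, peak area, row retention time`` the assignment stage expects;
* assigned-formula tables from the formula-assignment stage (column names
  vary by configuration, so reading goes through a ``column_map``);
* a local toxic-compound table in an OpenFoodTox/TPPT-like schema.

All outputs are plain CSV with a deterministic column order and row order
(severity rank descending, then name), so identical runs produce
byte-identical reports and write->read is the identity.

Dialect is fixed: comma separator, UTF-8, header row required.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .elements import monoisotopic_mass
from .formula import FormulaError, FormulaKey, parse_formula
from .taxonomy import rank_of_label

logger = logging.getLogger(__name__)

#: Default mass/formula agreement tolerance, matching the assignment
#: stage's own ppm error bound.
DEFAULT_PPM_TOL = 3.0

FEATURE_COLUMNS = ("row m/z", "peak area", "row retention time")

#: Default assigned-formula column names (assignment-stage output naming);
#: override via column_map for any other dialect.
DEFAULT_COLUMN_MAP = {
    "formula": "formula",
    "mass": "exp_mass",
    "abundance": "abundance",
    "retention_time": "RT",
}


class ContractViolationError(ValueError):
    """An interchange file breaks its column contract."""


class OrderViolationError(ContractViolationError):
    """Required columns present but not in the stated left-to-right order."""


class RowParseError(ValueError):
    """A cell failed to parse; carries the offending row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class PeakFeature:
    """One monoisotopic feature from peak picking."""

    mz: float
    peak_area: float
    retention_time: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.peak_area < 0:
            raise ValueError(f"peak_area must be >= 0, got {self.peak_area}")
        if self.retention_time < 0:
            raise ValueError(
                f"retention_time must be >= 0, got {self.retention_time}"
            )


@dataclass(frozen=True)
class AssignedFormula:
    """One neutral molecular formula assigned to a feature.

    ``mass_consistent`` records whether the formula's computed monoisotopic
    mass agrees with the stated neutral mass within the configured ppm
    tolerance; inconsistent rows are flagged, never dropped, because
    downstream matching is by formula rather than mass.
    """

    formula: FormulaKey
    neutral_mass: float
    abundance: float
    retention_time: float
    ion_mode: str
    ambiguous: bool = False
    mass_consistent: bool = True

    def __post_init__(self) -> None:
        counts = self.formula.count_map
        if counts.get("C", 0) <= 0 or counts.get("H", 0) <= 0:
            raise ValueError(
                f"assigned formula must contain C and H: {self.formula.canonical}"
            )
        if not self.neutral_mass > 0:
            raise ValueError(f"neutral_mass must be > 0, got {self.neutral_mass}")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"ion_mode must be positive|negative, got {self.ion_mode!r}")


@dataclass(frozen=True)
class ToxicTableEntry:
    """One candidate toxic compound from the local table."""

    name: str
    formula: FormulaKey
    monoisotopic_mass: float
    source: str = "user"
    safety_class: str | None = None

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("toxic-table entry name must be non-empty")
        if not self.monoisotopic_mass > 0:
            raise ValueError(
                f"monoisotopic_mass must be > 0, got {self.monoisotopic_mass}"
            )
        if self.source not in ("OpenFoodTox", "TPPT", "user"):
            raise ValueError(f"unknown source {self.source!r}")


def read_feature_table(path: str | Path, strict_order: bool = True) -> list[PeakFeature]:
    """Read a peak-picking feature table.

    The downstream assignment stage requires the columns ``row m/z``,
    ``peak area``, ``row retention time`` in exactly that left-to-right
    order; ``strict_order=True`` (default) enforces it, ``False`` accepts
    any order as long as all three columns exist.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    for required in FEATURE_COLUMNS:
        if required not in cols:
            raise ContractViolationError(
                f"feature table {path}: missing required column {required!r}"
            )
    if strict_order:
        positions = [cols.index(c) for c in FEATURE_COLUMNS]
        if positions != sorted(positions):
            raise OrderViolationError(
                f"feature table {path}: columns must appear in order "
                f"{', '.join(FEATURE_COLUMNS)}; found {', '.join(cols)}"
            )
    features: list[PeakFeature] = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = dict(zip(cols, row))
        parsed = {}
        for col in FEATURE_COLUMNS:
            v = values[col]
            try:
                parsed[col] = float(v)
            except (TypeError, ValueError):
                raise RowParseError(i, f"non-numeric value {v!r} in column {col!r}")
            if math.isnan(parsed[col]):
                raise RowParseError(i, f"missing value in column {col!r}")
        features.append(
            PeakFeature(
                mz=parsed["row m/z"],
                peak_area=parsed["peak area"],
                retention_time=parsed["row retention time"],
            )
        )
    return features


def read_assigned_formulas(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    ion_mode: str = "negative",
    ppm_tol: float = DEFAULT_PPM_TOL,
    ambiguous: bool = False,
) -> list[AssignedFormula]:
    """Read an assigned-formula table, stamping ``ion_mode`` on every row.

    ``column_map`` maps the logical fields {formula, mass, abundance,
    retention_time} to this file's header names; defaults cover the
    assignment stage's own output naming.  Rows whose formula mass
    disagrees with the stated mass beyond ``ppm_tol`` are flagged
    (``mass_consistent=False``) and kept, with a logged warning.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    for logical, name in cmap.items():
        if name not in df.columns:
            raise ContractViolationError(
                f"assigned-formula table {path}: missing column {name!r} "
                f"(mapped from {logical!r})"
            )
    out: list[AssignedFormula] = []
    n_flagged = 0
    for i, row in df.iterrows():
        text = str(row[cmap["formula"]])
        try:
            key = parse_formula(text)
        except FormulaError as exc:
            raise RowParseError(int(i), str(exc)) from exc
        try:
            mass = float(row[cmap["mass"]])
            abundance = float(row[cmap["abundance"]])
            rt = float(row[cmap["retention_time"]])
        except (TypeError, ValueError) as exc:
            raise RowParseError(int(i), f"non-numeric cell: {exc}") from exc
        computed = monoisotopic_mass(key.count_map)
        ppm = abs(computed - mass) / computed * 1e6
        consistent = ppm <= ppm_tol
        if not consistent:
            n_flagged += 1
            logger.warning(
                "row %d: formula %s computed mass %.6f differs from stated "
                "%.6f by %.1f ppm (tolerance %.1f)",
                i, key.canonical, computed, mass, ppm, ppm_tol,
            )
        out.append(
            AssignedFormula(
                formula=key,
                neutral_mass=mass,
                abundance=abundance,
                retention_time=rt,
                ion_mode=ion_mode,
                ambiguous=ambiguous,
                mass_consistent=consistent,
            )
        )
    if n_flagged:
        logger.warning("%s: %d/%d rows flagged mass-inconsistent", path, n_flagged, len(out))
    return out


def read_toxic_table(path: str | Path) -> list[ToxicTableEntry]:
    """Read the local toxic-compound table.

    Duplicate (name, formula) rows keep the first occurrence; rows with
    unparsable formulas are skipped with a logged warning and a reported
    count.
    """
    df = pd.read_csv(path)
    required = ("name", "formula", "monoisotopic_mass", "source")
    for col in required:
        if col not in df.columns:
            raise ContractViolationError(
                f"toxic table {path}: missing required column {col!r}"
            )
    entries: list[ToxicTableEntry] = []
    seen: set[tuple[str, str]] = set()
    n_skipped = 0
    for i, row in df.iterrows():
        try:
            key = parse_formula(str(row["formula"]))
        except FormulaError as exc:
            n_skipped += 1
            logger.warning("toxic table row %d skipped: %s", i, exc)
            continue
        dedup = (str(row["name"]), key.canonical)
        if dedup in seen:
            continue
        seen.add(dedup)
        safety = row["safety_class"] if "safety_class" in df.columns else None
        if safety is not None and pd.isna(safety):
            safety = None
        elif safety is not None:
            safety = str(safety)
        entries.append(
            ToxicTableEntry(
                name=str(row["name"]),
                formula=key,
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                source=str(row["source"]),
                safety_class=safety,
            )
        )
    if n_skipped:
        logger.warning("toxic table %s: skipped %d unparsable rows", path, n_skipped)
    return entries


# ---------------------------------------------------------------------------
# Report files

REPORT_KINDS = ("toxic", "unfound", "unchecked", "safe")

#: Column set per report kind; fixed order for byte-identical output.
REPORT_COLUMNS: dict[str, tuple[str, ...]] = {
    "toxic": ("name", "formula", "classification", "evidence", "samples", "modes"),
    "unfound": ("name", "formula", "note", "samples", "modes"),
    "unchecked": ("name", "formula", "samples", "modes"),
    "safe": ("name", "classification", "note", "samples", "modes"),
}


@dataclass(frozen=True)
class ReportRow:
    """One line of a screening report; unused fields stay empty strings.

    ``samples`` and ``modes`` are semicolon-joined presence flags
    (e.g. ``"S1;S2"``, ``"negative;positive"``).
    """

    name: str
    formula: str = ""
    classification: str = ""
    evidence: str = ""
    note: str = ""
    samples: str = ""
    modes: str = ""

    @property
    def severity(self) -> int:
        return rank_of_label(self.classification)


def write_report(records: list[ReportRow], path: str | Path, kind: str) -> Path:
    """Write a report CSV of the given kind.

    Rows are sorted severity-rank descending then name ascending, the
    column order is fixed per kind, and re-reading with
    :func:`read_report` yields identical records.
    """
    if kind not in REPORT_KINDS:
        raise ValueError(f"unknown report kind {kind!r}")
    cols = REPORT_COLUMNS[kind]
    rows = sorted(records, key=lambda r: (-r.severity, r.name))
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in rows:
            writer.writerow([getattr(r, c) for c in cols])
    return path


def read_report(path: str | Path, kind: str) -> list[ReportRow]:
    """Read back a report written by :func:`write_report`."""
    if kind not in REPORT_KINDS:
        raise ValueError(f"unknown report kind {kind!r}")
    cols = REPORT_COLUMNS[kind]
    rows: list[ReportRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != cols:
            raise ContractViolationError(
                f"report {path}: expected header {cols}, found {header}"
            )
        for line in reader:
            rows.append(ReportRow(**dict(zip(cols, line))))
    return rows
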
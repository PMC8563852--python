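"""Full screening pipeline: per-sample matching, retrieval, classification
and local matching, then cross-sample merging and the final formatting
pass.

Stage order per sample: match assigned formulas against the toxic table ->
resolve and fetch compound records -> classify severity -> local-match the
unfound names.  After all samples: merge across samples three times (once
each for toxic, unfound and unchecked), then run the toxic formatting pass
over the merged toxic table.  All per-sample outputs are written under
``output_root/<sample-id>/``, merged outputs at the run root.

With the fixture provider the whole run is a pure function of (inputs,
config): rerunning produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import (
    DEFAULT_CID_CAP,
    CandidateOutcome,
    KeywordConfig,
    classify_compound,
    format_toxic_report,
)
from .formula import match_formulas
from .io import (
    DEFAULT_PPM_TOL,
    ContractViolationError,
    ReportRow,
    read_assigned_formulas,
    read_toxic_table,
    write_report,
)
from .merge import (
    CompoundPresence,
    LocalRecordEntry,
    MergedReport,
    combine_modes,
    match_local,
    merge_samples,
)
from .names import normalize_name
from .records import RecordSource, load_fixture_store
from .taxonomy import rank_of_label

import pandas as pd

logger = logging.getLogger(__name__)

MERGE_KINDS = ("toxic", "unfound", "unchecked")
DEFAULT_PATTERNS = {"pos": "*pos*.csv", "neg": "*neg*.csv"}


class ConfigError(ValueError):
    """The run configuration is invalid; message names the offending key."""


@dataclass
class RunConfig:
    """Validated configuration for one screening run."""

    sample_dirs: list[Path]
    toxic_table_path: Path
    output_root: Path
    provider: str = "fixture"  # fixture | live
    store_path: Path | None = None
    base_url: str = ""
    allow_network: bool = False
    local_table_path: Path | None = None
    keywords: KeywordConfig = field(default_factory=KeywordConfig)
    column_map: dict[str, str] = field(default_factory=dict)
    patterns: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PATTERNS))
    ppm_tol: float = DEFAULT_PPM_TOL
    cid_cap: int = DEFAULT_CID_CAP
    merge_how: str = "outer"
    seed: int = 0

    def validate(self) -> None:
        if not self.sample_dirs:
            raise ConfigError("sample_dirs: at least one sample directory required")
        for d in self.sample_dirs:
            if not Path(d).is_dir():
                raise ConfigError(f"sample_dirs: not a directory: {d}")
        if not Path(self.toxic_table_path).is_file():
            raise ConfigError(f"toxic_table: file not found: {self.toxic_table_path}")
        if self.provider not in ("fixture", "live"):
            raise ConfigError(f"provider: must be fixture|live, got {self.provider!r}")
        if self.provider == "fixture":
            if self.store_path is None:
                raise ConfigError("store: required when provider is 'fixture'")
            if not Path(self.store_path).is_dir():
                raise ConfigError(f"store: not a directory: {self.store_path}")
        if self.provider == "live" and not self.allow_network:
            raise ConfigError(
                "provider: 'live' requires allow_network: true (refused by default)"
            )
        if self.local_table_path is not None and not Path(self.local_table_path).is_file():
            raise ConfigError(f"local_table: file not found: {self.local_table_path}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing mandatory keys raise :class:`ConfigError` naming the key;
    defaults for optional keys are applied here and echoed to the run log
    by :func:`run_pipeline`.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    for key in ("samples", "toxic_table", "output"):
        if key not in raw:
            raise ConfigError(f"{key}: mandatory key missing")
    base = Path(path).parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    kw = raw.get("keywords", {})
    keywords = KeywordConfig(
        toxicity=tuple(kw.get("toxicity", KeywordConfig().toxicity)),
        food=tuple(kw.get("food", KeywordConfig().food)),
    )
    config = RunConfig(
        sample_dirs=[resolve(p) for p in raw["samples"]],
        toxic_table_path=resolve(raw["toxic_table"]),
        output_root=resolve(raw["output"]),
        provider=raw.get("provider", "fixture"),
        store_path=resolve(raw["store"]) if "store" in raw else None,
        base_url=raw.get("base_url", ""),
        allow_network=bool(raw.get("allow_network", False)),
        local_table_path=resolve(raw["local_table"]) if "local_table" in raw else None,
        keywords=keywords,
        column_map=dict(raw.get("column_map", {})),
        patterns={**DEFAULT_PATTERNS, **raw.get("patterns", {})},
        ppm_tol=float(raw.get("ppm_tol", DEFAULT_PPM_TOL)),
        cid_cap=int(raw.get("cid_cap", DEFAULT_CID_CAP)),
        merge_how=raw.get("merge_how", "outer"),
        seed=int(raw.get("seed", 0)),
    )
    config.validate()
    return config


def read_local_table(path: str | Path) -> list[LocalRecordEntry]:
    """Read the local table of previously-resolved records (CSV with
    ``name``, ``safety_class`` and optional ``note`` columns)."""
    df = pd.read_csv(path)
    for col in ("name", "safety_class"):
        if col not in df.columns:
            raise ContractViolationError(f"local table {path}: missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        note = row["note"] if "note" in df.columns and not pd.isna(row["note"]) else ""
        entries.append(
            LocalRecordEntry(
                name=str(row["name"]),
                safety_class=str(row["safety_class"]),
                note=str(note),
            )
        )
    return entries


@dataclass
class SampleResult:
    """Per-sample partitions after classification and local matching."""

    sample_id: str
    toxic: list[CompoundPresence]
    unchecked: list[CompoundPresence]
    unfound: list[CompoundPresence]
    locally_matched: list[CompoundPresence]
    unmatched_formulas: list[str]
    n_assigned: int
    n_matched_candidates: int


@dataclass
class ScreeningResult:
    """Everything one full run produced."""

    per_sample: dict[str, SampleResult]
    merged: dict[str, MergedReport]
    formatted_toxic_path: Path
    output_root: Path
    log_lines: list[str]


def _outcomes_to_rows(
    outcomes: list[CandidateOutcome], mode: str
) -> dict[str, list[CompoundPresence]]:
    """Bucket candidate outcomes into per-kind presence rows for one mode."""
    buckets: dict[str, dict[str, CompoundPresence]] = {
        "toxic": {}, "unchecked": {}, "unfound": {},
    }
    for oc in outcomes:
        kind = {"classified": "toxic", "unchecked": "unchecked", "unfound": "unfound"}[oc.status]
        row = CompoundPresence(
            name=oc.name,
            formula=oc.formula,
            classification=oc.classification.label if oc.classification else "",
            evidence=";".join(oc.classification.evidence) if oc.classification else "",
            note=oc.note,
            modes=frozenset([mode]),
        )
        key = normalize_name(oc.name)
        bucket = buckets[kind]
        if key in bucket:
            prev = bucket[key]
            keep = row if rank_of_label(row.classification) > rank_of_label(prev.classification) else prev
            bucket[key] = keep
        else:
            bucket[key] = row
    return {k: sorted(v.values(), key=lambda r: r.name) for k, v in buckets.items()}


def _presence_to_report_row(row: CompoundPresence) -> ReportRow:
    samples = ";".join(sid for sid, _ in row.samples)
    return ReportRow(
        name=row.name,
        formula=row.formula,
        classification=row.classification,
        evidence=row.evidence,
        note=row.note,
        samples=samples,
        modes=";".join(sorted(row.modes)),
    )


def _process_sample(
    sample_dir: Path,
    toxic_table,
    local_table: list[LocalRecordEntry],
    provider: RecordSource,
    config: RunConfig,
    log: list[str],
) -> SampleResult:
    sample_id = sample_dir.name
    per_mode: dict[str, dict[str, list[CompoundPresence]]] = {}
    unmatched_all: list[str] = []
    n_assigned = 0
    mode_names = {"pos": "positive", "neg": "negative"}
    found_any = False
    for tag in ("pos", "neg"):
        files = sorted(sample_dir.glob(config.patterns[tag]))
        if not files:
            continue
        found_any = True
        mode = mode_names[tag]
        assigned = []
        for f in files:
            assigned.extend(
                read_assigned_formulas(
                    f, column_map=config.column_map, ion_mode=mode, ppm_tol=config.ppm_tol
                )
            )
        matches, unmatched = match_formulas(assigned, toxic_table)
        outcomes: list[CandidateOutcome] = []
        for m in matches:
            outcomes.extend(
                classify_compound(m, provider, keywords=config.keywords, cid_cap=config.cid_cap)
            )
        per_mode[mode] = _outcomes_to_rows(outcomes, mode)
        unmatched_all.extend(sorted({af.formula.canonical for af in unmatched}))
        n_assigned += len(assigned)
        log.append(
            f"[{sample_id}/{mode}] features={len(assigned)} matched={len(matches)} "
            f"unmatched={len(unmatched)} candidates={len(outcomes)}"
        )
    if not found_any:
        raise ContractViolationError(
            f"sample {sample_id}: no input files matching "
            f"{config.patterns['pos']} or {config.patterns['neg']} in {sample_dir}"
        )

    empty = {"toxic": [], "unchecked": [], "unfound": []}
    pos_rows = per_mode.get("positive", empty)
    neg_rows = per_mode.get("negative", empty)
    combined = {
        kind: combine_modes(pos_rows[kind], neg_rows[kind]) for kind in MERGE_KINDS
    }

    found, still = match_local([r.name for r in combined["unfound"]], local_table)
    class_by_name = dict(found)
    locally_matched = [
        CompoundPresence(
            name=r.name, formula=r.formula, classification=class_by_name[r.name],
            note="local table", modes=r.modes,
        )
        for r in combined["unfound"] if r.name in class_by_name
    ]
    still_set = set(still)
    still_unfound = [r for r in combined["unfound"] if r.name in still_set]

    return SampleResult(
        sample_id=sample_id,
        toxic=combined["toxic"],
        unchecked=combined["unchecked"],
        unfound=still_unfound,
        locally_matched=locally_matched,
        unmatched_formulas=sorted(set(unmatched_all)),
        n_assigned=n_assigned,
        n_matched_candidates=sum(len(combined[k]) for k in MERGE_KINDS),
    )


def run_pipeline(config: RunConfig) -> ScreeningResult:
    """Execute the full screening run described by ``config``.

    Per-sample outputs land in ``output_root/<sample-id>/``; the three
    merged reports, the formatted toxic report and the run log at the run
    root.  Provider failures for individual compounds are routed
    conservatively (to "unfound" with a note) and never abort the run;
    unreadable inputs abort before any processing.
    """
    config.validate()
    log: list[str] = [f"config: provider={config.provider} merge={config.merge_how}"]

    toxic_table = read_toxic_table(config.toxic_table_path)
    log.append(f"toxic table: {len(toxic_table)} entries from {config.toxic_table_path.name}")
    local_table = (
        read_local_table(config.local_table_path) if config.local_table_path else []
    )
    provider = _build_provider(config)

    out_root = Path(config.output_root)
    out_root.mkdir(parents=True, exist_ok=True)

    per_sample: dict[str, SampleResult] = {}
    for sample_dir in sorted(config.sample_dirs):
        result = _process_sample(sample_dir, toxic_table, local_table, provider, config, log)
        per_sample[result.sample_id] = result
        sdir = out_root / result.sample_id
        sdir.mkdir(parents=True, exist_ok=True)
        write_report([_presence_to_report_row(r) for r in result.toxic], sdir / "toxic.csv", "toxic")
        write_report([_presence_to_report_row(r) for r in result.unchecked], sdir / "unchecked.csv", "unchecked")
        write_report([_presence_to_report_row(r) for r in result.unfound], sdir / "unfound.csv", "unfound")
        write_report([_presence_to_report_row(r) for r in result.locally_matched], sdir / "locally_matched.csv", "safe")
        (sdir / "unmatched_formulas.txt").write_text(
            "\n".join(result.unmatched_formulas) + ("\n" if result.unmatched_formulas else ""),
            encoding="utf-8",
        )
        log.append(
            f"[{result.sample_id}] toxic={len(result.toxic)} "
            f"unchecked={len(result.unchecked)} unfound={len(result.unfound)} "
            f"locally_matched={len(result.locally_matched)}"
        )

    merged: dict[str, MergedReport] = {}
    for kind in MERGE_KINDS:
        merged[kind] = merge_samples(
            {sid: getattr(res, kind) for sid, res in per_sample.items()},
            kind,
            how=config.merge_how,
        )
        rows = [_presence_to_report_row(r) for r in merged[kind].rows]
        report_kind = "toxic" if kind == "toxic" else kind
        write_report(rows, out_root / f"merged_{kind}.csv", report_kind)
        log.append(f"merged {kind}: {len(rows)} compounds across {len(per_sample)} samples")

    formatted = format_toxic_report(
        [_presence_to_report_row(r) for r in merged["toxic"].rows],
        out_root / "formatted_toxic.csv",
    )
    log.append("formatted toxic report written")

    (out_root / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return ScreeningResult(
        per_sample=per_sample,
        merged=merged,
        formatted_toxic_path=formatted,
        output_root=out_root,
        log_lines=log,
    )


def _build_provider(config: RunConfig) -> RecordSource:
    if config.provider == "fixture":
        return load_fixture_store(config.store_path)
    from .records import LiveProvider  # pragma: no cover - live mode

    return LiveProvider(config.base_url)  # pragma: no cover
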
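"""Compound-record retrieval: name -> identifiers -> full sectioned record.

Two providers share one interface:

* :class:`FixtureStore` — a directory of JSON record files (one compound
  per file).  Pure and deterministic; the default and the whole test
  surface.
* :class:`LiveProvider` — a rate-limited HTTP client against a public
  compound database's REST endpoints (name -> CID list, CID -> full
  record).  Requests are spaced at least 0.2 s apart so as not to overload
  the remote service; transient failures retry with backoff.  Excluded
  from the test suite; the clock and transport are injectable so the
  rate-limit contract itself is testable without network or real waiting.

"Record not found" and "provider broke" are distinct outcomes
(:class:`RecordNotFoundError` vs :class:`ProviderError`): only genuine
not-found results may flow into the local-match stage downstream.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

from .names import casefold_name, normalize_name

logger = logging.getLogger(__name__)

MIN_REQUEST_INTERVAL = 0.2  # seconds between live requests


class RecordNotFoundError(LookupError):
    """The store/service has no record for this name or identifier."""


class ProviderError(RuntimeError):
    """Transport or payload failure, distinct from not-found."""


class RecordSchemaError(ValueError):
    """A record payload violates the record schema; names the bad node."""


@dataclass(frozen=True)
class Section:
    """One heading in a compound record, with text content and subsections."""

    heading: str
    content: tuple[str, ...] = ()
    children: tuple["Section", ...] = ()


@dataclass(frozen=True)
class CompoundRecord:
    """Full hierarchical record for one compound."""

    cid: int
    name: str
    sections: tuple[Section, ...] = ()
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cid <= 0:
            raise ValueError(f"cid must be positive, got {self.cid}")


@dataclass(frozen=True)
class ProviderResult:
    """Outcome of a resolve-and-fetch round trip for one name."""

    status: str  # found | not_found | error
    cids: tuple[int, ...] = ()
    records: tuple[CompoundRecord, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("found", "not_found", "error"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "found") != bool(self.records):
            raise ValueError("status 'found' iff records non-empty")
        if self.status == "not_found" and self.cids:
            raise ValueError("not_found implies no cids")


class RecordSource(Protocol):
    def resolve_name(self, name: str) -> list[int]: ...
    def fetch_record(self, cid: int) -> CompoundRecord: ...


# ---------------------------------------------------------------------------
# JSON record schema (hand-validated; layout mirrors the hierarchical
# Record -> Section -> Information shape of real downloaded records, so a
# real record translated to this shape drops in unchanged).

def validate_record_payload(payload: object, origin: str = "<payload>") -> None:
    """Structural validation of one record JSON payload.

    Raises RecordSchemaError naming the first offending node.
    """
    if not isinstance(payload, dict):
        raise RecordSchemaError(f"{origin}: record must be an object")
    cid = payload.get("cid")
    if not isinstance(cid, int) or isinstance(cid, bool) or cid <= 0:
        raise RecordSchemaError(f"{origin}: 'cid' must be a positive integer")
    name = payload.get("name")
    if not isinstance(name, str) or not name.strip():
        raise RecordSchemaError(f"{origin}: 'name' must be a non-empty string")
    if "sections" not in payload:
        raise RecordSchemaError(f"{origin}: missing required 'sections' node")
    _validate_sections(payload["sections"], f"{origin}.sections")
    syns = payload.get("synonyms", [])
    if not isinstance(syns, list) or not all(isinstance(s, str) for s in syns):
        raise RecordSchemaError(f"{origin}: 'synonyms' must be a list of strings")


def _validate_sections(node: object, origin: str) -> None:
    if not isinstance(node, list):
        raise RecordSchemaError(f"{origin}: must be a list")
    for i, sec in enumerate(node):
        here = f"{origin}[{i}]"
        if not isinstance(sec, dict):
            raise RecordSchemaError(f"{here}: section must be an object")
        heading = sec.get("heading")
        if not isinstance(heading, str) or not heading.strip():
            raise RecordSchemaError(f"{here}: 'heading' must be a non-empty string")
        content = sec.get("content", [])
        if not isinstance(content, list) or not all(isinstance(c, str) for c in content):
            raise RecordSchemaError(f"{here}: 'content' must be a list of strings")
        _validate_sections(sec.get("children", []), f"{here}.children")


def record_from_payload(payload: dict, origin: str = "<payload>") -> CompoundRecord:
    validate_record_payload(payload, origin)
    return CompoundRecord(
        cid=payload["cid"],
        name=payload["name"],
        sections=_sections_from(payload["sections"]),
        synonyms=tuple(payload.get("synonyms", [])),
    )


def _sections_from(node: list) -> tuple[Section, ...]:
    return tuple(
        Section(
            heading=sec["heading"],
            content=tuple(sec.get("content", [])),
            children=_sections_from(sec.get("children", [])),
        )
        for sec in node
    )


def record_to_payload(record: CompoundRecord) -> dict:
    """Inverse of :func:`record_from_payload` (used by the on-disk cache)."""

    def dump(secs: tuple[Section, ...]) -> list:
        return [
            {
                "heading": s.heading,
                "content": list(s.content),
                "children": dump(s.children),
            }
            for s in secs
        ]

    return {
        "cid": record.cid,
        "name": record.name,
        "synonyms": list(record.synonyms),
        "sections": dump(record.sections),
    }


# ---------------------------------------------------------------------------
# Fixture store

class FixtureStore:
    """In-memory record source backed by a directory of JSON record files.

    Name resolution is case-insensitive, with a stereo-prefix-normalized
    fallback ("phenylalanine" finds a record filed as "L-phenylalanine").
    Duplicate names across files are all retained under that name, in
    sorted-file order.  Pure: identical queries return identical results.
    """

    def __init__(self, records: list[CompoundRecord]):
        self._by_cid: dict[int, CompoundRecord] = {}
        self._by_name: dict[str, list[int]] = {}
        self._by_norm: dict[str, list[int]] = {}
        for rec in records:
            self._by_cid[rec.cid] = rec
            for alias in (rec.name, *rec.synonyms):
                self._by_name.setdefault(casefold_name(alias), []).append(rec.cid)
                self._by_norm.setdefault(normalize_name(alias), []).append(rec.cid)

    def resolve_name(self, name: str) -> list[int]:
        if not name.strip():
            raise ValueError("name must be non-empty")
        hits = self._by_name.get(casefold_name(name))
        if hits is None:
            hits = self._by_norm.get(normalize_name(name))
        return list(dict.fromkeys(hits)) if hits else []

    def fetch_record(self, cid: int) -> CompoundRecord:
        if cid <= 0:
            raise ValueError("cid must be positive")
        try:
            return self._by_cid[cid]
        except KeyError:
            raise RecordNotFoundError(f"no record for cid {cid}") from None


def load_fixture_store(path: str | Path) -> FixtureStore:
    """Load every ``*.json`` record file under ``path`` into a FixtureStore.

    All files are validated before any is accepted; a load error lists
    every invalid file.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"fixture store directory not found: {root}")
    records: list[CompoundRecord] = []
    errors: list[str] = []
    for file in sorted(root.glob("*.json")):
        try:
            payload = json.loads(file.read_text(encoding="utf-8"))
            records.append(record_from_payload(payload, origin=file.name))
        except (json.JSONDecodeError, RecordSchemaError) as exc:
            errors.append(f"{file.name}: {exc}")
    if errors:
        raise RecordSchemaError(
            "invalid record files in store:\n  " + "\n  ".join(errors)
        )
    return FixtureStore(records)


# ---------------------------------------------------------------------------
# Live provider

class LiveProvider:
    """Rate-limited REST client for a public compound-record service.

    ``transport`` maps a URL to response bytes (default urllib); ``clock``
    and ``sleep`` exist so the >= 0.2 s inter-request spacing is testable
    with a fake clock and no real waiting.  Transient failures retry
    ``retries`` times with doubling backoff, then raise ProviderError;
    HTTP 404 raises RecordNotFoundError immediately.
    """

    def __init__(
        self,
        base_url: str,
        transport: Callable[[str], bytes] | None = None,
        clock: Callable[[], float] = time.monotonic,
        sleep: Callable[[float], None] = time.sleep,
        min_interval: float = MIN_REQUEST_INTERVAL,
        retries: int = 3,
        backoff: float = 0.5,
    ):
        self.base_url = base_url.rstrip("/")
        self._transport = transport or self._urllib_transport
        self._clock = clock
        self._sleep = sleep
        self._min_interval = min_interval
        self._retries = retries
        self._backoff = backoff
        self._last_request: float | None = None
        self.request_times: list[float] = []  # timestamps, for auditing

    @staticmethod
    def _urllib_transport(url: str) -> bytes:
        with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
            return resp.read()

    def _request(self, url: str) -> bytes:
        attempt = 0
        while True:
            # pacing: sleep a microsecond past the deadline so float
            # rounding can never leave the gap a hair short of the interval
            while self._last_request is not None:
                remaining = self._min_interval - (self._clock() - self._last_request)
                if remaining <= 0:
                    break
                self._sleep(remaining + 1e-6)
            self._last_request = self._clock()
            self.request_times.append(self._last_request)
            try:
                return self._transport(url)
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise RecordNotFoundError(f"404 for {url}") from exc
                err: Exception = exc
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                err = exc
            attempt += 1
            if attempt > self._retries:
                raise ProviderError(f"request failed after {attempt} attempts: {err}")
            self._sleep(self._backoff * (2 ** (attempt - 1)))

    def resolve_name(self, name: str) -> list[int]:
        if not name.strip():
            raise ValueError("name must be non-empty")
        quoted = urllib.parse.quote(name)
        url = f"{self.base_url}/compound/name/{quoted}/cids/JSON"
        try:
            payload = json.loads(self._request(url))
        except RecordNotFoundError:
            return []
        cids = payload.get("IdentifierList", {}).get("CID", [])
        if not isinstance(cids, list):
            raise ProviderError(f"malformed CID list for {name!r}")
        return [int(c) for c in cids]

    def fetch_record(self, cid: int) -> CompoundRecord:
        if cid <= 0:
            raise ValueError("cid must be positive")
        url = f"{self.base_url}/pug_view/data/compound/{cid}/JSON"
        raw = self._request(url)
        try:
            payload = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise RecordSchemaError(f"cid {cid}: response is not JSON") from exc
        return _record_from_pug_view(payload, cid)


def _record_from_pug_view(payload: dict, cid: int) -> CompoundRecord:
    """Translate a hierarchical Record/Section/Information payload into a
    CompoundRecord."""
    rec = payload.get("Record")
    if not isinstance(rec, dict):
        raise RecordSchemaError(f"cid {cid}: missing 'Record' node")
    name = rec.get("RecordTitle", f"CID {cid}")

    def walk(sections: list) -> tuple[Section, ...]:
        out = []
        for sec in sections or []:
            heading = sec.get("TOCHeading", "")
            if not heading:
                raise RecordSchemaError(f"cid {cid}: section without TOCHeading")
            content = []
            for info in sec.get("Information", []):
                value = info.get("Value", {})
                for swm in value.get("StringWithMarkup", []):
                    text = swm.get("String")
                    if text:
                        content.append(text)
            out.append(
                Section(
                    heading=heading,
                    content=tuple(content),
                    children=walk(sec.get("Section", [])),
                )
            )
        return tuple(out)

    return CompoundRecord(cid=cid, name=name, sections=walk(rec.get("Section", [])))


class JsonCache:
    """Pass-through on-disk cache: records fetched from the wrapped
    provider are stored as fixture-format JSON files, so a cache directory
    is itself a valid fixture store."""

    def __init__(self, provider: RecordSource, cache_dir: str | Path):
        self._provider = provider
        self._dir = Path(cache_dir)
        self._dir.mkdir(parents=True, exist_ok=True)

    def resolve_name(self, name: str) -> list[int]:
        return self._provider.resolve_name(name)

    def fetch_record(self, cid: int) -> CompoundRecord:
        path = self._dir / f"cid_{cid}.json"
        if path.exists():
            return record_from_payload(
                json.loads(path.read_text(encoding="utf-8")), origin=path.name
            )
        record = self._provider.fetch_record(cid)
        path.write_text(
            json.dumps(record_to_payload(record), indent=1, sort_keys=True),
            encoding="utf-8",
        )
        return record
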
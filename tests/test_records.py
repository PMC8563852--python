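"""Record providers: fixture store, schema validation, rate-limited live
client, and the not-found vs error distinction."""

from __future__ import annotations

import json
import urllib.error

import pytest

from toxscreen.records import (
    CompoundRecord,
    FixtureStore,
    JsonCache,
    LiveProvider,
    ProviderError,
    RecordNotFoundError,
    RecordSchemaError,
    Section,
    load_fixture_store,
    record_from_payload,
    record_to_payload,
    validate_record_payload,
)


class FakeClock:
    """Monotonic fake clock whose sleep() advances time instantly."""

    def __init__(self):
        self.now = 0.0

    def __call__(self):
        return self.now

    def sleep(self, seconds):
        self.now += seconds


def store_with(*records: CompoundRecord) -> FixtureStore:
    return FixtureStore(list(records))


class TestFixtureStore:
    def test_resolve_and_fetch(self, coumarin_record):
        store = store_with(coumarin_record)
        cids = store.resolve_name("coumarin")
        assert cids == [323]
        assert store.fetch_record(323) is coumarin_record

    def test_case_insensitive(self, coumarin_record):
        store = store_with(coumarin_record)
        assert store.resolve_name("COUMARIN") == [323]

    def test_nonexistent_name_is_empty_not_error(self, coumarin_record):
        store = store_with(coumarin_record)
        assert store.resolve_name("zzz-nonexistent") == []

    def test_stereo_prefix_normalization(self):
        rec = CompoundRecord(cid=5, name="L-phenylalanine")
        store = store_with(rec)
        assert store.resolve_name("phenylalanine") == [5]
        assert store.resolve_name("DL-Phenylalanine") == [5]

    def test_duplicate_names_both_retained(self):
        a = CompoundRecord(cid=1, name="dupol")
        b = CompoundRecord(cid=2, name="dupol")
        store = store_with(a, b)
        assert store.resolve_name("dupol") == [1, 2]

    def test_unknown_cid_raises_not_found(self, coumarin_record):
        store = store_with(coumarin_record)
        with pytest.raises(RecordNotFoundError):
            store.fetch_record(999)

    def test_pure_repeated_queries(self, coumarin_record):
        store = store_with(coumarin_record)
        assert [store.resolve_name("coumarin") for _ in range(3)] == [[323]] * 3


class TestLoadFixtureStore:
    def test_loads_valid_directory(self, tmp_path, valid_payload):
        (tmp_path / "testol.json").write_text(json.dumps(valid_payload))
        store = load_fixture_store(tmp_path)
        assert store.resolve_name("testol") == [42]
        # synonym is indexed too
        assert store.resolve_name("L-testol") == [42]

    def test_empty_directory_resolves_nothing(self, tmp_path):
        store = load_fixture_store(tmp_path)
        assert store.resolve_name("anything") == []

    def test_invalid_file_listed_in_error(self, tmp_path, valid_payload):
        (tmp_path / "good.json").write_text(json.dumps(valid_payload))
        bad = dict(valid_payload)
        del bad["sections"]
        (tmp_path / "bad.json").write_text(json.dumps(bad))
        with pytest.raises(RecordSchemaError, match="bad.json"):
            load_fixture_store(tmp_path)


class TestRecordSchema:
    def test_missing_sections_node(self, valid_payload):
        del valid_payload["sections"]
        with pytest.raises(RecordSchemaError, match="sections"):
            validate_record_payload(valid_payload)

    @pytest.mark.parametrize(
        "mutate,fragment",
        [
            (lambda p: p.update(cid=0), "cid"),
            (lambda p: p.update(cid="42"), "cid"),
            (lambda p: p.update(name=""), "name"),
            (lambda p: p["sections"][0].update(heading=""), "heading"),
            (lambda p: p["sections"][0].update(content=[1, 2]), "content"),
        ],
    )
    def test_offending_node_named(self, valid_payload, mutate, fragment):
        mutate(valid_payload)
        with pytest.raises(RecordSchemaError, match=fragment):
            validate_record_payload(valid_payload)

    def test_payload_round_trip(self, valid_payload):
        rec = record_from_payload(valid_payload)
        assert record_from_payload(record_to_payload(rec)) == rec


class TestLiveProviderRateLimit:
    def _provider(self, responses):
        clock = FakeClock()
        calls = []

        def transport(url):
            calls.append(url)
            resp = responses[min(len(calls), len(responses)) - 1]
            if isinstance(resp, Exception):
                raise resp
            return resp

        provider = LiveProvider(
            "https://example.test/rest",
            transport=transport,
            clock=clock,
            sleep=clock.sleep,
        )
        return provider, clock, calls

    def test_consecutive_requests_spaced(self):
        """Successive requests are at least a fifth of a second apart."""
        body = json.dumps({"IdentifierList": {"CID": [1]}}).encode()
        provider, clock, _ = self._provider([body])
        for _ in range(5):
            provider.resolve_name("anything")
        times = provider.request_times
        assert len(times) == 5
        assert all(b - a >= 0.2 for a, b in zip(times, times[1:]))

    def test_no_artificial_delay_when_already_spaced(self):
        body = json.dumps({"IdentifierList": {"CID": [1]}}).encode()
        provider, clock, _ = self._provider([body])
        provider.resolve_name("a")
        clock.now += 10.0
        t0 = clock.now
        provider.resolve_name("b")
        assert provider.request_times[-1] == pytest.approx(t0)

    def test_404_is_not_found_not_error(self):
        err = urllib.error.HTTPError("u", 404, "not found", {}, None)
        provider, _, _ = self._provider([err])
        assert provider.resolve_name("ghostol") == []

    def test_transient_failure_retries_then_errors(self):
        err = urllib.error.URLError("connection refused")
        provider, _, calls = self._provider([err])
        with pytest.raises(ProviderError):
            provider.resolve_name("x")
        assert len(calls) == 4  # initial attempt + 3 retries

    def test_retry_recovers(self):
        body = json.dumps({"IdentifierList": {"CID": [9]}}).encode()
        provider, _, _ = self._provider(
            [urllib.error.URLError("flaky"), body]
        )
        assert provider.resolve_name("x") == [9]

    def test_fetch_record_parses_hierarchical_payload(self):
        payload = {
            "Record": {
                "RecordTitle": "coumarin",
                "Section": [
                    {
                        "TOCHeading": "Safety and Hazards",
                        "Section": [
                            {
                                "TOCHeading": "GHS Classification",
                                "Information": [
                                    {"Value": {"StringWithMarkup": [{"String": "H302"}]}}
                                ],
                            }
                        ],
                    }
                ],
            }
        }
        provider, _, _ = self._provider([json.dumps(payload).encode()])
        rec = provider.fetch_record(323)
        assert rec.sections[0].children[0].heading == "GHS Classification"
        assert rec.sections[0].children[0].content == ("H302",)


class TestJsonCache:
    def test_cache_dir_is_a_valid_fixture_store(self, tmp_path, coumarin_record):
        inner = store_with(coumarin_record)
        cache = JsonCache(inner, tmp_path / "cache")
        assert cache.fetch_record(323) == coumarin_record
        # second fetch served from disk; directory loads as a fixture store
        assert cache.fetch_record(323) == coumarin_record
        reloaded = load_fixture_store(tmp_path / "cache")
        assert reloaded.fetch_record(323) == coumarin_record
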
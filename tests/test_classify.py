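"""Record scanning, hazard-code extraction and severity classification."""

from __future__ import annotations

import itertools

import pytest

from toxscreen.classify import (
    MAPPED_CODES,
    CandidateOutcome,
    KeywordConfig,
    classify,
    classify_compound,
    extract_hazard_codes,
    format_toxic_report,
    scan_record,
)
from toxscreen.formula import FormulaMatch, parse_formula
from toxscreen.io import AssignedFormula, ReportRow, ToxicTableEntry
from toxscreen.records import CompoundRecord, FixtureStore, Section
from toxscreen.taxonomy import Family

# ---------------------------------------------------------------------------
# Independent severity oracle: an explicit ordered list of every possible
# outcome, scanned most-severe-first.  Shares no code with the classifier.

_ORACLE_ORDER = [
    ("Acute toxic", 1), ("Acute toxic", 2), ("Acute toxic", 3),
    ("Acute toxic", 4), ("Acute toxic", 5),
    ("Skin and eye irritant", 1), ("Skin and eye irritant", 2),
    ("Eye irritant", 1), ("Eye irritant", 2),
    ("Skin irritant", 1), ("Skin irritant", 2),
    ("Potentially toxic", None),
]

_ORACLE_ACUTE = {
    "H300": 2, "H310": 2, "H330": 2, "H301": 3, "H311": 3, "H331": 3,
    "H302": 4, "H312": 4, "H332": 4, "H303": 5, "H313": 5, "H333": 5,
}
_ORACLE_SKIN = {"H315": 2}
_ORACLE_EYE = {"H318": 1, "H319": 2}


def oracle_label(codes: set[str]) -> str:
    possible = set()
    for c in codes:
        if c in _ORACLE_ACUTE:
            possible.add(("Acute toxic", _ORACLE_ACUTE[c]))
        if c in _ORACLE_SKIN:
            possible.add(("Skin irritant", _ORACLE_SKIN[c]))
        if c in _ORACLE_EYE:
            possible.add(("Eye irritant", _ORACLE_EYE[c]))
    skin_levels = [_ORACLE_SKIN[c] for c in codes if c in _ORACLE_SKIN]
    eye_levels = [_ORACLE_EYE[c] for c in codes if c in _ORACLE_EYE]
    if skin_levels and eye_levels:
        possible.add(("Skin and eye irritant", min(skin_levels + eye_levels)))
        # the combined family supersedes its two constituents
        possible = {
            p for p in possible if p[0] not in ("Skin irritant", "Eye irritant")
        }
    if not possible:
        return "Potentially toxic"
    for fam, level in _ORACLE_ORDER:
        if (fam, level) in possible:
            return f"{fam} {level}" if level else fam
    raise AssertionError("unreachable")


def oracle_rank(codes: set[str]) -> int:
    lbl = oracle_label(codes)
    for i, (fam, level) in enumerate(_ORACLE_ORDER):
        if lbl == (f"{fam} {level}" if level else fam):
            return len(_ORACLE_ORDER) - i
    raise AssertionError(lbl)


# 11 codes -> 2048 subsets for exhaustive oracle comparison
_ORAL_AND_IRRITANT = (
    "H300", "H301", "H302", "H303",
    "H310", "H311", "H312", "H313",
    "H315", "H318", "H319",
)


def all_subsets(codes):
    for r in range(len(codes) + 1):
        yield from (set(c) for c in itertools.combinations(codes, r))


class TestScanRecord:
    def test_ghs_heading_matched(self, coumarin_record):
        fields = scan_record(coumarin_record)
        assert any("GHS" in h for h, _ in fields.tox_sections)

    def test_physical_only_record_is_empty(self, bland_record):
        assert scan_record(bland_record).empty

    def test_food_heading_collected(self):
        rec = CompoundRecord(
            cid=1, name="x",
            sections=(Section("Food Additives and Ingredients", ("ok",)),),
        )
        fields = scan_record(rec)
        assert fields.food_sections and not fields.tox_sections

    def test_nested_sections_found_depth_first(self, coumarin_record):
        # H302 sits two levels deep under Safety and Hazards
        fields = scan_record(coumarin_record)
        headings = [h for h, _ in fields.tox_sections]
        assert "Safety and Hazards" in headings
        assert "GHS Classification" in headings

    def test_custom_keywords(self, bland_record):
        kw = KeywordConfig(toxicity=("melting",), food=())
        assert not scan_record(bland_record, kw).empty


class TestExtractHazardCodes:
    def test_single_code_with_context(self, coumarin_record):
        fields = scan_record(coumarin_record)
        assert extract_hazard_codes(fields) == {"H302"}

    def test_multiple_codes_in_one_line(self):
        rec = CompoundRecord(
            cid=1, name="x",
            sections=(Section("GHS Classification", ("H315 ... H319",)),),
        )
        assert extract_hazard_codes(scan_record(rec)) == {"H315", "H319"}

    def test_exactly_three_digits(self):
        rec = CompoundRecord(
            cid=1, name="x",
            sections=(Section("Hazard", ("H31 H3020 EC2H315x H318",)),),
        )
        # H31 too short; H3020 has a fourth digit; H315 embedded mid-token
        # still counts (exactly three digits follow the H); H318 plain
        assert extract_hazard_codes(scan_record(rec)) == {"H315", "H318"}

    def test_food_sections_carry_no_codes(self):
        rec = CompoundRecord(
            cid=1, name="x",
            sections=(Section("Food Additives", ("H302 mentioned in food context",)),),
        )
        assert extract_hazard_codes(scan_record(rec)) == set()


class TestClassify:
    @pytest.mark.parametrize(
        "codes,label",
        [
            ({"H302"}, "Acute toxic 4"),
            ({"H315", "H319"}, "Skin and eye irritant 2"),
            (set(), "Potentially toxic"),
            ({"H301", "H315", "H319"}, "Acute toxic 3"),
            ({"H319"}, "Eye irritant 2"),
            ({"H315"}, "Skin irritant 2"),
            ({"H318"}, "Eye irritant 1"),
            ({"H300"}, "Acute toxic 2"),
            ({"H330", "H303"}, "Acute toxic 2"),
            ({"H315", "H318"}, "Skin and eye irritant 1"),
        ],
    )
    def test_labels(self, codes, label):
        assert classify(codes).label == label

    def test_unknown_codes_ignored_never_fatal(self):
        assert classify({"H999", "H302"}).label == "Acute toxic 4"
        assert classify({"H999"}).label == "Potentially toxic"

    def test_evidence_recorded(self):
        result = classify({"H315", "H319"})
        assert set(result.evidence) == {"H315", "H319"}

    def test_exhaustive_oracle_equivalence(self):
        """classify agrees with the independent severity oracle on every
        subset of an 11-code set (2048 subsets)."""
        for codes in all_subsets(_ORAL_AND_IRRITANT):
            assert classify(codes).label == oracle_label(codes), codes

    def test_monotone_in_code_set(self):
        """Adding hazard codes can never decrease severity."""
        codes_list = list(all_subsets(("H302", "H311", "H315", "H318", "H319")))
        for a in codes_list:
            rank_a = classify(a).rank
            for extra in ("H300", "H313", "H315", "H319", "H318", "H331"):
                assert classify(a | {extra}).rank >= rank_a


class TestClassifyCompound:
    @staticmethod
    def _match(*names, formula="C9H6O2"):
        key = parse_formula(formula)
        assigned = AssignedFormula(
            formula=key, neutral_mass=146.0368, abundance=1e5,
            retention_time=1.0, ion_mode="negative",
        )
        candidates = tuple(
            ToxicTableEntry(name=n, formula=key, monoisotopic_mass=146.0368)
            for n in names
        )
        return FormulaMatch(assigned=assigned, candidates=candidates)

    def test_classified_route(self, coumarin_record):
        store = FixtureStore([coumarin_record])
        (outcome,) = classify_compound(self._match("coumarin"), store)
        assert outcome.status == "classified"
        assert outcome.classification.label == "Acute toxic 4"

    def test_unfound_route(self, coumarin_record):
        store = FixtureStore([coumarin_record])
        (outcome,) = classify_compound(self._match("ghostol"), store)
        assert outcome.status == "unfound"

    def test_unchecked_route(self, bland_record):
        store = FixtureStore([bland_record])
        (outcome,) = classify_compound(self._match("blandine"), store)
        assert outcome.status == "unchecked"

    def test_max_severity_across_multiple_records(self):
        mild = CompoundRecord(
            cid=1, name="dupol",
            sections=(Section("GHS Classification", ("H319",)),),
        )
        severe = CompoundRecord(
            cid=2, name="dupol",
            sections=(Section("GHS Classification", ("H301",)),),
        )
        store = FixtureStore([mild, severe])
        (outcome,) = classify_compound(self._match("dupol"), store)
        assert outcome.classification.label == "Acute toxic 3"

    def test_every_candidate_gets_an_outcome(self, coumarin_record, bland_record):
        store = FixtureStore([coumarin_record, bland_record])
        outcomes = classify_compound(
            self._match("coumarin", "blandine", "ghostol"), store
        )
        assert [o.status for o in outcomes] == ["classified", "unchecked", "unfound"]


class TestFormatToxicReport:
    rows = [
        ReportRow(name="coumarin", classification="Acute toxic 4", evidence="H302"),
        ReportRow(name="anisol", classification="Acute toxic 4", evidence="H302"),
        ReportRow(name="citric acid", classification="Skin and eye irritant 2"),
    ]

    def test_grouped_in_severity_order(self, tmp_path):
        p = format_toxic_report(self.rows, tmp_path / "f.csv")
        lines = p.read_text().splitlines()
        cats = [line.split(",")[0] for line in lines[1:]]
        assert cats == ["Acute toxic", "Acute toxic", "Skin and eye irritant"]

    def test_empty_input_header_only(self, tmp_path):
        p = format_toxic_report([], tmp_path / "f.csv")
        assert len(p.read_text().splitlines()) == 1

    def test_deterministic(self, tmp_path):
        a = format_toxic_report(self.rows, tmp_path / "a.csv")
        b = format_toxic_report(list(reversed(self.rows)), tmp_path / "b.csv")
        assert a.read_bytes() == b.read_bytes()
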
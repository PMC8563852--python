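"""Shared fixtures: small synthetic scenarios and record payloads."""

from __future__ import annotations

import pytest

from toxscreen import fixtures as fx
from toxscreen.records import CompoundRecord, Section, record_from_payload


@pytest.fixture(scope="session")
def table3_run(tmp_path_factory):
    """The bundled eight-compound validation scenario on disk."""
    root = tmp_path_factory.mktemp("table3")
    return fx.table3_fixture(root)


@pytest.fixture
def coumarin_record() -> CompoundRecord:
    """A coumarin record with H302 nested under Safety and Hazards."""
    return CompoundRecord(
        cid=323,
        name="coumarin",
        sections=(
            Section("Names and Identifiers", ("Molecular Formula: C9H6O2",)),
            Section(
                "Safety and Hazards",
                (),
                (
                    Section(
                        "GHS Classification",
                        ("H302 (100%): Harmful if swallowed",),
                    ),
                ),
            ),
        ),
    )


@pytest.fixture
def bland_record() -> CompoundRecord:
    """A record with only physical-property sections (no hazard evidence)."""
    return CompoundRecord(
        cid=7,
        name="blandine",
        sections=(
            Section("Melting Point", ("123 C",)),
            Section("Solubility", ("soluble in water",)),
        ),
    )


@pytest.fixture
def valid_payload() -> dict:
    return {
        "cid": 42,
        "name": "testol",
        "synonyms": ["L-testol"],
        "sections": [
            {
                "heading": "Safety and Hazards",
                "content": [],
                "children": [
                    {"heading": "GHS Classification", "content": ["H319"], "children": []}
                ],
            }
        ],
    }
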
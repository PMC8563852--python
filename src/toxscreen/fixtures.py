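"""Synthetic fixtures: toxic tables, assigned-formula samples with planted
toxic compounds, and JSON record stores with controllable hazard codes.

The generators emulate the interchange surface of the upstream stages so
the whole screening pipeline is exercisable with no download:

* background formulas are random CHNO compositions constrained to
  chemically plausible H/C ratios (0.3-3.0, echoing the assignment
  stage's own elemental-ratio constraint), with masses computed from
  element counts so every generated row passes the mass/formula
  consistency check;
* abundances are log-uniform (peak areas span decades), retention times
  uniform on the 0-70 min gradient of the reference LC method;
* decoy toxic-table entries never collide with background formulas, so a
  synthetic run has zero false-positive matches by construction;
* record JSON files embed the requested hazard codes inside a "GHS
  Classification" section surrounded by distractor sections; compounds
  flagged record-absent get no file, exercising the unfound path.

``table3_fixture`` bundles the eight-compound validation set whose
classifications the screening stage is expected to reproduce.

All generators are deterministic under ``FixtureSpec.seed``.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .elements import monoisotopic_mass
from .formula import FormulaKey, hill_format, parse_formula

MODES = ("positive", "negative")

_GHS_PHRASE = {
    "H300": "Fatal if swallowed",
    "H301": "Toxic if swallowed",
    "H302": "Harmful if swallowed",
    "H303": "May be harmful if swallowed",
    "H310": "Fatal in contact with skin",
    "H311": "Toxic in contact with skin",
    "H312": "Harmful in contact with skin",
    "H313": "May be harmful in contact with skin",
    "H315": "Causes skin irritation",
    "H318": "Causes serious eye damage",
    "H319": "Causes serious eye irritation",
    "H330": "Fatal if inhaled",
    "H331": "Toxic if inhaled",
    "H332": "Harmful if inhaled",
    "H333": "May be harmful if inhaled",
}


@dataclass(frozen=True)
class PlantedCompound:
    """One compound deliberately planted into a synthetic run.

    ``record`` controls the record store: "ghs" writes a record whose GHS
    section carries ``hazard_codes`` (with a bare toxicology heading when
    the code set is empty, so classification yields "Potentially toxic");
    "plain" writes a record with only physical-property sections (routes
    to "unchecked"); "absent" writes no record (routes to "unfound").
    ``record_name`` lets the store file the compound under a variant name
    (e.g. a stereo-prefixed synonym) to exercise name normalization.
    """

    name: str
    formula: str
    hazard_codes: tuple[str, ...] = ()
    present_in_modes: tuple[str, ...] = MODES
    record: str = "ghs"  # ghs | plain | absent
    record_name: str | None = None

    def __post_init__(self) -> None:
        if self.record not in ("ghs", "plain", "absent"):
            raise ValueError(f"bad record kind {self.record!r}")
        for m in self.present_in_modes:
            if m not in MODES:
                raise ValueError(f"bad mode {m!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic screening scenario."""

    planted: tuple[PlantedCompound, ...]
    n_background_formulas: int = 50
    n_table_decoys: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.planted]
        if len(names) != len(set(names)):
            raise ValueError("planted compound names must be unique")


def _random_chno(rng: random.Random) -> dict[str, int]:
    """One random CHNO composition with H/C in [0.3, 3.0]."""
    c = rng.randint(5, 40)
    h = rng.randint(max(2, int(0.3 * c)), max(3, int(3.0 * c)))
    n = rng.randint(0, 3)
    o = rng.randint(0, 12)
    counts = {"C": c, "H": h}
    if n:
        counts["N"] = n
    if o:
        counts["O"] = o
    return counts


def background_formulas(
    seed: int, n: int, avoid: frozenset[str] = frozenset()
) -> list[FormulaKey]:
    """``n`` distinct random CHNO formulas, none in ``avoid`` (canonical
    strings).  Deterministic under ``seed``."""
    rng = random.Random(seed)
    out: list[FormulaKey] = []
    seen = set(avoid)
    while len(out) < n:
        counts = _random_chno(rng)
        canonical = hill_format(counts)
        if canonical in seen:
            continue  # collision: regenerate, never emit
        seen.add(canonical)
        out.append(parse_formula(canonical))
    return out


def _planted_canonicals(spec: FixtureSpec) -> frozenset[str]:
    return frozenset(parse_formula(p.formula).canonical for p in spec.planted)


def gen_toxic_table(
    spec: FixtureSpec, path: str | Path, extra_avoid: frozenset[str] = frozenset()
) -> Path:
    """Write the local toxic-compound table: every planted compound plus
    ``n_table_decoys`` random CHNO formulas that collide with neither the
    background set nor ``extra_avoid``."""
    planted_keys = _planted_canonicals(spec)
    background = {
        k.canonical
        for k in background_formulas(spec.seed, spec.n_background_formulas, planted_keys)
    }
    avoid = planted_keys | background | extra_avoid
    decoys = background_formulas(spec.seed + 999983, spec.n_table_decoys, frozenset(avoid))
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["name", "formula", "monoisotopic_mass", "source", "safety_class"])
        for p in spec.planted:
            key = parse_formula(p.formula)
            writer.writerow(
                [p.name, key.canonical, f"{monoisotopic_mass(key.count_map):.6f}", "OpenFoodTox", ""]
            )
        for i, key in enumerate(decoys):
            writer.writerow(
                [f"decoy-{i:03d}", key.canonical, f"{monoisotopic_mass(key.count_map):.6f}", "TPPT", ""]
            )
    return path


def gen_sample(spec: FixtureSpec, mode: str, path: str | Path) -> Path:
    """Write one assigned-formula CSV for the given ESI mode.

    Contains the background formulas plus every planted compound whose
    ``present_in_modes`` includes ``mode``.  Masses are computed from the
    element counts, never sampled, so every row is mass-consistent.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    planted_keys = _planted_canonicals(spec)
    background = background_formulas(spec.seed, spec.n_background_formulas, planted_keys)
    # str hash() is salted per process; derive the per-mode stream arithmetically
    rng = random.Random(spec.seed * 2 + MODES.index(mode) + 12345)
    rows: list[FormulaKey] = list(background)
    seen = set()
    for p in spec.planted:
        if mode in p.present_in_modes:
            key = parse_formula(p.formula)
            if key.canonical not in seen:  # isomeric plants share one feature
                seen.add(key.canonical)
                rows.append(key)
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["formula", "exp_mass", "abundance", "RT"])
        for key in rows:
            mass = monoisotopic_mass(key.count_map)
            abundance = 10 ** rng.uniform(4.0, 9.0)
            rt = rng.uniform(0.0, 70.0)
            writer.writerow([key.canonical, f"{mass:.6f}", f"{abundance:.3f}", f"{rt:.3f}"])
    return path


def _record_payload(p: PlantedCompound, cid: int) -> dict:
    name = p.record_name or p.name
    key = parse_formula(p.formula)
    identifiers = {
        "heading": "Names and Identifiers",
        "content": [f"Molecular Formula: {key.canonical}"],
        "children": [],
    }
    physical = {
        "heading": "Chemical and Physical Properties",
        "content": [],
        "children": [
            {"heading": "Melting Point", "content": ["not determined"], "children": []},
            {
                "heading": "Solubility",
                "content": ["soluble in water"],
                "children": [],
            },
        ],
    }
    sections = [identifiers, physical]
    if p.record == "ghs":
        ghs_lines = [
            f"{code} ({100 - 5 * i}%): {_GHS_PHRASE.get(code, 'Hazard statement')}"
            for i, code in enumerate(p.hazard_codes)
        ]
        safety_children = []
        if ghs_lines:
            safety_children.append(
                {"heading": "GHS Classification", "content": ghs_lines, "children": []}
            )
        else:
            safety_children.append(
                {
                    "heading": "Toxicological Information",
                    "content": ["No acute hazard statements on file for this substance."],
                    "children": [],
                }
            )
        sections.append(
            {"heading": "Safety and Hazards", "content": [], "children": safety_children}
        )
        sections.append(
            {
                "heading": "Food Additives and Ingredients",
                "content": ["Evaluated for use in food."],
                "children": [],
            }
        )
    synonyms = [p.name] if p.record_name else []
    return {"cid": cid, "name": name, "synonyms": synonyms, "sections": sections}


def gen_record_store(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write one JSON record file per planted compound (except the
    record-absent ones) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(spec.planted):
        if p.record == "absent":
            continue
        payload = _record_payload(p, cid=1001 + i)
        fname = "".join(ch if ch.isalnum() else "_" for ch in p.name.lower()) + ".json"
        (out / fname).write_text(
            json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
        )
    return out


@dataclass(frozen=True)
class RunPaths:
    """Paths of one generated screening scenario on disk."""

    toxic_table: Path
    store_dir: Path
    sample_dirs: tuple[Path, ...]


def gen_run(spec: FixtureSpec, out_dir: str | Path, n_samples: int = 1) -> RunPaths:
    """Generate a complete runnable scenario: toxic table, record store and
    ``n_samples`` sample directories each holding a pos and a neg CSV.

    Sample ``k`` derives its background from ``seed + k`` so samples share
    the planted compounds but differ in background; decoys avoid every
    sample's background.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    planted_keys = _planted_canonicals(spec)
    sample_specs = [
        FixtureSpec(
            planted=spec.planted,
            n_background_formulas=spec.n_background_formulas,
            n_table_decoys=spec.n_table_decoys,
            seed=spec.seed + k,
        )
        for k in range(n_samples)
    ]
    all_background = frozenset(
        key.canonical
        for s in sample_specs
        for key in background_formulas(s.seed, s.n_background_formulas, planted_keys)
    )
    table = gen_toxic_table(spec, out / "toxic_table.csv", extra_avoid=all_background)
    store = gen_record_store(spec, out / "store")
    sample_dirs = []
    for k, s in enumerate(sample_specs, start=1):
        sdir = out / f"sample_{k:02d}"
        sdir.mkdir(exist_ok=True)
        gen_sample(s, "positive", sdir / "assigned_pos.csv")
        gen_sample(s, "negative", sdir / "assigned_neg.csv")
        sample_dirs.append(sdir)
    return RunPaths(toxic_table=table, store_dir=store, sample_dirs=tuple(sample_dirs))


# ---------------------------------------------------------------------------
# The eight-compound validation set

TABLE3_PLANTED: tuple[PlantedCompound, ...] = (
    PlantedCompound("3-methoxybenzaldehyde", "C8H8O2", ("H315", "H319"),
                    present_in_modes=("positive",)),
    PlantedCompound("4-methoxybenzaldehyde", "C8H8O2", ("H302",),
                    present_in_modes=("positive",)),
    PlantedCompound("coumarin", "C9H6O2", ("H302",),
                    present_in_modes=("negative",)),
    PlantedCompound("glutamic acid", "C5H9NO4", (),
                    present_in_modes=("negative",), record_name="L-glutamic acid"),
    PlantedCompound("phenylalanine", "C9H11NO2", ("H319",),
                    present_in_modes=("positive",), record_name="L-phenylalanine"),
    PlantedCompound("citric acid", "C6H8O7", ("H315", "H319"),
                    present_in_modes=("negative",)),
    PlantedCompound("aspartic acid", "C4H7NO4", (),
                    present_in_modes=("negative",), record_name="L-aspartic acid"),
    PlantedCompound("naringin", "C27H32O14", ("H315", "H319"),
                    present_in_modes=("negative",)),
)

#: Classification label each validation compound must receive.
TABLE3_EXPECTED: dict[str, str] = {
    "3-methoxybenzaldehyde": "Skin and eye irritant 2",
    "4-methoxybenzaldehyde": "Acute toxic 4",
    "coumarin": "Acute toxic 4",
    "glutamic acid": "Potentially toxic",
    "phenylalanine": "Eye irritant 2",
    "citric acid": "Skin and eye irritant 2",
    "aspartic acid": "Potentially toxic",
    "naringin": "Skin and eye irritant 2",
}


def table3_spec(seed: int = 1913) -> FixtureSpec:
    """FixtureSpec bundling the eight validation compounds with a small
    random background."""
    return FixtureSpec(
        planted=TABLE3_PLANTED,
        n_background_formulas=12,
        n_table_decoys=4,
        seed=seed,
    )


def table3_fixture(out_dir: str | Path, seed: int = 1913) -> RunPaths:
    """Generate the bundled validation scenario: the eight compounds split
    across both ESI modes of one sample, their record store, and a toxic
    table containing all of them."""
    return gen_run(table3_spec(seed), out_dir, n_samples=1)
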
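# toxscreen

Non-targeted toxin screening for LC/MS data: given molecular formulas
assigned to high-resolution mass-spectrometry features, `toxscreen` flags
the ones that could belong to known toxic compounds and tells you how bad
they are.

It is the filtering stage of an open-source screening toolchain for
alternative and resilient foods (leaf concentrate, agricultural residues,
and similar): peak picking and formula assignment happen upstream with
existing tools; `toxscreen` takes the assigned-formula CSVs those tools
write and produces severity-ranked screening reports, with no commercial
software and — in its default fixture-provider mode — no network access.

## What it does

For each sample (run in both ESI polarities):

1. **Match** — every assigned neutral formula is canonicalized to Hill
   notation (C, H, then other elements alphabetically) and matched by
   exact element counts against a local toxic-compound table in an
   OpenFoodTox/TPPT-like schema. Isomers sharing a formula are all kept
   as candidates: a formula match carries no structural information, so
   every hit is tentative by construction.
2. **Retrieve** — each candidate name is resolved to compound identifiers
   and its full hierarchical record fetched, either from a local JSON
   record store (default) or from a rate-limited live REST provider
   (requests spaced ≥ 0.2 s, retried with backoff). Lookup is
   case-insensitive with stereo-prefix fallback, so "phenylalanine" finds
   a record filed as "L-phenylalanine".
3. **Classify** — the record's toxicity/food-safety sections are scanned
   for GHS hazard-statement codes (`H` + three digits), and the compound
   is placed in one of five severity-ordered families, keeping the
   highest severity:

   | family | produced by | example label |
   |---|---|---|
   | Acute toxic (cat. 1–5) | H300–H303, H310–H313, H330–H333 | `Acute toxic 4` |
   | Skin and eye irritant | H315 together with H318/H319 | `Skin and eye irritant 2` |
   | Eye irritant | H318 (cat. 1) or H319 (cat. 2) | `Eye irritant 2` |
   | Skin irritant | H315 | `Skin irritant 2` |
   | Potentially toxic | listed in a hazards database, no mapped code | `Potentially toxic` |

   A compound with no record is **unfound** (and is then checked against a
   local table of previously hand-resolved names); a record with no
   toxicity or food-safety sections at all is **unchecked**.
4. **Merge** — per-mode results combine per sample, then per-sample
   results merge across samples (a union join on the normalized compound
   name) — once each for the toxic, unfound and unchecked data — and the
   merged toxic table gets a final formatting pass grouped by family.

## Worked example

Generate a complete synthetic scenario (toxic table, JSON record store,
two samples with pos/neg assigned-formula CSVs) and screen it:

```sh
toxscreen gen-fixtures --out fixture --samples 2
cat > run.yaml <<EOF
samples:
  - fixture/sample_01
  - fixture/sample_02
toxic_table: fixture/toxic_table.csv
store: fixture/store
output: out
EOF
toxscreen run --config run.yaml
```

which prints:

```
config: provider=fixture merge=outer
toxic table: 12 entries from toxic_table.csv
[sample_01/positive] features=14 matched=2 unmatched=12 candidates=3
[sample_01/negative] features=17 matched=5 unmatched=12 candidates=5
[sample_01] toxic=8 unchecked=0 unfound=0 locally_matched=0
[sample_02/positive] features=14 matched=2 unmatched=12 candidates=3
[sample_02/negative] features=17 matched=5 unmatched=12 candidates=5
[sample_02] toxic=8 unchecked=0 unfound=0 locally_matched=0
merged toxic: 8 compounds across 2 samples
merged unfound: 0 compounds across 2 samples
merged unchecked: 0 compounds across 2 samples
formatted toxic report written
outputs written under out
```

Per mode, most features are background formulas that match nothing in the
toxic table (`unmatched=12`); the two positive-mode matches yield three
candidates because one formula, C8H8O2, is shared by two isomeric table
entries. The merged toxic report ranks everything by severity:

```
name,formula,classification,evidence,samples,modes
4-methoxybenzaldehyde,C8H8O2,Acute toxic 4,H302,sample_01;sample_02,positive
coumarin,C9H6O2,Acute toxic 4,H302,sample_01;sample_02,negative
3-methoxybenzaldehyde,C8H8O2,Skin and eye irritant 2,H315;H319,sample_01;sample_02,positive
citric acid,C6H8O7,Skin and eye irritant 2,H315;H319,sample_01;sample_02,negative
...
```

`evidence` lists the hazard codes that produced the label, and the
`samples`/`modes` columns say where the compound was seen. The default
scenario is the bundled eight-compound validation set — anisaldehydes,
coumarin, amino acids, citric acid and naringin — whose expected labels
ship in `toxscreen.fixtures.TABLE3_EXPECTED`.

The same pipeline is available as a library:

```python
from toxscreen import fixtures as fx
from toxscreen.pipeline import RunConfig, run_pipeline

paths = fx.table3_fixture("fixture")
result = run_pipeline(RunConfig(
    sample_dirs=list(paths.sample_dirs),
    toxic_table_path=paths.toxic_table,
    output_root="out",
    store_path=paths.store_dir,
))
for row in result.merged["toxic"].rows:
    print(row.name, "->", row.classification)
```

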
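# Methods

## Scope and model

`toxscreen` is a suspect-screening filter, not an identification engine.
Its input is the output of a molecular-formula assignment stage: neutral
monoisotopic formulas with mass, abundance and retention-time metadata.
Its claim per compound is deliberately weak — "a compound with this
elemental composition is listed in a hazards database with these GHS
hazard statements" — because an elemental composition alone cannot
distinguish isomers. All matches are tentative; confirmation requires
orthogonal evidence (retention time against standards, fragmentation).
The tool therefore keeps every isomeric candidate of a matched formula
and lets each proceed independently to record retrieval and
classification.

The screening partitions each sample's matched candidates into four
disjoint sets:

* **toxic** — a record was found and contained toxicity or food-safety
  sections; classified into one of five severity families;
* **unchecked** — a record was found but contained no such sections, so
  nothing can be said either way;
* **locally matched** — no public record, but the name appears in a local
  table of previously hand-resolved compounds, whose recorded safety
  class is carried through;
* **unfound** — no record anywhere; written out so the list can be
  curated into the local table.

## Formula matching

Formulas are compared on element-count maps, canonicalized to Hill
notation. Matching is exact: no mass-tolerance fallback exists, because
the upstream assignment stage already resolved mass to formula under its
own ppm error model, and re-introducing a mass window here would only
re-admit the ambiguity that stage removed. Inputs are treated as neutral
formulas; an optional ion-form adjustment (`ion_adjust=
"deprotonated"|"protonated"`) exists for users feeding raw ion formulas,
and defaults off.

The supported element set is C, H, N, O, S, P, Cl with monoisotopic
masses embedded as a single constant table (C = 12.000000,
H = 1.0078250319, N = 14.0030740052, O = 15.9949146221, S = 31.97207069,
P = 30.97376151, Cl = 34.96885271) shared by the parser, the
mass/formula consistency check and the synthetic-data generators. On
reading assigned formulas, the computed mass is checked against the
stated mass at a default tolerance of 3 ppm (matching the assignment
stage's own error bound); inconsistent rows are flagged and kept, never
dropped, since downstream matching is by formula.

## Severity classification

Record sections are selected by case-insensitive substring keywords on
headings — toxicity: `toxic`, `ghs`, `hazard`, `safety`; food: `food` —
both configurable. GHS hazard-statement codes are extracted from the
toxicity sections as substrings of the form `H` + exactly three digits
(a fourth digit disqualifies the token).

The code → category mapping follows the standard GHS hazard-statement
table. Acute-toxicity codes collapse across exposure route, since the
screening labels carry no route:

| level | oral | dermal | inhalation |
|---|---|---|---|
| 2 | H300 | H310 | H330 |
| 3 | H301 | H311 | H331 |
| 4 | H302 | H312 | H332 |
| 5 | H303 | H313 | H333 |

H300/H310/H330 each cover GHS categories 1–2; the less extreme level (2)
is reported. Irritants: H315 → skin category 2, H318 → eye category 1,
H319 → eye category 2. When both a skin and an eye code are present the
compound moves to the combined "Skin and eye irritant" family at the
more severe (numerically lower) of the two levels — the only monotone
extension of the combination rule consistent with the severity order.
Unknown H-codes are logged and ignored, never fatal.

Severity is a single total order — acute toxic 1 … 5, then skin-and-eye,
eye, skin irritant (category 1 before 2 within each family), then
potentially toxic — and the final label is the maximum over all per-code
outcomes across all fetched records for the compound (up to a
configurable cap of 3 identifiers per name). An empty code set with a
relevant section present yields "Potentially toxic". Food-safety
sections are collected as evidence context only and never change
severity; whether they should escalate is a judgment the tool leaves to
the analyst.

## Record providers

The default provider is a directory of JSON record files mirroring the
hierarchical Record → Section → Information layout of public
compound-database records, validated structurally on load. Name
resolution is case-insensitive with a normalized fallback that strips
stereo-descriptor prefixes (L-, D-, DL-, (+)-, (−)-), motivated by
hazard databases filing amino acids under their stereo-prefixed names.
When a name resolves to several identifiers, all (up to the cap) are
fetched and the maximum severity wins; no selection heuristic is
attempted.

The live provider spaces consecutive requests at least 0.2 s apart so as
not to overload the remote service. The pacing loop sleeps a microsecond
past the deadline so floating-point rounding can never leave a gap
fractionally short of the interval; clock and sleep are injectable, so
the contract is tested with a fake clock and no real waiting. Transient
transport failures retry 3 times with doubling backoff (0.5 s base) and
then surface as a provider error — which is routed per-compound to the
unfound set with a note, never aborting a run. HTTP 404 is "not found",
a distinct outcome that alone feeds the local-match stage. A
pass-through JSON cache can wrap any provider; its cache directory is
itself a valid fixture store.

## Merging

Per-mode rows combine per sample, then per-sample rows merge across
samples, keyed on the normalized compound name, once per report kind
(toxic, unfound, unchecked). The merge is a union (outer join): a merged
report exists to show everything any sample produced, and dropping
compounds absent from one sample would defeat that purpose; an
intersection view is available (`merge_how: inner`) for users who want
only shared compounds. Cross-mode or cross-sample classification
conflicts for the same compound resolve to the higher severity with a
logged warning. Merged row order is severity rank descending, then name
— all outputs are deterministically ordered, so a rerun with identical
inputs is byte-identical.

## Synthetic data

The fixture generators emulate the interchange surface of the upstream
stages, not their physics:

* background formulas are random CHNO compositions (C 5–40, H/C
  constrained to 0.3–3.0 — the elemental-ratio range the assignment
  stage itself enforces; N ≤ 3, O ≤ 12), with masses computed from
  element counts so every generated row passes the consistency check;
* abundances are log-uniform over 1e4–1e9 (peak areas span decades);
  retention times uniform on 0–70 min, the gradient length of the
  reference LC method;
* toxic-table decoys are generated to never collide with any sample's
  background formulas, so synthetic runs have zero false-positive
  matches by construction — planted compounds are the only possible
  matches;
* record fixtures embed the requested hazard codes in a GHS
  classification section nested under a safety heading, surrounded by
  distractor sections, exercising the depth-first scan.

What this does **not** emulate: mass error (fixture masses are exact, so
the ppm flag path is exercised only by dedicated tests), isotope
patterns, adducts, ambiguous assignments, chromatographic noise, or a
toxic table with realistic coverage (~thousands of substances). Passing
tests therefore demonstrate the correctness of the matching, retrieval,
classification and merging logic — not the sensitivity of the overall
workflow on real instrument data, which is bounded upstream by
assignment quality and by database coverage.

The bundled validation set is eight compounds (3- and
4-methoxybenzaldehyde, coumarin, glutamic acid, phenylalanine, citric
acid, aspartic acid, naringin) with their standard GHS codes, split
across the two ESI modes of one sample. The two anisaldehyde isomers
share C8H8O2 and both must emerge from one matched feature; the amino
acids are filed in the record store under stereo-prefixed names and must
resolve through normalization; the two acids with no mapped acute code
must land in "Potentially toxic" via their toxicology headings.

## Numerical and design choices

* Report row ordering (severity desc, then name) and fixed per-kind
  column sets make golden-file comparisons possible; write → read is the
  identity on every report kind.
* The strict feature-table contract accepts exactly the column order
  `row m/z, peak area, row retention time` (the order the downstream
  assignment stage requires) and rejects the other five permutations; a
  lenient mode accepts any order for ad-hoc use.
* Duplicate (name, formula) toxic-table rows keep the first occurrence;
  unparsable formulas in the table are skipped with a counted warning
  rather than aborting, since a curated table may mix notations.
* Fixture generation derives all randomness from one integer seed;
  per-mode streams are derived arithmetically (never from string
  hashing, which is salted per process).
* Sample directories are discovered by filename patterns
  (`*pos*.csv` / `*neg*.csv` by default, configurable); only outputs are
  written into the run's output tree, inputs are left in place.

## Known limitations

* Coverage-bound: a compound absent from the toxic table is invisible,
  and a formula the upstream stage could not assign never reaches the
  tool.
* No structural evidence: isomers are indistinguishable; labels are
  candidate hazards, not identifications.
* Chronic toxicity, dose extraction (LD50/ADI/TDI) and fragmentation
  verification are out of scope.
* The five-family scheme compresses the full GHS statement set; codes
  outside the mapped acute/irritant set (e.g. carcinogenicity H350) are
  currently ignored with a warning rather than classified.
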
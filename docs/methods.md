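# Methods

## The model

`vancalc` computes vancomycin regimens by table lookup, not by
pharmacokinetic modelling. A nomogram table is a grid indexed by two banded
axes — total body weight (kg) and estimated creatinine clearance
(CrCl, mL/min) — in which each cell stores a maintenance dose and dosing
interval, and each weight band stores one loading dose. This encodes the
standard clinical logic for a renally cleared drug with a narrow therapeutic
index: the loading dose scales with body size (distribution volume), while
the maintenance dose *rate* scales with renal function (clearance). Within
every weight band the total daily maintenance dose (dose × 24/interval) is
non-decreasing in CrCl, and within every CrCl band it is non-decreasing in
weight; both monotonicity properties are asserted over every cell of both
bundled tables in the test suite.

Two tables are bundled:

- **adult** — 5 weight bands (50–100 kg) × 11 CrCl bands (< 10 to ≥ 120
  mL/min); doses are multiples of 250 mg; intervals range q96h (severe renal
  impairment) to q6h (augmented clearance).
- **pediatric** — 8 weight bands (2.5–70 kg) × 5 CrCl bands (< 15 to ≥ 90
  mL/min); doses are multiples of 25 mg; the lowest renal band is dosed
  q168h (weekly) in the smallest weights.

The engine takes estimated CrCl as an input and deliberately does not
estimate it; which estimator (and whether pediatric CrCl is body-surface
normalized to 1.73 m²) is the caller's responsibility. The axis is
documented as plain mL/min, matching its source header.

## Band semantics

Printed band labels ("50–60" / "61–70", "2.5–4.5" / "4.6–12.0") are stored
as contiguous half-open intervals `[lower, next_lower)` — e.g. adult weights
[50, 61), [61, 71), … [91, 101) — so real-valued inputs such as 60.5 kg
resolve to exactly one band without rounding; the printed integer (or
0.1-kg-grain) labels are kept verbatim for provenance display. A value `v`
belongs to a band iff `lower ≤ v < upper`. Out-of-range inputs (adult weight
< 50 or ≥ 101 kg; pediatric weight < 2.5 or ≥ 70.1 kg) raise a hard
`OutOfRangeError`: the tables give no guidance outside their range and the
engine never extrapolates.

One transcription judgement call: the adult renal column printed between
"80–99" and "≥ 120" carries an upper figure (199) that contradicts the
column that follows it. It is stored as 100–119 and labelled accordingly;
the printed figure is treated as a typographical artifact. This is the only
cell-level deviation from the source layout, and it affects band edges only,
not any dose.

`CrCl = 0` (anuric/dialysis) is accepted and resolves to the lowest renal
band, with a warning attached to the regimen — the tables have no separate
dialysis column, and the lowest band (q96h / q168h dosing) is the table's
own representation of negligible clearance.

## Neonatal interval rule

Four cells of the pediatric table's smallest weight band (2.5–4.5 kg) are
age-conditional: q8h for postnatal age > 7 days, q12h for < 7 days (neonatal
renal maturation). Two edge cases the rule leaves open are resolved
conservatively:

- **age exactly 7 days** — the longer interval (q12h) is chosen and a
  warning is attached, since the published rule covers only the strict
  inequalities;
- **age absent** — `MissingPostnatalAgeError` is raised rather than guessing
  either interval.

## Infusion durations

The infusion rule is dose-tiered: 60 min for doses ≤ 1000 mg, 90 min for
1001–1500 mg, 120 min for 1501–2000 mg, and a flat rate of 1000 mg/h above
2000 mg. The same rule is applied to loading and maintenance doses; no
separate loading rule exists in the source, and the tiered rule reproduces
its worked displays (a 2000 mg adult loading dose infused over 2 h, a
pediatric loading dose over 60 min). Durations above the last tier are
reported in whole minutes, rounded half-up (computed in decimal arithmetic
to avoid float-representation ties), minutes being the display unit — e.g.
2250 mg → 135 min. The rule implies an infusion-rate cap of 1000/60
≈ 16.7 mg/min everywhere (equality at tier bounds and in the overflow
regime), the conventional ceiling for limiting vancomycin infusion
reactions; the rule validator enforces that every tier respects the
overflow rate, and a test asserts the cap over every dose reachable from
either bundled table. The pediatric source states the tiers without the
overflow clause; both bundled tables share the single rule, which is
indistinguishable there because no bundled pediatric dose exceeds 2000 mg.

## Assembled regimen

`compute_regimen` is a pure function: weight-band lookup → CrCl-band lookup
→ cell read → interval resolution → infusion durations. The wait between
loading and first maintenance dose is set equal to the resolved dosing
interval — the natural reading of the output field it reproduces, recorded
here as a package decision because no numeric rule is published for it.
Population routing is explicit (the caller names adult or pediatric; weights
50–70 kg exist in both tables) and a population/table mismatch is an error.
Identical inputs always produce identical regimens; there is no randomness
anywhere in the package, which is why the acceptance script's `--seed` flag
does not influence its output.

## Serialization

The canonical persistent form is a JSON document (UTF-8, en-dash labels
verbatim): axes as `{lower, upper, label}` lists with `null` upper meaning
+∞, the maintenance grid row-major with either `interval_h` or a
`conditional_interval` pair `[if_age_gt_7d, if_age_lt_7d]`, the infusion
rule inline, and `schema_version: "1"` (unknown versions are rejected, not
coerced). Field-level validation is done with pydantic models
(`extra="forbid"`), so schema errors name the JSON path of the offending
field; structural invariants — band contiguity, grid dimensions, dose grain,
tier ordering — are re-checked by the same constructors the bundled tables
pass through. `dump_nomogram` emits keys in fixed order with canonical
number formatting (integral values print without a decimal point), making
repeated dumps byte-identical and `dump ∘ load ∘ dump` idempotent. A
read-only CSV export of the maintenance grid is provided for spreadsheet
audits.

## Test strategy and what it shows

There is no synthetic-data question here — the nomogram tables themselves
are the ground truth — so testing centres on transcription fidelity and
lookup semantics:

- an **exhaustive grid replay**: all 55 adult and 40 pediatric cells plus
  all 13 loading doses, evaluated at band midpoints (lower + 1 for unbounded
  bands), compared against a transcription frozen separately inside the
  acceptance tests, so a drift in either copy fails;
- **boundary probes** at `lower`, `lower + ε`, `upper − ε`, `upper` of every
  band (ε = 10⁻⁹) pinning the half-open convention;
- **property tests** (hypothesis, fixed-seed examples plus randomized
  in-range floats): unique band resolution, the infusion-rate cap over the
  25 mg dose grain, monotonicity along both axes;
- **mutation tests** on the JSON schema: deleting any required field from a
  valid document must be rejected;
- **CLI contract tests**: exit codes (0 success, 1 bad nomogram file, 2
  invalid input), decimal-comma parsing, pt/en labels, and text/json output
  parity.

Everything is deterministic and desk-scale; the whole suite runs in about a
second. What passing shows is that the engine reproduces its source tables
exactly and handles their edges as documented — it says nothing about
clinical outcomes, which the source itself did not measure.

## Known limitations

- No CrCl estimator, no AUC₂₄/MIC or Bayesian individualization, no
  trough-level redosing, no obesity/adjusted-body-weight logic — actual
  weight only, per the source tables.
- Indications outside severe MRSA infection (e.g. *C. difficile* diarrhea,
  surgical prophylaxis) are outside the tables' intent.
- Adults above 100 kg and children above 70 kg are simply out of range;
  clinical judgement, not this package, covers them.
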
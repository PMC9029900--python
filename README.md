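# vancalc

An offline vancomycin dosing-nomogram engine and command-line calculator for
adult and pediatric inpatients with severe MRSA infection.

Vancomycin has a narrow therapeutic index, so its dose must be adjusted to
body weight and renal function. `vancalc` implements this adjustment as a
**banded lookup**: two published nomogram tables map total body weight (kg)
and estimated creatinine clearance (CrCl, mL/min) to a complete regimen —
loading dose, maintenance dose, dosing interval (qNh), and infusion
durations. The adult table spans 50–100 kg × 11 renal bands (from CrCl < 10,
dosed q96h, up to ≥ 120 mL/min, dosed q6h); the pediatric table spans
2.5–70 kg × 5 renal bands, with its neonatal band (2.5–4.5 kg) choosing q8h
vs q12h by postnatal age (> 7 days vs < 7 days). Infusion durations follow a
dose-tiered rule — 60 min for doses ≤ 1.0 g, 90 min for 1.1–1.5 g, 120 min
for 1.6–2.0 g, and a flat 1.0 g/h above 2.0 g — which caps the infusion rate
at 1000/60 mg/min to limit infusion reactions.

The package is aimed at antimicrobial-stewardship tooling: the tables are
auditable data (JSON-serializable, CSV-exportable, replaceable by a
user-supplied document), band lookups use a strict half-open convention
`[lower, upper)` so every in-range weight/CrCl resolves to exactly one cell,
and out-of-range inputs are hard errors, never extrapolations.

**This is decision-support software, not medical advice.** CrCl estimation
(Cockcroft–Gault, Schwartz, …), AUC₂₄/MIC-based individualization and
therapeutic drug monitoring are out of scope: estimated CrCl is an input.

## Worked example

An adult weighing 75 kg with estimated CrCl 65 mL/min:

```bash
vancalc --population adult --weight 75 --crcl 65 --lang en
```

```
Loading dose: 2000 mg
Infusion duration (loading): 120 minutes
Maintenance dose: 1000 mg
Time after loading dose: 12 hours
Dosing interval: 12 hours
Infusion duration: 60 minutes
```

The 75 kg weight falls in the 71–80 kg band (loading 2000 mg, infused over
120 min because 2000 mg is in the 1.6–2.0 g tier); CrCl 65 falls in the
60–69 mL/min band, whose cell reads 1000 mg q12h (60 min infusion, since
1000 mg ≤ 1.0 g). The first maintenance dose follows one dosing interval
(12 h) after the loading dose. The same comes out of the library:

```python
from vancalc import PatientInput, compute_regimen

regimen = compute_regimen(PatientInput("adult", weight=75, crcl=65))
print(regimen.maintenance_dose_mg, regimen.interval_h)   # 1000 12
```

A neonate (3 kg, CrCl 40 mL/min) needs `--postnatal-days`; with age 5 days
the engine returns 25 mg q12h, with age 10 days 25 mg q8h. JSON output
(`--format json`) carries the same numbers plus provenance (table and band
labels) and any warnings; Portuguese labels are the text-mode default
(`--lang pt`). Decimal commas are accepted (`--weight 4,5`).

Custom tables: `vancalc --nomogram-file my_table.json …` loads a validated
nomogram document (see `vancalc.nomogram_io`); `dump_nomogram` writes the
bundled tables in the same format for auditing.

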
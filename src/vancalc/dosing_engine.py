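"""Resolution of a patient against a nomogram into a complete regimen.

The engine is a pure function of its inputs: band lookup on the weight and
creatinine-clearance axes, cell read, neonatal interval resolution, and the
dose-tiered infusion-duration rule. There is no randomness and no state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple

from .errors import MissingPostnatalAgeError, OutOfRangeError
from .nomogram_model import (
    Band,
    BandedAxis,
    DoseEntry,
    NomogramTable,
    PatientInput,
    Provenance,
    Regimen,
)


@dataclass(frozen=True)
class InfusionRule:
    """Dose-tiered infusion durations with a flat overflow rate.

    ``tiers`` maps an inclusive dose upper bound (mg) to a fixed duration
    (min); a dose above the last tier is infused at ``overflow_rate_mg_per_h``
    (duration = dose / rate, reported in whole minutes). The standard rule —
    60 min up to 1.0 g, 90 min up to 1.5 g, 120 min up to 2.0 g, then 1.0 g/h
    — keeps the infusion rate at or below 1000/60 mg/min everywhere, the cap
    used to limit infusion reactions ("red man" syndrome).
    """

    tiers: Tuple[Tuple[float, int], ...] = ((1000, 60), (1500, 90), (2000, 120))
    overflow_rate_mg_per_h: float = 1000.0
    rule_id: str = "standard"

    def __post_init__(self) -> None:
        object.__setattr__(self, "tiers", tuple(tuple(t) for t in self.tiers))
        if not self.tiers:
            raise ValueError("infusion rule needs at least one tier")
        bounds = [b for b, _ in self.tiers]
        durations = [d for _, d in self.tiers]
        if any(b <= 0 for b in bounds) or any(d <= 0 for d in durations):
            raise ValueError("tier bounds and durations must be positive")
        if sorted(set(bounds)) != bounds:
            raise ValueError("tier dose bounds must be strictly increasing")
        if sorted(set(durations)) != durations:
            raise ValueError("tier durations must be strictly increasing")
        if self.overflow_rate_mg_per_h <= 0:
            raise ValueError("overflow rate must be positive")
        cap = self.overflow_rate_mg_per_h / 60.0
        for bound, duration in self.tiers:
            if bound / duration > cap * (1 + 1e-12):
                raise ValueError(
                    f"tier {bound} mg / {duration} min exceeds the overflow rate "
                    f"{self.overflow_rate_mg_per_h:g} mg/h"
                )


def standard_infusion_rule() -> InfusionRule:
    """The rule bundled with both built-in tables (id ``"standard"``)."""
    return InfusionRule()


def find_band(axis: BandedAxis, value: float) -> Band:
    """Return the unique band of ``axis`` with ``lower <= value < upper``.

    Raises
    ------
    OutOfRangeError
        If ``value`` lies below the first band or at/above the upper edge of
        the last band. Values outside the table are never extrapolated.
    """
    if not math.isfinite(value):
        raise ValueError(f"{axis.name}: value must be finite, got {value!r}")
    if value < axis.lower or value >= axis.upper:
        raise OutOfRangeError(axis.name, value, axis.lower, axis.upper)
    for band in axis.bands:
        if band.contains(value):
            return band
    raise AssertionError("contiguous axis must resolve any in-range value")  # pragma: no cover


def infusion_duration_min(rule: InfusionRule, dose_mg: float) -> int:
    """Infusion duration in whole minutes for a dose.

    Doses at or below a tier bound get that tier's fixed duration; doses above
    the last tier run at the overflow rate, rounded half-up to the nearest
    minute (e.g. 2250 mg at 1.0 g/h -> 135 min).
    """
    if not (math.isfinite(dose_mg) and dose_mg > 0):
        raise ValueError(f"dose_mg must be a positive finite number, got {dose_mg!r}")
    for bound, duration in rule.tiers:
        if dose_mg <= bound:
            return int(duration)
    minutes = Decimal(str(dose_mg)) * 60 / Decimal(str(rule.overflow_rate_mg_per_h))
    return int(minutes.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def resolve_interval(
    entry: DoseEntry, postnatal_age_days: Optional[int] = None
) -> Tuple[float, Optional[str]]:
    """Resolve a cell's dosing interval, applying the neonatal age rule.

    Unconditional cells return their interval unchanged and ignore age.
    Age-conditional cells return the shorter interval (q8h in the bundled
    table) for postnatal age > 7 days and the longer one (q12h) for age
    < 7 days. Age exactly 7 days is not covered by the source rule; the
    longer, more conservative interval is returned with a warning.

    Returns ``(interval_h, warning_or_None)``.

    Raises
    ------
    MissingPostnatalAgeError
        For a conditional cell when ``postnatal_age_days`` is ``None``.
    """
    if not entry.is_conditional:
        return entry.interval_h, None
    if postnatal_age_days is None:
        raise MissingPostnatalAgeError()
    gt7_h, lt7_h = entry.conditional_interval
    if postnatal_age_days > 7:
        return gt7_h, None
    if postnatal_age_days < 7:
        return lt7_h, None
    return lt7_h, (
        "postnatal age exactly 7 days is not covered by the age rule; "
        f"the longer interval (q{lt7_h:g}h) was chosen"
    )


def compute_regimen(
    patient: PatientInput,
    table: Optional[NomogramTable] = None,
    rule: Optional[InfusionRule] = None,
) -> Regimen:
    """Resolve a patient against a nomogram table into a complete regimen.

    When ``table`` is omitted the bundled table for the patient's population
    is used; when ``rule`` is omitted the standard infusion rule is used.

    The loading dose comes from the resolved weight band; the maintenance
    dose and interval from the (weight band, CrCl band) grid cell. Both
    infusion durations follow the dose-tiered rule. The wait before the first
    maintenance dose equals the resolved dosing interval.

    Raises
    ------
    ValueError
        If the table's population does not match the patient's.
    OutOfRangeError
        If weight or CrCl falls outside the table.
    MissingPostnatalAgeError
        If an age-conditional cell is hit without a postnatal age.
    """
    if table is None:
        from .nomogram_model import builtin_table

        table = builtin_table(patient.population)
    if rule is None:
        rule = standard_infusion_rule()
    if table.population != patient.population:
        raise ValueError(
            f"table {table.name!r} is for {table.population} patients, "
            f"not {patient.population}"
        )

    weight_band = find_band(table.weight_axis, patient.weight)
    crcl_band = find_band(table.crcl_axis, patient.crcl)
    wi = table.weight_axis.bands.index(weight_band)
    ci = table.crcl_axis.bands.index(crcl_band)

    warnings = []
    if patient.crcl == 0:
        warnings.append(
            "CrCl 0 mL/min (anuric/dialysis) was mapped to the lowest renal "
            f"band ({crcl_band.label}); the table has no separate dialysis column"
        )

    entry = table.cell(wi, ci)
    interval_h, age_warning = resolve_interval(entry, patient.postnatal_age_days)
    if age_warning:
        warnings.append(age_warning)

    loading_mg = table.loading_mg[wi]
    return Regimen(
        loading_dose_mg=loading_mg,
        loading_infusion_min=infusion_duration_min(rule, loading_mg),
        maintenance_dose_mg=entry.dose_mg,
        interval_h=interval_h,
        maintenance_infusion_min=infusion_duration_min(rule, entry.dose_mg),
        first_maintenance_after_h=interval_h,
        provenance=Provenance(
            table=table.name, weight_band=weight_band.label, crcl_band=crcl_band.label
        ),
        warnings=tuple(warnings),
    )
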
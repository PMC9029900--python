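"""Data model for banded vancomycin dosing nomograms.

A nomogram here is a two-way banded lookup table: rows are total-body-weight
bands (kg), columns are estimated creatinine-clearance bands (mL/min), and
each cell holds a maintenance dose with its dosing interval. Each weight band
additionally carries a single loading dose. Two tables are bundled: one for
adult patients (5 weight bands x 11 CrCl bands) and one for pediatric
patients (8 weight bands x 5 CrCl bands), whose smallest weight band
(neonates, 2.5-4.5 kg) uses age-conditional intervals.

Band convention
---------------
Printed band labels such as "50–60" / "61–70" (adult, integer steps) or
"2.5–4.5" / "4.6–12.0" (pediatric, 0.1 kg steps) are stored as contiguous
half-open intervals [lower, next_lower), so any real-valued input inside the
table's overall range — e.g. 60.5 kg — resolves to exactly one band without
rounding. A value v belongs to a band iff lower <= v < upper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

Population = Literal["adult", "pediatric"]

#: Dosing intervals (hours) that occur in the bundled tables. Custom tables
#: may use any positive interval; this set exists for auditing only.
BUNDLED_INTERVALS_H = frozenset({6, 8, 12, 24, 96, 168})


@dataclass(frozen=True)
class PatientInput:
    """The engine's sole clinical input.

    Parameters
    ----------
    population:
        ``"adult"`` or ``"pediatric"``. Routing is explicit — the caller
        selects the table; weights between 50 and 70 kg exist in both.
    weight:
        Actual (total) body weight in kg. Must be positive.
    crcl:
        Estimated creatinine clearance in mL/min. Must be non-negative;
        0 (anuric / dialysis) resolves to the lowest renal band.
    postnatal_age_days:
        Postnatal age in days. Only consulted when the resolved maintenance
        cell is age-conditional (neonatal weight band); ignored otherwise.
    """

    population: Population
    weight: float
    crcl: float
    postnatal_age_days: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population not in ("adult", "pediatric"):
            raise ValueError(f"unknown population {self.population!r}")
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValueError(f"weight must be a positive finite number of kg, got {self.weight!r}")
        if not (math.isfinite(self.crcl) and self.crcl >= 0):
            raise ValueError(f"crcl must be a non-negative finite number of mL/min, got {self.crcl!r}")
        if self.postnatal_age_days is not None and self.postnatal_age_days < 0:
            raise ValueError("postnatal_age_days must be >= 0 when given")


@dataclass(frozen=True)
class Band:
    """A half-open numeric interval [lower, upper) with its printed label."""

    lower: float
    upper: float  # may be math.inf for an unbounded top band
    label: str

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"band {self.label!r}: lower ({self.lower}) must be < upper ({self.upper})")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class BandedAxis:
    """An ordered, disjoint, contiguous sequence of bands covering one axis."""

    name: Literal["weight_kg", "crcl_ml_min"]
    bands: Tuple[Band, ...]

    def __post_init__(self) -> None:
        if self.name not in ("weight_kg", "crcl_ml_min"):
            raise ValueError(f"unknown axis name {self.name!r}")
        if not self.bands:
            raise ValueError("axis must have at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.upper != nxt.lower:
                raise ValueError(
                    f"axis {self.name}: bands {prev.label!r} and {nxt.label!r} are not "
                    f"contiguous (gap between {prev.upper} and {nxt.lower})"
                )

    @property
    def lower(self) -> float:
        return self.bands[0].lower

    @property
    def upper(self) -> float:
        return self.bands[-1].upper


@dataclass(frozen=True)
class DoseEntry:
    """One maintenance cell: a dose in mg plus its interval in hours.

    Exactly one of ``interval_h`` and ``conditional_interval`` is set. A
    conditional interval is the pair ``(interval_if_age_gt_7d, interval_if_age_lt_7d)``
    used by the neonatal weight band, where the choice depends on postnatal age.
    """

    dose_mg: float
    interval_h: Optional[float] = None
    conditional_interval: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.dose_mg > 0 and self.dose_mg % 25 == 0):
            raise ValueError(f"dose_mg must be a positive multiple of 25 mg, got {self.dose_mg!r}")
        if (self.interval_h is None) == (self.conditional_interval is None):
            raise ValueError("exactly one of interval_h / conditional_interval must be set")
        if self.interval_h is not None and self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        if self.conditional_interval is not None:
            object.__setattr__(self, "conditional_interval", tuple(self.conditional_interval))
            if len(self.conditional_interval) != 2 or any(h <= 0 for h in self.conditional_interval):
                raise ValueError("conditional_interval must be a pair of positive hours")

    @property
    def is_conditional(self) -> bool:
        return self.conditional_interval is not None

    def daily_dose_mg(self, interval_h: Optional[float] = None) -> float:
        """Total dose per 24 h; conditional cells need the resolved interval
        (defaults to the >7-day interval)."""
        if interval_h is None:
            interval_h = self.interval_h if self.interval_h is not None else self.conditional_interval[0]
        return self.dose_mg * 24.0 / interval_h


@dataclass(frozen=True)
class NomogramTable:
    """One population's complete dosing table.

    ``maintenance`` is indexed ``[weight band][crcl band]``; ``loading_mg``
    has one loading dose per weight band. ``infusion_rule_id`` names the
    infusion-duration rule the table was published with (bundled tables use
    ``"standard"``, the 60/90/120-min tiers capped at 1 g/h).
    """

    name: str
    population: Population
    weight_axis: BandedAxis
    crcl_axis: BandedAxis
    loading_mg: Tuple[float, ...]
    maintenance: Tuple[Tuple[DoseEntry, ...], ...]
    infusion_rule_id: str = "standard"

    def __post_init__(self) -> None:
        object.__setattr__(self, "loading_mg", tuple(self.loading_mg))
        object.__setattr__(self, "maintenance", tuple(tuple(row) for row in self.maintenance))
        n_w = len(self.weight_axis.bands)
        n_c = len(self.crcl_axis.bands)
        if self.weight_axis.name != "weight_kg" or self.crcl_axis.name != "crcl_ml_min":
            raise ValueError("weight_axis must be weight_kg and crcl_axis must be crcl_ml_min")
        if len(self.loading_mg) != n_w:
            raise ValueError(
                f"table {self.name!r}: expected {n_w} loading doses (one per weight band), "
                f"found {len(self.loading_mg)}"
            )
        if any(d <= 0 for d in self.loading_mg):
            raise ValueError("loading doses must be positive")
        if len(self.maintenance) != n_w:
            raise ValueError(
                f"table {self.name!r}: expected {n_w} maintenance rows, found {len(self.maintenance)}"
            )
        for i, row in enumerate(self.maintenance):
            if len(row) != n_c:
                raise ValueError(
                    f"table {self.name!r}, weight band {self.weight_axis.bands[i].label!r}: "
                    f"expected {n_c} maintenance cells, found {len(row)}"
                )

    def cell(self, weight_index: int, crcl_index: int) -> DoseEntry:
        return self.maintenance[weight_index][crcl_index]


@dataclass(frozen=True)
class Provenance:
    """Which table and which bands produced a regimen."""

    table: str
    weight_band: str
    crcl_band: str


@dataclass(frozen=True)
class Regimen:
    """The assembled dosing output.

    All doses are mg, intervals/waits are hours, infusion durations are
    minutes. ``first_maintenance_after_h`` is the wait between the end of the
    loading dose and the first maintenance dose, set equal to the resolved
    dosing interval. ``warnings`` collects advisory notes (e.g. postnatal age
    exactly 7 days, CrCl 0 mapped to the lowest renal band).
    """

    loading_dose_mg: float
    loading_infusion_min: int
    maintenance_dose_mg: float
    interval_h: float
    maintenance_infusion_min: int
    first_maintenance_after_h: float
    provenance: Provenance
    warnings: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "warnings", tuple(self.warnings))
        for name in ("loading_dose_mg", "loading_infusion_min", "maintenance_dose_mg",
                     "interval_h", "maintenance_infusion_min", "first_maintenance_after_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Bundled tables
# ---------------------------------------------------------------------------

def _axis(name: str, edges: list, labels: list) -> BandedAxis:
    bands = tuple(
        Band(lower=lo, upper=hi, label=lab)
        for lo, hi, lab in zip(edges[:-1], edges[1:], labels)
    )
    return BandedAxis(name=name, bands=bands)


_ADULT_WEIGHT_EDGES = [50, 61, 71, 81, 91, 101]
_ADULT_WEIGHT_LABELS = ["50–60", "61–70", "71–80", "81–90", "91–100"]
_ADULT_CRCL_EDGES = [0, 10, 20, 30, 40, 50, 60, 70, 80, 100, 120, math.inf]
# The source column between "80–99" and ">= 120" is labelled here as 100–119;
# its printed upper figure conflicts with the following column and is treated
# as a typographical artifact (see docs/methods.md).
_ADULT_CRCL_LABELS = ["< 10", "10–19", "20–29", "30–39", "40–49", "50–59",
                      "60–69", "70–79", "80–99", "100–119", "≥ 120"]

_ADULT_LOADING = [1500, 1500, 2000, 2000, 2250]
# (dose_mg, interval_h) per cell, rows = weight bands, cols = CrCl bands.
_ADULT_GRID = [
    [(1000, 96), (500, 24), (750, 24), (500, 12), (500, 12), (750, 12),
     (750, 12), (1000, 12), (1250, 12), (1750, 12), (1750, 12)],
    [(1250, 96), (500, 24), (750, 24), (500, 12), (750, 12), (750, 12),
     (1000, 12), (1250, 12), (1000, 8), (1750, 12), (1250, 8)],
    [(1250, 96), (500, 24), (1000, 24), (750, 12), (750, 12), (1000, 12),
     (1000, 12), (1500, 12), (1000, 8), (1250, 8), (1000, 6)],
    [(1500, 96), (750, 24), (1250, 24), (750, 12), (1000, 12), (1000, 12),
     (1250, 12), (1500, 12), (1750, 12), (1000, 6), (1000, 6)],
    [(1750, 96), (750, 24), (1250, 24), (750, 12), (1000, 12), (1250, 12),
     (1500, 12), (1500, 12), (1000, 6), (1000, 6), (1000, 6)],
]

_PED_WEIGHT_EDGES = [2.5, 4.6, 12.1, 18.1, 30.1, 40.1, 50.1, 60.1, 70.1]
_PED_WEIGHT_LABELS = ["2.5–4.5", "4.6–12.0", "12.1–18.0", "18.1–30.0",
                      "30.1–40.0", "40.1–50.0", "50.1–60.0", "60.1–70.0"]
_PED_CRCL_EDGES = [0, 15, 30, 60, 90, math.inf]
_PED_CRCL_LABELS = ["< 15", "15–29", "30–59", "60–89", "≥ 90"]

_PED_LOADING = [100, 250, 500, 750, 1000, 1250, 1500, 2000]
# "C" marks neonatal age-conditional cells: q8h if postnatal age > 7 days,
# q12h if < 7 days.
_C = "C"
_PED_GRID = [
    [(25, 168), (25, _C), (25, _C), (50, _C), (50, _C)],
    [(100, 168), (150, 24), (150, 12), (150, 8), (150, 6)],
    [(150, 168), (250, 24), (250, 12), (250, 8), (250, 6)],
    [(250, 168), (250, 24), (250, 12), (250, 8), (500, 6)],
    [(500, 168), (500, 24), (500, 12), (500, 8), (500, 6)],
    [(500, 168), (750, 24), (750, 12), (750, 8), (750, 6)],
    [(500, 168), (750, 24), (750, 12), (750, 8), (750, 6)],
    [(500, 168), (1000, 24), (1000, 12), (750, 8), (750, 6)],
]


def _entry(cell) -> DoseEntry:
    dose, interval = cell
    if interval == _C:
        return DoseEntry(dose_mg=dose, conditional_interval=(8, 12))
    return DoseEntry(dose_mg=dose, interval_h=interval)


def builtin_adult_table() -> NomogramTable:
    """The bundled adult nomogram: 5 weight bands (50–100 kg) x 11 CrCl bands."""
    return NomogramTable(
        name="adult",
        population="adult",
        weight_axis=_axis("weight_kg", _ADULT_WEIGHT_EDGES, _ADULT_WEIGHT_LABELS),
        crcl_axis=_axis("crcl_ml_min", _ADULT_CRCL_EDGES, _ADULT_CRCL_LABELS),
        loading_mg=tuple(_ADULT_LOADING),
        maintenance=tuple(tuple(_entry(c) for c in row) for row in _ADULT_GRID),
        infusion_rule_id="standard",
    )


def builtin_pediatric_table() -> NomogramTable:
    """The bundled pediatric nomogram: 8 weight bands (2.5–70 kg) x 5 CrCl bands.

    The neonatal weight band (2.5–4.5 kg) stores age-conditional intervals in
    four of its five cells: q8h for postnatal age > 7 days, q12h for < 7 days.
    """
    return NomogramTable(
        name="pediatric",
        population="pediatric",
        weight_axis=_axis("weight_kg", _PED_WEIGHT_EDGES, _PED_WEIGHT_LABELS),
        crcl_axis=_axis("crcl_ml_min", _PED_CRCL_EDGES, _PED_CRCL_LABELS),
        loading_mg=tuple(_PED_LOADING),
        maintenance=tuple(tuple(_entry(c) for c in row) for row in _PED_GRID),
        infusion_rule_id="standard",
    )


def builtin_table(population: Population) -> NomogramTable:
    """Return the bundled table for a population tag."""
    if population == "adult":
        return builtin_adult_table()
    if population == "pediatric":
        return builtin_pediatric_table()
    raise ValueError(f"unknown population {population!r}")
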
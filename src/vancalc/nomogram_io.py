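"""Serialization, validation and fixture generation for nomogram tables.

The canonical on-disk form is a JSON document (UTF-8, human-auditable,
diff-able) describing the axes, the loading-dose column, the maintenance
grid in row-major order, and the infusion rule. Unbounded band edges are
encoded as an explicit ``null`` upper bound. ``schema_version`` starts at
"1"; unknown versions are rejected, not coerced.

A read-only CSV export of the maintenance grid is offered as a convenience.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
from pathlib import Path
from typing import IO, List, Literal, Optional, Tuple, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .dosing_engine import InfusionRule, infusion_duration_min, standard_infusion_rule
from .errors import NomogramFormatError
from .nomogram_model import (
    Band,
    BandedAxis,
    DoseEntry,
    NomogramTable,
    PatientInput,
    Provenance,
    Regimen,
)

SCHEMA_VERSION = "1"

PathOrStream = Union[str, Path, IO[str]]


# ---------------------------------------------------------------------------
# Document schema (pydantic models; extra keys are rejected)
# ---------------------------------------------------------------------------

class BandSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lower: float
    upper: Optional[float] = None  # null means +infinity
    label: str


class CellSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dose_mg: float
    interval_h: Optional[float] = None
    conditional_interval: Optional[Tuple[float, float]] = None

    @model_validator(mode="after")
    def _one_interval_kind(self) -> "CellSpec":
        if (self.interval_h is None) == (self.conditional_interval is None):
            raise ValueError("exactly one of interval_h / conditional_interval must be set")
        return self


class InfusionRuleSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tiers: List[Tuple[float, float]]
    overflow_rate_mg_per_h: float


class NomogramDocument(BaseModel):
    """Persistent form of a dosing table; see module docstring for format."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str
    name: str
    population: Literal["adult", "pediatric"]
    weight_bands: List[BandSpec] = Field(min_length=1)
    crcl_bands: List[BandSpec] = Field(min_length=1)
    loading_mg: List[float]
    maintenance: List[List[CellSpec]]
    infusion_rule: InfusionRuleSpec
    source: str = ""

    @model_validator(mode="after")
    def _check_version_and_dimensions(self) -> "NomogramDocument":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version!r} "
                f"(this reader understands {SCHEMA_VERSION!r})"
            )
        n_w, n_c = len(self.weight_bands), len(self.crcl_bands)
        if len(self.loading_mg) != n_w:
            raise ValueError(
                f"loading_mg: expected {n_w} entries (one per weight band), "
                f"found {len(self.loading_mg)}"
            )
        if len(self.maintenance) != n_w:
            raise ValueError(
                f"maintenance: expected {n_w} rows, found {len(self.maintenance)}"
            )
        for i, row in enumerate(self.maintenance):
            if len(row) != n_c:
                raise ValueError(
                    f"maintenance row {i}: expected {n_c} cells, found {len(row)}"
                )
        return self


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_text(source: PathOrStream) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    return source.read()


def read_document(source: PathOrStream) -> NomogramDocument:
    """Parse and schema-validate a nomogram JSON document.

    Raises :class:`NomogramFormatError` naming the JSON path of the first
    offending field on any schema violation.
    """
    text = _read_text(source)
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NomogramFormatError(f"not valid JSON: {exc}") from exc
    try:
        return NomogramDocument.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = ".".join(str(p) for p in first["loc"]) or "<document root>"
        raise NomogramFormatError(f"at {path}: {first['msg']}") from exc


def _band_from_spec(spec: BandSpec) -> Band:
    upper = math.inf if spec.upper is None else spec.upper
    return Band(lower=spec.lower, upper=upper, label=spec.label)


def document_to_table(doc: NomogramDocument) -> NomogramTable:
    """Build a fully validated :class:`NomogramTable` from a parsed document.

    Structural invariants (band contiguity, grid dimensions, dose grain) are
    re-checked by the table constructor; violations surface as
    :class:`NomogramFormatError`.
    """
    try:
        weight_axis = BandedAxis(
            name="weight_kg", bands=tuple(_band_from_spec(b) for b in doc.weight_bands)
        )
        crcl_axis = BandedAxis(
            name="crcl_ml_min", bands=tuple(_band_from_spec(b) for b in doc.crcl_bands)
        )
        cells = tuple(
            tuple(
                DoseEntry(
                    dose_mg=c.dose_mg,
                    interval_h=c.interval_h,
                    conditional_interval=c.conditional_interval,
                )
                for c in row
            )
            for row in doc.maintenance
        )
        rule = document_infusion_rule(doc)
        return NomogramTable(
            name=doc.name,
            population=doc.population,
            weight_axis=weight_axis,
            crcl_axis=crcl_axis,
            loading_mg=tuple(doc.loading_mg),
            maintenance=cells,
            infusion_rule_id=rule.rule_id,
        )
    except ValueError as exc:
        raise NomogramFormatError(str(exc)) from exc


def document_infusion_rule(doc: NomogramDocument) -> InfusionRule:
    """The infusion rule embedded in a document.

    A rule identical to the bundled standard keeps the id ``"standard"``;
    anything else is tagged with the document name.
    """
    std = standard_infusion_rule()
    tiers = tuple(
        (b, int(d)) if float(d).is_integer() else (b, d)
        for b, d in doc.infusion_rule.tiers
    )
    rule_id = (
        "standard"
        if tiers == std.tiers and doc.infusion_rule.overflow_rate_mg_per_h == std.overflow_rate_mg_per_h
        else f"{doc.name}:inline"
    )
    try:
        return InfusionRule(
            tiers=tiers,
            overflow_rate_mg_per_h=doc.infusion_rule.overflow_rate_mg_per_h,
            rule_id=rule_id,
        )
    except ValueError as exc:
        raise NomogramFormatError(f"infusion_rule: {exc}") from exc


def load_nomogram(source: PathOrStream) -> NomogramTable:
    """Load a nomogram JSON document into a validated :class:`NomogramTable`."""
    return document_to_table(read_document(source))


# ---------------------------------------------------------------------------
# Dumping
# ---------------------------------------------------------------------------

def _num(x: float):
    """Canonical JSON number: integral floats print without a decimal point."""
    if isinstance(x, float) and x.is_integer():
        return int(x)
    return x


def _band_to_obj(band: Band) -> dict:
    return {
        "lower": _num(band.lower),
        "upper": None if math.isinf(band.upper) else _num(band.upper),
        "label": band.label,
    }


def _cell_to_obj(entry: DoseEntry) -> dict:
    obj = {"dose_mg": _num(entry.dose_mg)}
    if entry.is_conditional:
        obj["conditional_interval"] = [_num(h) for h in entry.conditional_interval]
    else:
        obj["interval_h"] = _num(entry.interval_h)
    return obj


def dump_nomogram(
    table: NomogramTable,
    rule: Optional[InfusionRule] = None,
    source: str = "",
) -> str:
    """Render a table as deterministic JSON text.

    Key order and number formatting are fixed, so repeated dumps of equal
    tables are byte-identical. Band labels (including en-dashes) are written
    verbatim, not escaped.
    """
    if rule is None:
        rule = standard_infusion_rule()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": table.name,
        "population": table.population,
        "weight_bands": [_band_to_obj(b) for b in table.weight_axis.bands],
        "crcl_bands": [_band_to_obj(b) for b in table.crcl_axis.bands],
        "loading_mg": [_num(d) for d in table.loading_mg],
        "maintenance": [[_cell_to_obj(c) for c in row] for row in table.maintenance],
        "infusion_rule": {
            "tiers": [[_num(b), _num(d)] for b, d in rule.tiers],
            "overflow_rate_mg_per_h": _num(rule.overflow_rate_mg_per_h),
        },
        "source": source,
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def export_csv(table: NomogramTable) -> str:
    """Read-only CSV view of the maintenance grid.

    Header row holds the CrCl band labels; one row per weight band; cells are
    formatted ``DOSEmg qINTERVALh`` (conditional cells as ``q8h/q12h``).
    """
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["weight_kg"] + [b.label for b in table.crcl_axis.bands])
    for wband, row in zip(table.weight_axis.bands, table.maintenance):
        cells = []
        for entry in row:
            if entry.is_conditional:
                gt7, lt7 = entry.conditional_interval
                cells.append(f"{_num(entry.dose_mg)}mg q{_num(gt7)}h/q{_num(lt7)}h")
            else:
                cells.append(f"{_num(entry.dose_mg)}mg q{_num(entry.interval_h)}h")
        writer.writerow([wband.label] + cells)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def band_probe(band: Band) -> float:
    """A representative in-band value: the midpoint of a finite band, or
    lower + 1 for an unbounded one."""
    if math.isinf(band.upper):
        return band.lower + 1.0
    return (band.lower + band.upper) / 2.0


def generate_grid_fixtures(
    table: NomogramTable, rule: Optional[InfusionRule] = None
) -> List[Tuple[PatientInput, Regimen]]:
    """One (patient, expected regimen) pair per grid cell of ``table``.

    The expected regimen is assembled by direct cell read, independently of
    the resolution engine, so replaying each fixture through
    ``compute_regimen`` exercises the full lookup path. Age-conditional cells
    emit two fixtures (postnatal age 3 d and 10 d).
    """
    if rule is None:
        rule = standard_infusion_rule()
    fixtures: List[Tuple[PatientInput, Regimen]] = []
    for wi, wband in enumerate(table.weight_axis.bands):
        weight = band_probe(wband)
        loading = table.loading_mg[wi]
        for ci, cband in enumerate(table.crcl_axis.bands):
            crcl = band_probe(cband)
            entry = table.cell(wi, ci)
            provenance = Provenance(table=table.name, weight_band=wband.label, crcl_band=cband.label)
            if entry.is_conditional:
                gt7_h, lt7_h = entry.conditional_interval
                variants = [(10, gt7_h), (3, lt7_h)]
            else:
                variants = [(None, entry.interval_h)]
            for age, interval_h in variants:
                patient = PatientInput(
                    population=table.population,
                    weight=weight,
                    crcl=crcl,
                    postnatal_age_days=age,
                )
                expected = Regimen(
                    loading_dose_mg=loading,
                    loading_infusion_min=infusion_duration_min(rule, loading),
                    maintenance_dose_mg=entry.dose_mg,
                    interval_h=interval_h,
                    maintenance_infusion_min=infusion_duration_min(rule, entry.dose_mg),
                    first_maintenance_after_h=interval_h,
                    provenance=provenance,
                )
                fixtures.append((patient, expected))
    return fixtures
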
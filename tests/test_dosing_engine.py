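"""Band lookup, infusion durations, interval resolution, and full regimens."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vancalc import (
    DoseEntry,
    InfusionRule,
    MissingPostnatalAgeError,
    OutOfRangeError,
    PatientInput,
    compute_regimen,
    find_band,
    infusion_duration_min,
    resolve_interval,
    standard_infusion_rule,
)

EPS = 1e-9
RATE_CAP_MG_PER_MIN = 1000 / 60


class TestFindBand:
    @pytest.mark.parametrize(
        "value,label",
        [(55, "50–60"), (60.5, "50–60"), (61, "61–70"), (100.9, "91–100")],
    )
    def test_adult_weight_lookup(self, adult_table, value, label):
        assert find_band(adult_table.weight_axis, value).label == label

    def test_lower_bound_inclusive_on_open_top_band(self, pediatric_table):
        assert find_band(pediatric_table.crcl_axis, 90).label == "≥ 90"

    @pytest.mark.parametrize("value", [49.9, 101, 150])
    def test_out_of_range_weight_rejected(self, adult_table, value):
        with pytest.raises(OutOfRangeError) as exc:
            find_band(adult_table.weight_axis, value)
        # the error names the axis, the value and the covered range
        msg = str(exc.value)
        assert "weight_kg" in msg and f"{value:g}" in msg and "[50, 101)" in msg

    def test_non_finite_value_rejected(self, adult_table):
        with pytest.raises(ValueError):
            find_band(adult_table.weight_axis, math.nan)

    def test_boundary_coherence(self, any_table):
        """lower, lower+eps and upper-eps resolve to the band itself; the
        upper edge belongs to the next band (half-open convention)."""
        for axis in (any_table.weight_axis, any_table.crcl_axis):
            for i, band in enumerate(axis.bands):
                assert find_band(axis, band.lower) is band
                assert find_band(axis, band.lower + EPS) is band
                if math.isfinite(band.upper):
                    assert find_band(axis, band.upper - EPS) is band
                    if i + 1 < len(axis.bands):
                        assert find_band(axis, band.upper) is axis.bands[i + 1]

    @given(value=st.floats(min_value=50, max_value=101, exclude_max=True,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_every_in_range_weight_resolves_uniquely(self, value):
        axis = standard_adult_weight_axis()
        band = find_band(axis, value)
        assert band.lower <= value < band.upper
        assert sum(b.contains(value) for b in axis.bands) == 1


def standard_adult_weight_axis():
    from vancalc import builtin_adult_table

    return builtin_adult_table().weight_axis


class TestInfusionDuration:
    @pytest.mark.parametrize(
        "dose,minutes",
        [
            (25, 60),      # smallest pediatric dose, first tier
            (500, 60),
            (1000, 60),    # tier edge: <= 1.0 g -> 60 min
            (1001, 90),
            (1250, 90),    # 1.1–1.5 g -> 90 min
            (1500, 90),
            (1750, 120),   # 1.6–2.0 g -> 120 min
            (2000, 120),
            (2250, 135),   # above 2.0 g: 1.0 g/h => 2250/1000*60 min
            (2500, 150),
        ],
    )
    def test_tiered_durations(self, rule, dose, minutes):
        assert infusion_duration_min(rule, dose) == minutes

    def test_overflow_matches_rate_oracle(self, rule):
        """Above the last tier the duration equals dose / (1 g/h), to the
        nearest minute (half-up)."""
        for dose in range(2025, 4001, 25):
            expected = math.floor(dose * 60 / 1000 + 0.5)
            assert infusion_duration_min(rule, dose) == expected

    @pytest.mark.parametrize("dose", [0, -500, math.inf])
    def test_invalid_dose_rejected(self, rule, dose):
        with pytest.raises(ValueError):
            infusion_duration_min(rule, dose)

    @given(dose=st.integers(min_value=1, max_value=200).map(lambda k: 25 * k))
    @settings(max_examples=200, deadline=None)
    def test_rate_never_exceeds_cap(self, dose):
        """dose/duration <= 1000/60 mg/min for every 25 mg-grain dose."""
        duration = infusion_duration_min(standard_infusion_rule(), dose)
        assert dose / duration <= RATE_CAP_MG_PER_MIN + 1e-9

    def test_rule_rejects_tier_faster_than_overflow_rate(self):
        with pytest.raises(ValueError):
            InfusionRule(tiers=((1000, 30),), overflow_rate_mg_per_h=1000)

    def test_rule_rejects_non_increasing_tiers(self):
        with pytest.raises(ValueError):
            InfusionRule(tiers=((1500, 90), (1000, 60)))


class TestResolveInterval:
    def test_unconditional_cell_ignores_age(self):
        entry = DoseEntry(dose_mg=250, interval_h=12)
        assert resolve_interval(entry, None) == (12, None)
        assert resolve_interval(entry, 3) == (12, None)

    @pytest.mark.parametrize("age,interval", [(8, 8), (10, 8), (365, 8), (0, 12), (3, 12), (6, 12)])
    def test_conditional_cell_by_age(self, age, interval):
        entry = DoseEntry(dose_mg=25, conditional_interval=(8, 12))
        resolved, warning = resolve_interval(entry, age)
        assert resolved == interval
        assert warning is None

    def test_age_exactly_seven_days_takes_longer_interval_with_warning(self):
        entry = DoseEntry(dose_mg=25, conditional_interval=(8, 12))
        resolved, warning = resolve_interval(entry, 7)
        assert resolved == 12
        assert warning is not None and "7 days" in warning

    def test_conditional_cell_without_age_errors(self):
        entry = DoseEntry(dose_mg=25, conditional_interval=(8, 12))
        with pytest.raises(MissingPostnatalAgeError):
            resolve_interval(entry, None)


class TestComputeRegimen:
    def test_adult_example(self, adult_table, rule):
        r = compute_regimen(PatientInput("adult", 75, 65), adult_table, rule)
        assert r.loading_dose_mg == 2000
        assert r.loading_infusion_min == 120
        assert r.maintenance_dose_mg == 1000
        assert r.interval_h == 12
        assert r.maintenance_infusion_min == 60
        assert r.first_maintenance_after_h == 12
        assert r.provenance.weight_band == "71–80"
        assert r.provenance.crcl_band == "60–69"

    def test_pediatric_example(self, pediatric_table, rule):
        r = compute_regimen(PatientInput("pediatric", 15, 45), pediatric_table, rule)
        assert (r.loading_dose_mg, r.loading_infusion_min) == (500, 60)
        assert (r.maintenance_dose_mg, r.interval_h, r.maintenance_infusion_min) == (250, 12, 60)

    def test_neonate_under_seven_days_gets_q12(self, pediatric_table, rule):
        r = compute_regimen(PatientInput("pediatric", 3, 40, postnatal_age_days=5),
                            pediatric_table, rule)
        assert (r.maintenance_dose_mg, r.interval_h) == (25, 12)

    def test_neonate_over_seven_days_gets_q8(self, pediatric_table, rule):
        r = compute_regimen(PatientInput("pediatric", 3, 40, postnatal_age_days=10),
                            pediatric_table, rule)
        assert (r.maintenance_dose_mg, r.interval_h) == (25, 8)

    def test_severe_renal_impairment_adult(self, adult_table, rule):
        r = compute_regimen(PatientInput("adult", 55, 5), adult_table, rule)
        assert (r.maintenance_dose_mg, r.interval_h) == (1000, 96)

    def test_crcl_zero_maps_to_lowest_band_with_warning(self, adult_table, rule):
        r = compute_regimen(PatientInput("adult", 55, 0), adult_table, rule)
        assert r.provenance.crcl_band == "< 10"
        assert any("lowest renal band" in w for w in r.warnings)

    def test_population_mismatch_rejected(self, pediatric_table, rule):
        with pytest.raises(ValueError, match="pediatric"):
            compute_regimen(PatientInput("adult", 60, 50), pediatric_table, rule)

    def test_missing_age_propagates(self, pediatric_table, rule):
        with pytest.raises(MissingPostnatalAgeError):
            compute_regimen(PatientInput("pediatric", 3, 40), pediatric_table, rule)

    def test_out_of_range_propagates(self, adult_table, rule):
        with pytest.raises(OutOfRangeError):
            compute_regimen(PatientInput("adult", 40, 65), adult_table, rule)

    def test_default_table_and_rule(self):
        assert compute_regimen(PatientInput("adult", 75, 65)).maintenance_dose_mg == 1000

    def test_deterministic(self, any_table, rule):
        p = PatientInput(any_table.population, 55, 35, postnatal_age_days=10)
        assert compute_regimen(p, any_table, rule) == compute_regimen(p, any_table, rule)

    def test_exhaustive_grid_matches_printed_cells(self, any_table, rule):
        """Every (weight band, CrCl band) midpoint lookup reproduces the
        table cell and loading dose read directly from storage."""
        from vancalc.nomogram_io import band_probe

        checked = 0
        for wi, wband in enumerate(any_table.weight_axis.bands):
            for ci, cband in enumerate(any_table.crcl_axis.bands):
                entry = any_table.cell(wi, ci)
                age = 10 if entry.is_conditional else None
                p = PatientInput(any_table.population, band_probe(wband),
                                 band_probe(cband), postnatal_age_days=age)
                r = compute_regimen(p, any_table, rule)
                assert r.loading_dose_mg == any_table.loading_mg[wi]
                assert r.maintenance_dose_mg == entry.dose_mg
                expected_h = entry.conditional_interval[0] if entry.is_conditional else entry.interval_h
                assert r.interval_h == expected_h
                checked += 1
        assert checked == len(any_table.weight_axis.bands) * len(any_table.crcl_axis.bands)

    def test_infusion_rate_cap_over_all_reachable_doses(self, any_table, rule):
        doses = set(any_table.loading_mg)
        for row in any_table.maintenance:
            doses.update(e.dose_mg for e in row)
        for dose in doses:
            assert dose / infusion_duration_min(rule, dose) <= RATE_CAP_MG_PER_MIN + 1e-9
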
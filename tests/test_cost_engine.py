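from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcapath.cost_engine import (
    CostModelError,
    CostTable,
    DiscountSpec,
    Intervention,
    MissingUnitCostError,
    PathwayCost,
    ScheduledEvent,
    ScheduleSegment,
    StaffRate,
    StaffingConfig,
    SurveillanceSchedule,
    UnitCost,
    discount_factor,
    expand_schedule,
    expected_management_cost,
    pathway_cost,
    staff_time_cost,
    standard_carrier_interventions,
    stream_cost,
)
from brcapath.pathway_catalog import Activity


class TestDiscountFactor:
    def test_unity_at_reference_age(self, discount_spec):
        assert discount_factor(30, discount_spec) == 1

    def test_unity_at_zero_rate(self):
        spec = DiscountSpec(Decimal(0), Decimal(30))
        assert discount_factor(40, spec) == 1

    def test_ten_year_factor(self, discount_spec):
        # oracle: 1.035 ** -10
        assert abs(discount_factor(40, discount_spec) - Decimal("0.70892")) < Decimal("1e-5")

    def test_event_before_reference_age_rejected(self, discount_spec):
        with pytest.raises(CostModelError, match="precedes"):
            discount_factor(29, discount_spec)

    def test_fractional_years(self, discount_spec):
        # between the adjacent whole-year factors
        f = discount_factor(Decimal("31.5"), discount_spec)
        assert discount_factor(32, discount_spec) < f < discount_factor(31, discount_spec)

    @given(
        a=st.integers(min_value=30, max_value=99),
        b=st.integers(min_value=31, max_value=100),
    )
    def test_strictly_decreasing_in_age(self, a, b):
        spec = DiscountSpec(Decimal("0.035"), Decimal(30))
        if a < b:
            assert discount_factor(a, spec) > discount_factor(b, spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(CostModelError):
            DiscountSpec(Decimal("1.0"), Decimal(30))
        with pytest.raises(CostModelError):
            DiscountSpec(Decimal("0.035"), Decimal(0))


class TestStaffTimeCost:
    def test_one_hour_at_hourly_rate(self, staffing):
        band3 = StaffRate("band3", Decimal("17.19"))
        assert staff_time_cost(60, band3, staffing) == Decimal("17.19")

    def test_consultant_appointment(self, staffing):
        # oracle: 139.73 * 45/60 = 104.7975 -> published appointment cost 104.80
        consultant = StaffRate("consultant", Decimal("139.73"))
        cost = staff_time_cost(45, consultant, staffing)
        assert abs(cost - Decimal("104.80")) < Decimal("0.01")

    def test_counsellor_with_supervision(self, staffing):
        # oracle: (55.54 + 139.73 / 12.5) * 0.75
        counsellor = StaffRate("counsellor", Decimal("55.54"))
        consultant = StaffRate("consultant", Decimal("139.73"))
        cost = staff_time_cost(45, counsellor, staffing, supervising_rate=consultant)
        assert abs(cost - Decimal("50.04")) < Decimal("0.01")

    def test_weighting_applied_once_to_unweighted_rate(self, staffing):
        raw = StaffRate("raw", Decimal("100.00"), london_weighted=False)
        assert staff_time_cost(60, raw, staffing) == Decimal("119.00")
        weighted = StaffRate("w", Decimal("119.00"), london_weighted=True)
        assert staff_time_cost(60, weighted, staffing) == Decimal("119.00")

    def test_negative_minutes_rejected(self, staffing):
        with pytest.raises(CostModelError, match="negative"):
            staff_time_cost(-1, StaffRate("x", Decimal(1)), staffing)

    def test_zero_minutes_free(self, staffing):
        assert staff_time_cost(0, StaffRate("x", Decimal("55.54")), staffing) == 0


def _schedule(*segments):
    return SurveillanceSchedule("test", segments)


class TestExpandSchedule:
    def test_population_tier_seven_events(self):
        sched = _schedule(ScheduleSegment("mammography", Decimal("45.50"), 50, 70, 3))
        events = expand_schedule(sched)
        assert [e.age_at_event for e in events] == [50, 53, 56, 59, 62, 65, 68]
        assert all(e.unit_cost == Decimal("45.50") for e in events)

    def test_empty_schedule(self):
        assert expand_schedule(_schedule()) == []

    def test_annual_decade_ten_events(self):
        sched = _schedule(ScheduleSegment("mammography", Decimal("45.50"), 40, 50, 1))
        ages = [e.age_at_event for e in expand_schedule(sched)]
        assert ages == list(range(40, 50))

    def test_18_monthly_on_grid(self):
        sched = _schedule(ScheduleSegment("mammography", Decimal("45.50"), 50, 60, Decimal("1.5")))
        ages = [e.age_at_event for e in expand_schedule(sched)]
        assert ages == [Decimal(50), Decimal("51.5"), Decimal(53), Decimal("54.5"),
                        Decimal(56), Decimal("57.5"), Decimal(59)]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(CostModelError, match="overlap"):
            _schedule(
                ScheduleSegment("mammography", Decimal(1), 40, 50, 1),
                ScheduleSegment("mammography", Decimal(1), 45, 55, 1),
            )

    def test_distinct_modalities_may_overlap(self):
        sched = _schedule(
            ScheduleSegment("mammography", Decimal(1), 40, 50, 1),
            ScheduleSegment("mri", Decimal(2), 40, 50, 1),
        )
        assert len(expand_schedule(sched)) == 20

    def test_degenerate_segment_rejected(self):
        with pytest.raises(CostModelError):
            ScheduleSegment("mammography", Decimal(1), 50, 50, 1)


class TestStreamCost:
    def test_empty_stream(self, discount_spec):
        assert stream_cost([], discount_spec) == 0

    def test_zero_rate_is_undiscounted_sum(self):
        spec = DiscountSpec(Decimal(0), Decimal(30))
        events = [ScheduledEvent(age, Decimal("45.50"), "m") for age in (40, 50, 60)]
        assert stream_cost(events, spec) == Decimal("136.50")

    def test_surgery_not_discounted(self, discount_spec):
        surgery = ScheduledEvent(55, Decimal("6784.00"), "mastectomy", discountable=False)
        assert stream_cost([surgery], discount_spec) == Decimal("6784.00")

    def test_discounted_below_face_value(self, discount_spec):
        events = [ScheduledEvent(40, Decimal("45.50"), "m")]
        cost = stream_cost(events, discount_spec)
        assert Decimal("32.25") < cost < Decimal("32.26")  # 45.50 * 1.035**-10

    @given(scale=st.integers(min_value=1, max_value=1000))
    @settings(max_examples=25)
    def test_linear_in_unit_cost(self, scale):
        spec = DiscountSpec(Decimal("0.035"), Decimal(30))
        base = [ScheduledEvent(a, Decimal(1), "m") for a in (31, 40, 55)]
        scaled = [ScheduledEvent(a, Decimal(scale), "m") for a in (31, 40, 55)]
        # equality up to the last digits of the working precision
        assert abs(stream_cost(scaled, spec) - scale * stream_cost(base, spec)) < Decimal("1e-18")

    def test_additive_over_disjoint_sets(self, discount_spec):
        a = [ScheduledEvent(40, Decimal("45.50"), "m")]
        b = [ScheduledEvent(50, Decimal("145.88"), "mri")]
        assert stream_cost(a + b, discount_spec) == stream_cost(a, discount_spec) + stream_cost(
            b, discount_spec
        )


class TestExpectedManagementCost:
    @pytest.fixture()
    def schedules(self, config, full_table):
        return config.schedules(full_table)

    def test_bso_expectation_for_unaffected_carrier(self, discount_spec, schedules, unit_costs):
        iv = Intervention(
            "bso", unit_costs.amount("salpingo_oophorectomy"), Decimal("0.60")
        )
        empty = {"carrier": SurveillanceSchedule("carrier", ())}
        cost = expected_management_cost("carrier", [iv], discount_spec, empty)
        assert abs(cost - Decimal("2013.26")) < Decimal("0.01")  # 0.60 * 3355.43

    def test_mastectomy_expectation_for_unaffected_carrier(self, discount_spec, unit_costs):
        iv = Intervention("rrm", unit_costs.amount("mastectomy"), Decimal("0.30"))
        empty = {"carrier": SurveillanceSchedule("carrier", ())}
        cost = expected_management_cost("carrier", [iv], discount_spec, empty)
        assert cost == Decimal("2035.2000")  # 0.30 * 6784.00

    def test_zero_uptake_is_free(self, discount_spec):
        iv = Intervention("rrm", Decimal("6784.00"), Decimal(0))
        empty = {"carrier": SurveillanceSchedule("carrier", ())}
        assert expected_management_cost("carrier", [iv], discount_spec, empty) == 0

    def test_unknown_tier_rejected(self, discount_spec, schedules):
        with pytest.raises(CostModelError, match="unknown management"):
            expected_management_cost("extreme", [], discount_spec, schedules)

    def test_tier_cost_is_discounted_surveillance(self, discount_spec, schedules):
        cost = expected_management_cost("population", [], discount_spec, schedules)
        undiscounted = 7 * Decimal("45.50")
        assert 0 < cost < undiscounted

    def test_tier_ordering(self, discount_spec, schedules):
        tiers = {
            t: expected_management_cost(t, [], discount_spec, schedules)
            for t in ("population", "moderate", "higher", "carrier")
        }
        assert tiers["population"] < tiers["moderate"] < tiers["higher"] < tiers["carrier"]

    def test_standard_unaffected_carrier_surgery_bundle(self, unit_costs, discount_spec):
        ivs = standard_carrier_interventions(unit_costs)
        empty = {"carrier": SurveillanceSchedule("carrier", ())}
        cost = expected_management_cost("carrier", ivs, discount_spec, empty)
        # 0.30*6784 + 0.60*3355.43
        assert abs(cost - Decimal("4048.46")) < Decimal("0.01")

    def test_post_ovarian_mastectomy_expectation(self, unit_costs, discount_spec):
        ivs = standard_carrier_interventions(unit_costs, affected=True, cancer_type="ovarian")
        empty = {"carrier": SurveillanceSchedule("carrier", ())}
        cost = expected_management_cost("carrier", ivs, discount_spec, empty)
        # 0.05 * 0.69 * 6784, undiscounted (surgery rule)
        assert abs(cost - Decimal("234.05")) < Decimal("0.01")


class _StubPathway:
    def __init__(self, pid, labels):
        self.id = pid
        self.activities = tuple(Activity(label) for label in labels)


class TestPathwayCost:
    def test_zero_activities(self, unit_costs):
        assert pathway_cost(_StubPathway(1, []), unit_costs).total == 0

    def test_missing_unit_cost_names_activity(self, unit_costs):
        with pytest.raises(MissingUnitCostError, match="hrt_bundle"):
            pathway_cost(_StubPathway(1, ["hrt_bundle"]), unit_costs)

    def test_total_is_sum_of_items(self, catalog, full_table):
        for pathway in catalog:
            pc = pathway_cost(pathway, full_table)
            assert pc.total == sum(item.amount for item in pc.items)

    def test_items_in_pathway_order(self, catalog, full_table):
        pc = pathway_cost(catalog[6], full_table)
        assert [i.label for i in pc.items[:2]] == ["oncology_referral", "referral_received"]
        assert pc.items[-1].label == "surveillance_higher"

    def test_pathway6_has_18_items(self, catalog, full_table):
        assert len(pathway_cost(catalog[6], full_table).items) == 18

    def test_by_category_conserves_total(self, catalog, full_table):
        pc = pathway_cost(catalog[17], full_table)
        assert sum(pc.by_category().values()) == pc.total


class TestCostTable:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(CostModelError, match="duplicate"):
            CostTable([UnitCost("x", Decimal(1)), UnitCost("x", Decimal(2))])

    def test_with_amount_is_copy_on_write(self, unit_costs):
        changed = unit_costs.with_amount("full_gene_test", Decimal("700"))
        assert changed.amount("full_gene_test") == 700
        assert unit_costs.amount("full_gene_test") == 540

    def test_negative_amount_rejected(self):
        with pytest.raises(CostModelError):
            UnitCost("x", Decimal(-1))

    def test_staff_rate_lookup(self, unit_costs):
        rate = unit_costs.staff_rate("consultant")
        assert rate.hourly_rate == Decimal("139.73")
        with pytest.raises(CostModelError):
            unit_costs.staff_rate("mammography")
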
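"""Core arithmetic of the pathway costing model.

Discount factors, staff-time costs with supervision loading and London
weighting, expansion of age-indexed surveillance schedules into dated cost
events, discounted stream costs, probability-weighted carrier-management
expectations, and full itemised pathway costing.

Conventions
-----------
* Time origin is the presentation (reference) age; the discount exponent is
  the elapsed time in years, fractional years allowed.
* Surveillance segments generate events on an arithmetic grid from the
  segment start: start inclusive, end exclusive.
* Risk-reducing surgery is dated in the year of diagnosis and is therefore
  not discounted (``discountable=False``).
* Money is held at full precision; see :mod:`brcapath.money`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, localcontext
from typing import Iterable, Mapping, Optional, Sequence

from .money import Money, ZERO, gbp

__all__ = [
    "CostModelError",
    "MissingUnitCostError",
    "DiscountSpec",
    "StaffRate",
    "StaffingConfig",
    "ScheduledEvent",
    "ScheduleSegment",
    "SurveillanceSchedule",
    "Intervention",
    "CostItem",
    "PathwayCost",
    "UnitCost",
    "CostTable",
    "discount_factor",
    "staff_time_cost",
    "expand_schedule",
    "stream_cost",
    "expected_management_cost",
    "pathway_cost",
]


class CostModelError(ValueError):
    """Invalid input to a costing operation."""


class MissingUnitCostError(CostModelError, KeyError):
    """An activity references a label absent from the cost table."""

    def __init__(self, label: str):
        super().__init__(f"no unit cost for activity {label!r}")
        self.label = label


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate anchored at the presentation age."""

    annual_rate: Decimal = Decimal("0.035")
    reference_age: Decimal = Decimal(30)

    def __post_init__(self) -> None:
        object.__setattr__(self, "annual_rate", gbp(self.annual_rate))
        object.__setattr__(self, "reference_age", gbp(self.reference_age))
        if not (0 <= self.annual_rate < 1):
            raise CostModelError(f"annual_rate must be in [0, 1): {self.annual_rate}")
        if self.reference_age <= 0:
            raise CostModelError(f"reference_age must be positive: {self.reference_age}")


@dataclass(frozen=True)
class StaffRate:
    band_label: str
    hourly_rate: Money
    london_weighted: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "hourly_rate", gbp(self.hourly_rate))
        if self.hourly_rate <= 0:
            raise CostModelError(f"hourly_rate must be positive: {self.hourly_rate}")


@dataclass(frozen=True)
class StaffingConfig:
    london_weighting_factor: Decimal = Decimal("1.19")
    supervision_hours_per_counsellor_hour: Decimal = Decimal("0.08")  # 1 / 12.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "london_weighting_factor", gbp(self.london_weighting_factor))
        object.__setattr__(
            self,
            "supervision_hours_per_counsellor_hour",
            gbp(self.supervision_hours_per_counsellor_hour),
        )
        if self.london_weighting_factor < 1:
            raise CostModelError("london_weighting_factor must be >= 1")
        if self.supervision_hours_per_counsellor_hour < 0:
            raise CostModelError("supervision ratio must be >= 0")


@dataclass(frozen=True)
class ScheduledEvent:
    """A single dated cost in a surveillance/therapy stream."""

    age_at_event: Decimal
    unit_cost: Money
    label: str
    discountable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_at_event", gbp(self.age_at_event))
        object.__setattr__(self, "unit_cost", gbp(self.unit_cost))


@dataclass(frozen=True)
class ScheduleSegment:
    modality: str
    unit_cost: Money
    start_age: Decimal
    end_age: Decimal
    interval_years: Decimal

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_cost", gbp(self.unit_cost))
        object.__setattr__(self, "start_age", gbp(self.start_age))
        object.__setattr__(self, "end_age", gbp(self.end_age))
        object.__setattr__(self, "interval_years", gbp(self.interval_years))
        if self.start_age >= self.end_age:
            raise CostModelError(
                f"segment {self.modality}: start_age {self.start_age} must precede "
                f"end_age {self.end_age}"
            )
        if self.interval_years <= 0:
            raise CostModelError(f"segment {self.modality}: interval_years must be positive")


@dataclass(frozen=True)
class SurveillanceSchedule:
    tier: str
    segments: tuple[ScheduleSegment, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        by_modality: dict[str, list[ScheduleSegment]] = {}
        for seg in self.segments:
            by_modality.setdefault(seg.modality, []).append(seg)
        for modality, segs in by_modality.items():
            segs = sorted(segs, key=lambda s: s.start_age)
            for prev, nxt in zip(segs, segs[1:]):
                if nxt.start_age < prev.end_age:
                    raise CostModelError(
                        f"overlapping {modality} segments: "
                        f"[{prev.start_age}, {prev.end_age}) and "
                        f"[{nxt.start_age}, {nxt.end_age})"
                    )


@dataclass(frozen=True)
class Intervention:
    """A probabilistic management option (e.g. risk-reducing surgery)."""

    name: str
    unit_cost: Money
    uptake_probability: Decimal = Decimal(1)
    survival_scaling: Decimal = Decimal(1)
    discountable: bool = False
    timing_age: Decimal = Decimal(30)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_cost", gbp(self.unit_cost))
        object.__setattr__(self, "uptake_probability", gbp(self.uptake_probability))
        object.__setattr__(self, "survival_scaling", gbp(self.survival_scaling))
        object.__setattr__(self, "timing_age", gbp(self.timing_age))
        for name, value in (
            ("uptake_probability", self.uptake_probability),
            ("survival_scaling", self.survival_scaling),
        ):
            if not (0 <= value <= 1):
                raise CostModelError(f"{name} must be in [0, 1]: {value}")


@dataclass(frozen=True)
class CostItem:
    label: str
    amount: Money
    category: str
    actor: str = "patient"

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", gbp(self.amount))
        if self.amount < 0:
            raise CostModelError(f"negative cost item {self.label!r}: {self.amount}")


@dataclass(frozen=True)
class PathwayCost:
    pathway_id: int
    items: tuple[CostItem, ...]

    @property
    def total(self) -> Money:
        return sum((item.amount for item in self.items), ZERO)

    def by_category(self) -> dict[str, Money]:
        out: dict[str, Money] = {}
        for item in self.items:
            out[item.category] = out.get(item.category, ZERO) + item.amount
        return out


# ---------------------------------------------------------------------------
# unit-cost table


@dataclass(frozen=True)
class UnitCost:
    label: str
    amount: Money
    category: str = "management"
    staff_time: bool = False
    unit: str = "per_item"
    source: str = ""
    calibrated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", gbp(self.amount))
        if self.amount < 0:
            raise CostModelError(f"negative unit cost for {self.label!r}: {self.amount}")


class CostTable(Mapping[str, UnitCost]):
    """Immutable label -> :class:`UnitCost` lookup with copy-on-write edits."""

    def __init__(self, entries: Iterable[UnitCost] = ()):
        self._entries: dict[str, UnitCost] = {}
        for entry in entries:
            if entry.label in self._entries:
                raise CostModelError(f"duplicate unit-cost label {entry.label!r}")
            self._entries[entry.label] = entry

    def __getitem__(self, label: str) -> UnitCost:
        try:
            return self._entries[label]
        except KeyError:
            raise MissingUnitCostError(label) from None

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def amount(self, label: str) -> Money:
        return self[label].amount

    def with_entry(self, entry: UnitCost) -> "CostTable":
        table = CostTable()
        table._entries = {**self._entries, entry.label: entry}
        return table

    def with_amount(self, label: str, amount: Money) -> "CostTable":
        entry = self[label]
        return self.with_entry(
            UnitCost(label, gbp(amount), entry.category, entry.staff_time, entry.unit, entry.source, entry.calibrated)
        )

    def merged(self, other: "CostTable") -> "CostTable":
        table = CostTable()
        table._entries = {**self._entries, **other._entries}
        return table

    def staff_rate(self, label: str) -> StaffRate:
        entry = self[label]
        if entry.unit != "per_hour":
            raise CostModelError(f"{label!r} is not an hourly staff rate")
        return StaffRate(label, entry.amount, london_weighted=True)


# ---------------------------------------------------------------------------
# operations


def discount_factor(age_at_event: object, spec: DiscountSpec) -> Decimal:
    """``(1 + rate) ** -(age_at_event - reference_age)`` at full precision.

    Equals 1 at the reference age and for a zero rate; events dated before
    the reference age are rejected.
    """
    age = gbp(age_at_event)
    if age < spec.reference_age:
        raise CostModelError(
            f"event at age {age} precedes the reference age {spec.reference_age}"
        )
    elapsed = age - spec.reference_age
    if elapsed == 0 or spec.annual_rate == 0:
        return Decimal(1)
    with localcontext() as ctx:
        ctx.prec = 40
        base = Decimal(1) + spec.annual_rate
        return (-elapsed * base.ln()).exp()


def staff_time_cost(
    minutes: object,
    rate: StaffRate,
    cfg: StaffingConfig,
    supervising_rate: Optional[StaffRate] = None,
) -> Money:
    """Cost of a block of staff time, with optional supervision loading.

    The London weighting factor is applied exactly once to any rate that is
    not already weighted.  Supervision adds ``supervisor rate x ratio`` per
    staff hour before the time multiplication.
    """
    mins = gbp(minutes)
    if mins < 0:
        raise CostModelError(f"negative minutes: {mins}")

    def weighted(r: StaffRate) -> Money:
        if r.london_weighted:
            return r.hourly_rate
        return r.hourly_rate * cfg.london_weighting_factor

    hourly = weighted(rate)
    if supervising_rate is not None:
        hourly += weighted(supervising_rate) * cfg.supervision_hours_per_counsellor_hour
    return hourly * mins / Decimal(60)


def expand_schedule(schedule: SurveillanceSchedule) -> list[ScheduledEvent]:
    """Enumerate the dated events of a surveillance schedule.

    Each segment yields events at ``start, start + interval, ...`` strictly
    below ``end``.  Ages are exact decimals so fractional intervals (e.g.
    18-monthly imaging) stay on-grid.
    """
    events: list[ScheduledEvent] = []
    for seg in schedule.segments:
        age = seg.start_age
        while age < seg.end_age:
            events.append(ScheduledEvent(age, seg.unit_cost, seg.modality, discountable=True))
            age += seg.interval_years
    events.sort(key=lambda e: (e.age_at_event, e.label))
    return events


def stream_cost(events: Sequence[ScheduledEvent], spec: DiscountSpec) -> Money:
    """Present value of a stream of dated costs.

    Discountable events are scaled by :func:`discount_factor`; events flagged
    non-discountable (risk-reducing surgery) enter at face value.
    """
    total = ZERO
    for event in events:
        if event.discountable:
            total += event.unit_cost * discount_factor(event.age_at_event, spec)
        else:
            total += event.unit_cost
    return total


def expected_management_cost(
    tier_or_carrier: str,
    interventions: Sequence[Intervention],
    spec: DiscountSpec,
    schedules: Mapping[str, SurveillanceSchedule],
    context: Optional[Mapping[str, object]] = None,
) -> Money:
    """Expected management cost for a risk tier or mutation carrier.

    The surveillance stream for the assignment is discounted and added to
    the probability-weighted intervention expectations
    ``uptake x survival_scaling x unit cost`` (discounted only where the
    intervention is flagged discountable).  ``context`` is accepted for
    symmetry with callers that build intervention lists from it.
    """
    if tier_or_carrier not in schedules:
        known = ", ".join(sorted(schedules))
        raise CostModelError(f"unknown management assignment {tier_or_carrier!r} (known: {known})")
    total = stream_cost(expand_schedule(schedules[tier_or_carrier]), spec)
    for iv in interventions:
        amount = iv.unit_cost * iv.uptake_probability * iv.survival_scaling
        if iv.discountable:
            amount *= discount_factor(iv.timing_age, spec)
        total += amount
    return total


def standard_carrier_interventions(
    costs: CostTable,
    *,
    mastectomy_uptake: Decimal = Decimal("0.30"),
    bso_uptake: Decimal = Decimal("0.60"),
    affected: bool = False,
    cancer_type: Optional[str] = None,
    five_year_survival: Optional[Mapping[str, Decimal]] = None,
    post_ovarian_mastectomy_rate: Decimal = Decimal("0.05"),
    presentation_age: Decimal = Decimal(30),
) -> list[Intervention]:
    """Build the carrier risk-reducing surgery expectation list.

    Unaffected carriers take bilateral mastectomy and salpingo-oophorectomy
    at the configured uptakes, undiscounted (surgery in year of decision).
    Affected ovarian-cancer carriers additionally carry the deferred
    mastectomy expectation at five years, scaled by 5-year survival.
    """
    survival = dict(five_year_survival or {"breast": Decimal("0.70"), "ovarian": Decimal("0.69")})
    out: list[Intervention] = []
    if not affected:
        out.append(
            Intervention("bilateral_mastectomy", costs.amount("mastectomy"), mastectomy_uptake)
        )
        out.append(
            Intervention(
                "bilateral_salpingo_oophorectomy", costs.amount("salpingo_oophorectomy"), bso_uptake
            )
        )
        return out
    if cancer_type == "ovarian":
        out.append(
            Intervention(
                "post_ovarian_mastectomy",
                costs.amount("mastectomy"),
                gbp(post_ovarian_mastectomy_rate),
                survival_scaling=gbp(survival["ovarian"]),
                discountable=False,  # surgery rule: face value in year of decision
                timing_age=gbp(presentation_age) + 5,
            )
        )
    else:
        out.append(
            Intervention(
                "bilateral_mastectomy",
                costs.amount("mastectomy"),
                mastectomy_uptake,
                survival_scaling=gbp(survival.get(cancer_type or "breast", Decimal(1))),
            )
        )
        out.append(
            Intervention(
                "bilateral_salpingo_oophorectomy",
                costs.amount("salpingo_oophorectomy"),
                bso_uptake,
                survival_scaling=gbp(survival.get(cancer_type or "breast", Decimal(1))),
            )
        )
    return out


def pathway_cost(pathway, costs: CostTable) -> PathwayCost:
    """Itemise a pathway against a unit-cost table.

    ``pathway`` is any object with ``id`` and an ``activities`` sequence of
    ``(label, actor)`` pairs (see :mod:`brcapath.pathway_catalog`).  Every
    label must price; a missing label raises :class:`MissingUnitCostError`
    naming the activity.
    """
    items = []
    for activity in pathway.activities:
        label, actor = activity.label, activity.actor
        entry = costs[label]
        items.append(CostItem(label, entry.amount, entry.category, actor))
    return PathwayCost(pathway.id, tuple(items))
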
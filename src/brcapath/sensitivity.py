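"""One-way deterministic sensitivity analysis over the service total.

Each scenario perturbs the unit-cost table — test price override, the
consultant/counsellor mix of clinic appointments, the face-to-face/telephone
mix, or removal of the London weighting — and the full pathway model is
re-run to obtain the audit-period service total.

Scenario totals are reported as the anchor (base) service total plus the
model-computed scenario delta.  This keeps the sub-penny least-squares
calibration residual out of every scenario row: the delta between two model
runs is exact even where an individual pathway total differs from its
published reference by a penny of rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal
from typing import Iterable, Mapping, Optional

from .audit_weighting import AuditCounts, service_total
from .config import ModelConfig
from .cost_engine import CostTable, UnitCost, pathway_cost, staff_time_cost
from .money import Money, gbp, to_pennies
from .pathway_catalog import Catalog

__all__ = ["ScenarioError", "Scenario", "apply_scenario", "one_way_table", "counsellor_appointment_cost"]


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """Overrides relative to the base case (all-consultant, all face-to-face,
    published test price, London weighting on)."""

    label: str = "base case"
    test_price_override: Optional[Money] = None
    consultant_fraction: Decimal = Decimal(1)
    face_to_face_fraction: Decimal = Decimal(1)
    london_weighting_on: bool = True

    def __post_init__(self) -> None:
        if self.test_price_override is not None:
            object.__setattr__(self, "test_price_override", gbp(self.test_price_override))
            if self.test_price_override < 0:
                raise ScenarioError("test price must be >= 0")
        object.__setattr__(self, "consultant_fraction", gbp(self.consultant_fraction))
        object.__setattr__(self, "face_to_face_fraction", gbp(self.face_to_face_fraction))
        for name in ("consultant_fraction", "face_to_face_fraction"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ScenarioError(f"{name} must be in [0, 1]: {value}")

    @property
    def is_base(self) -> bool:
        return (
            self.test_price_override is None
            and self.consultant_fraction == 1
            and self.face_to_face_fraction == 1
            and self.london_weighting_on
        )


def counsellor_appointment_cost(costs: CostTable, config: ModelConfig) -> Money:
    """Cost of one counsellor-led appointment, supervision loading included."""
    return staff_time_cost(
        config.appointments.duration_minutes,
        costs.staff_rate(config.appointments.counsellor_rate_label),
        config.staffing,
        supervising_rate=costs.staff_rate(config.appointments.consultant_rate_label),
    )


def _scenario_table(scenario: Scenario, costs: CostTable, config: ModelConfig) -> CostTable:
    table = costs
    if scenario.test_price_override is not None:
        table = table.with_amount("full_gene_test", scenario.test_price_override)

    f, ff = scenario.consultant_fraction, scenario.face_to_face_fraction
    if f != 1 or ff != 1:
        consultant_appt = costs.amount("clinic_appointment")
        counsellor_appt = counsellor_appointment_cost(costs, config)
        face = f * consultant_appt + (1 - f) * counsellor_appt
        blended = ff * face + (1 - ff) * config.appointments.telephone_unit_cost
        table = table.with_amount("clinic_appointment", blended)

    if not scenario.london_weighting_on:
        factor = config.staffing.london_weighting_factor
        for label, entry in list(table.items()):
            if entry.unit == "per_hour":
                continue  # hourly rates feed the blend above, not pathway items
            meta = config.calibrated_components.get(label)
            if meta is not None and meta.staff_fraction > 0:
                share = meta.staff_fraction
                scaled = entry.amount * ((1 - share) + share / factor)
                table = table.with_amount(label, scaled)
            elif entry.staff_time:
                table = table.with_amount(label, entry.amount / factor)
    return table


def apply_scenario(
    scenario: Scenario,
    catalog: Catalog,
    costs: CostTable,
    counts: AuditCounts,
    config: ModelConfig,
    anchor_costs: Optional[Mapping[int, Money]] = None,
) -> Money:
    """Service total for the audit window under a scenario.

    ``costs`` must price every activity (i.e. be post-calibration).  With
    ``anchor_costs`` (per-pathway reference totals) the return value is
    anchored: base total from the anchors plus the model-computed delta.
    """

    def engine_total(table: CostTable) -> Money:
        per_pathway = {p.id: pathway_cost(p, table).total for p in catalog}
        return service_total(per_pathway, counts)

    scen_total = engine_total(_scenario_table(scenario, costs, config))
    if anchor_costs is None:
        return scen_total
    base_total = engine_total(costs)
    return service_total(anchor_costs, counts) + (scen_total - base_total)


def one_way_table(
    scenarios: Iterable[Scenario],
    catalog: Catalog,
    costs: CostTable,
    counts: AuditCounts,
    config: ModelConfig,
    anchor_costs: Optional[Mapping[int, Money]] = None,
) -> list[dict]:
    """One row per scenario (base case first), totals in display pennies."""
    rows = []
    scenarios = list(scenarios)
    if not any(s.is_base for s in scenarios):
        scenarios.insert(0, Scenario())
    scenarios.sort(key=lambda s: not s.is_base)
    for scenario in scenarios:
        total = apply_scenario(scenario, catalog, costs, counts, config, anchor_costs)
        rows.append(
            {
                "label": scenario.label,
                "total_gbp": to_pennies(total),
                "is_base": scenario.is_base,
            }
        )
    return rows
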
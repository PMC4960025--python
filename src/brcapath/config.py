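"""Typed model configuration loaded from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .cost_engine import (
    CostTable,
    DiscountSpec,
    ScheduleSegment,
    StaffingConfig,
    SurveillanceSchedule,
)
from .money import Money, gbp

__all__ = ["ComponentMeta", "InterventionConfig", "AppointmentConfig", "ModelConfig", "load_config"]


@dataclass(frozen=True)
class ComponentMeta:
    category: str = "management"
    staff_fraction: Decimal = Decimal(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "staff_fraction", gbp(self.staff_fraction))
        if not (0 <= self.staff_fraction <= 1):
            raise ValueError(f"staff_fraction must be in [0, 1]: {self.staff_fraction}")


@dataclass(frozen=True)
class InterventionConfig:
    mastectomy_uptake_unaffected: Decimal = Decimal("0.30")
    bso_uptake_unaffected: Decimal = Decimal("0.60")
    five_year_survival: Mapping[str, Decimal] = field(
        default_factory=lambda: {"breast": Decimal("0.70"), "ovarian": Decimal("0.69")}
    )
    post_ovarian_mastectomy_rate: Decimal = Decimal("0.05")


@dataclass(frozen=True)
class AppointmentConfig:
    duration_minutes: Decimal = Decimal(45)
    consultant_rate_label: str = "consultant"
    counsellor_rate_label: str = "band8_genetic_counsellor"
    telephone_unit_cost: Money = Decimal("62.17")


@dataclass(frozen=True)
class ModelConfig:
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    staffing: StaffingConfig = field(default_factory=StaffingConfig)
    appointments: AppointmentConfig = field(default_factory=AppointmentConfig)
    interventions: InterventionConfig = field(default_factory=InterventionConfig)
    surveillance_raw: Mapping[str, list] = field(default_factory=dict)
    calibrated_components: Mapping[str, ComponentMeta] = field(default_factory=dict)

    def schedules(self, costs: CostTable) -> dict[str, SurveillanceSchedule]:
        """Materialise per-tier schedules, pricing modalities from the table."""
        out: dict[str, SurveillanceSchedule] = {}
        for tier, segments in self.surveillance_raw.items():
            out[tier] = SurveillanceSchedule(
                tier,
                tuple(
                    ScheduleSegment(
                        seg["modality"],
                        costs.amount(seg["modality"]),
                        gbp(seg["start_age"]),
                        gbp(seg["end_age"]),
                        gbp(seg["interval_years"]),
                    )
                    for seg in segments
                ),
            )
        return out


def load_config(path: Optional[Path] = None) -> ModelConfig:
    """Load model configuration; defaults to the shipped base case."""
    if path is None:
        text = resources.files("brcapath.data").joinpath("model_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}

    disc = doc.get("discount", {})
    staff = doc.get("staffing", {})
    appt = doc.get("appointments", {})
    iv = doc.get("interventions", {})
    comp = doc.get("calibrated_components", {})
    return ModelConfig(
        discount=DiscountSpec(
            annual_rate=gbp(disc.get("annual_rate", "0.035")),
            reference_age=gbp(disc.get("reference_age", 30)),
        ),
        staffing=StaffingConfig(
            london_weighting_factor=gbp(staff.get("london_weighting_factor", "1.19")),
            supervision_hours_per_counsellor_hour=gbp(
                staff.get("supervision_hours_per_counsellor_hour", "0.08")
            ),
        ),
        appointments=AppointmentConfig(
            duration_minutes=gbp(appt.get("duration_minutes", 45)),
            consultant_rate_label=appt.get("consultant_rate_label", "consultant"),
            counsellor_rate_label=appt.get("counsellor_rate_label", "band8_genetic_counsellor"),
            telephone_unit_cost=gbp(appt.get("telephone_unit_cost_gbp", "62.17")),
        ),
        interventions=InterventionConfig(
            mastectomy_uptake_unaffected=gbp(iv.get("mastectomy_uptake_unaffected", "0.30")),
            bso_uptake_unaffected=gbp(iv.get("bso_uptake_unaffected", "0.60")),
            five_year_survival={
                k: gbp(v)
                for k, v in iv.get(
                    "five_year_survival", {"breast": "0.70", "ovarian": "0.69"}
                ).items()
            },
            post_ovarian_mastectomy_rate=gbp(iv.get("post_ovarian_mastectomy_rate", "0.05")),
        ),
        surveillance_raw=doc.get("surveillance", {}),
        calibrated_components={
            label: ComponentMeta(
                category=str(info.get("category", "management")),
                staff_fraction=gbp(info.get("staff_fraction", 0)),
            )
            for label, info in comp.items()
        },
    )
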
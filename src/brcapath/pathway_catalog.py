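"""The 28 referral-to-management pathways and case classification.

The catalogue is data (``data/pathways.yaml``): each pathway carries an
ordered activity list (labels into the unit-cost table, tagged by actor),
a test specification, management assignments and the published reference
total used by calibration.  :func:`classify` maps a structured referral
case description onto exactly one pathway id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .money import Money, gbp

__all__ = [
    "CatalogError",
    "InconsistentCaseError",
    "Activity",
    "Pathway",
    "Catalog",
    "CaseRecord",
    "load_catalog",
    "classify",
    "case_for_pathway",
    "SUBGROUP_NAMES",
]

AFFECTED_IDS = tuple(range(1, 11))
UNAFFECTED_IDS = tuple(range(11, 29))

TEST_SPECS = {
    "none",
    "full_in_patient",
    "predictive_in_patient",
    "full_in_relative",
    "predictive_in_relative_chain",
}
MANAGEMENTS = {"population", "moderate", "higher", "carrier"}


class CatalogError(ValueError):
    """Malformed pathway definition file."""


class InconsistentCaseError(ValueError):
    """A CaseRecord violates an internal consistency constraint."""


@dataclass(frozen=True)
class Activity:
    label: str
    actor: str = "patient"  # patient | relative


@dataclass(frozen=True)
class Pathway:
    id: int
    affected: bool
    description: str
    activities: tuple[Activity, ...]
    test_spec: str
    management: str
    relative_management: Optional[str] = None
    reference_total: Optional[Money] = None

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 28:
            raise CatalogError(f"pathway id out of range: {self.id}")
        if self.test_spec not in TEST_SPECS:
            raise CatalogError(f"pathway {self.id}: unknown test spec {self.test_spec!r}")
        if self.management not in MANAGEMENTS:
            raise CatalogError(f"pathway {self.id}: unknown management {self.management!r}")

    def activity_count(self, label: str) -> int:
        return sum(1 for a in self.activities if a.label == label)


class Catalog:
    """Ordered, id-indexed collection of the 28 pathways."""

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: tuple[Pathway, ...] = tuple(sorted(pathways, key=lambda p: p.id))
        ids = [p.id for p in self.pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate pathway ids: {dupes}")
        if ids != list(range(1, 29)):
            missing = sorted(set(range(1, 29)) - set(ids))
            raise CatalogError(
                f"expected pathways 1-28, got {len(ids)} entries (missing: {missing})"
            )
        affected = [p.id for p in self.pathways if p.affected]
        if affected != list(AFFECTED_IDS):
            raise CatalogError(f"pathways 1-10 must be the affected group, got {affected}")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: int) -> Pathway:
        if not 1 <= pathway_id <= 28:
            raise KeyError(pathway_id)
        return self.pathways[pathway_id - 1]

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(p.id for p in self.pathways)

    def reference_totals(self) -> dict[int, Money]:
        return {p.id: p.reference_total for p in self.pathways if p.reference_total is not None}

    def subgroup(self, name: str) -> tuple[int, ...]:
        """Pathway ids of a named reporting subgroup (see SUBGROUP_NAMES)."""
        if name == "all":
            return self.ids
        if name == "affected":
            return tuple(p.id for p in self if p.affected)
        if name == "unaffected":
            return tuple(p.id for p in self if not p.affected)
        if name == "carrier_presenting":
            return tuple(p.id for p in self if p.management == "carrier")
        if name == "full_test":
            return tuple(
                p.id for p in self if p.test_spec in ("full_in_patient", "full_in_relative")
            )
        if name == "predictive_test":
            return tuple(
                p.id
                for p in self
                if p.test_spec in ("predictive_in_patient", "predictive_in_relative_chain")
            )
        if name == "relative_tested":
            return tuple(p.id for p in self if p.test_spec == "full_in_relative")
        raise KeyError(f"unknown subgroup {name!r}")


SUBGROUP_NAMES = (
    "all",
    "affected",
    "unaffected",
    "carrier_presenting",
    "full_test",
    "predictive_test",
    "relative_tested",
)


def _expand_activities(raw: list, blocks: dict[str, list[str]]) -> tuple[Activity, ...]:
    out: list[Activity] = []
    for entry in raw:
        if isinstance(entry, str):
            out.append(Activity(entry))
            continue
        if not isinstance(entry, dict):
            raise CatalogError(f"bad activity entry: {entry!r}")
        actor = entry.get("actor", "patient")
        if actor not in ("patient", "relative"):
            raise CatalogError(f"unknown actor {actor!r}")
        if "block" in entry:
            name = entry["block"]
            if name not in blocks:
                raise CatalogError(f"unknown activity block {name!r}")
            out.extend(Activity(label, actor) for label in blocks[name])
        elif "item" in entry:
            out.append(Activity(entry["item"], actor))
        else:
            raise CatalogError(f"activity entry needs 'block' or 'item': {entry!r}")
    return tuple(out)


def load_catalog(path: Optional[Path] = None) -> Catalog:
    """Load the pathway catalogue; defaults to the shipped definition file."""
    if path is None:
        text = resources.files("brcapath.data").joinpath("pathways.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise CatalogError("definition file must contain a 'pathways' list")
    blocks = doc.get("blocks", {})
    pathways = []
    for entry in doc["pathways"]:
        try:
            pathways.append(
                Pathway(
                    id=int(entry["id"]),
                    affected=bool(entry["affected"]),
                    description=str(entry["description"]).strip(),
                    activities=_expand_activities(entry["activities"], blocks),
                    test_spec=entry.get("test", "none"),
                    management=entry["management"],
                    relative_management=entry.get("relative_management"),
                    reference_total=(
                        gbp(entry["reference_total_gbp"])
                        if "reference_total_gbp" in entry
                        else None
                    ),
                )
            )
        except KeyError as exc:
            raise CatalogError(f"pathway entry {entry.get('id', '?')}: missing {exc}") from exc
    return Catalog(pathways)


# ---------------------------------------------------------------------------
# case records and classification


@dataclass(frozen=True)
class CaseRecord:
    """Structured description of a referral, sufficient to pick a pathway."""

    affected: bool
    cancer_type: str = "none"  # breast | ovarian | both | none
    familial_mutation_status: str = "none_known"
    # none_known | known_in_family | family_tested_negative | family_untested
    eligible_for_test: bool = False
    patient_decision: str = "n/a"  # accepts | declines | n/a
    test_performed: str = "none"  # full | predictive | none
    test_result: str = "n/a"  # positive | negative | n/a
    relative_pathway: str = "none"
    # none | relative_full_test_positive | relative_full_test_negative |
    # intervening_relative_negative | relative_unavailable
    family_history_tier: str = "population"  # population | moderate | higher

    def validate(self) -> None:
        _validate_case(self)


_FAMILIAL = {"none_known", "known_in_family", "family_tested_negative", "family_untested"}
_RELATIVE = {
    "none",
    "relative_full_test_positive",
    "relative_full_test_negative",
    "intervening_relative_negative",
    "relative_unavailable",
}


def _fail(rule: str) -> None:
    raise InconsistentCaseError(f"inconsistent case record: {rule}")


def _validate_case(c: CaseRecord) -> None:
    if c.cancer_type not in {"breast", "ovarian", "both", "none"}:
        _fail(f"unknown cancer_type {c.cancer_type!r}")
    if c.familial_mutation_status not in _FAMILIAL:
        _fail(f"unknown familial_mutation_status {c.familial_mutation_status!r}")
    if c.patient_decision not in {"accepts", "declines", "n/a"}:
        _fail(f"unknown patient_decision {c.patient_decision!r}")
    if c.test_performed not in {"full", "predictive", "none"}:
        _fail(f"unknown test_performed {c.test_performed!r}")
    if c.test_result not in {"positive", "negative", "n/a"}:
        _fail(f"unknown test_result {c.test_result!r}")
    if c.relative_pathway not in _RELATIVE:
        _fail(f"unknown relative_pathway {c.relative_pathway!r}")
    if c.family_history_tier not in {"population", "moderate", "higher"}:
        _fail(f"unknown family_history_tier {c.family_history_tier!r}")

    if c.affected != (c.cancer_type != "none"):
        _fail("affected flag must agree with cancer_type")
    if (c.test_result == "n/a") != (c.test_performed == "none"):
        _fail("test_result is n/a exactly when no test was performed")
    if c.patient_decision == "declines" and c.test_performed != "none":
        _fail("a declined test cannot have been performed")
    if c.test_performed != "none" and c.patient_decision != "accepts":
        _fail("a performed test requires patient_decision == accepts")

    if c.affected:
        if c.relative_pathway != "none":
            _fail("relative testing routes apply only to unaffected referrals")
        if c.familial_mutation_status in {"family_tested_negative", "family_untested"}:
            _fail("affected referrals carry familial status none_known or known_in_family")
        if c.familial_mutation_status == "known_in_family":
            if c.test_performed != "predictive":
                _fail("affected with a known familial mutation undergoes a predictive test")
        else:  # none_known
            if c.test_performed == "predictive":
                _fail("a predictive test requires a known familial mutation")
            if not c.eligible_for_test:
                if c.test_performed != "none" or c.patient_decision != "n/a":
                    _fail("ineligible patients are not offered testing")
            else:
                if c.patient_decision == "n/a":
                    _fail("eligible patients record an accept/decline decision")
                if c.patient_decision == "declines" and c.family_history_tier == "population":
                    _fail("declined full testing is managed at moderate/higher tier")
                if c.patient_decision == "accepts" and c.test_performed != "full":
                    _fail("eligible affected patients who accept undergo a full screen")
        return

    # unaffected referrals
    if c.test_performed == "full":
        _fail("unaffected patients receive predictive tests only")
    if c.familial_mutation_status == "known_in_family":
        if c.relative_pathway == "intervening_relative_negative":
            if c.test_performed != "none" or c.patient_decision != "n/a":
                _fail("after a negative intervening relative the patient is not tested")
        elif c.relative_pathway != "none":
            _fail("a known familial mutation admits only the intervening-relative route")
        else:
            if c.patient_decision == "n/a":
                _fail("a known familial mutation requires an accept/decline decision")
            if c.patient_decision == "accepts" and c.test_performed != "predictive":
                _fail("accepting with a known familial mutation means a predictive test")
        return
    if c.familial_mutation_status in {"family_tested_negative", "family_untested"}:
        if c.test_performed != "none" or c.patient_decision != "n/a":
            _fail("no patient test exists without a familial mutation to seek")
        expected = (
            "relative_unavailable"
            if c.familial_mutation_status == "family_untested"
            else "none"
        )
        if c.relative_pathway != expected:
            _fail(f"familial status {c.familial_mutation_status} implies "
                  f"relative_pathway {expected}")
        return
    # none_known
    if c.relative_pathway in {"intervening_relative_negative", "relative_unavailable"}:
        _fail("these relative routes require a different familial status")
    if c.relative_pathway == "none":
        if c.test_performed != "none" or c.patient_decision != "n/a":
            _fail("with no familial mutation and no relative tested, no patient test exists")
    elif c.relative_pathway == "relative_full_test_positive":
        if c.test_performed != "predictive":
            _fail("a positive relative screen leads to a patient predictive test")
    else:  # relative_full_test_negative
        if c.test_performed != "none" or c.patient_decision != "n/a":
            _fail("a negative relative screen ends testing in the family")


def classify(case: CaseRecord) -> int:
    """Map a consistent case record onto exactly one pathway id (total)."""
    _validate_case(case)
    tier = case.family_history_tier
    tier_pick = lambda higher, moderate, population: {  # noqa: E731
        "higher": higher, "moderate": moderate, "population": population
    }[tier]

    if case.affected:
        if case.familial_mutation_status == "known_in_family":
            return 2 if case.test_result == "positive" else 3
        if not case.eligible_for_test:
            return tier_pick(10, 9, 8)
        if case.patient_decision == "declines":
            return tier_pick(4, 5, None)
        return 1 if case.test_result == "positive" else tier_pick(6, 7, None)

    if case.familial_mutation_status == "known_in_family":
        if case.relative_pathway == "intervening_relative_negative":
            return 25
        if case.patient_decision == "declines":
            return 12
        return 11 if case.test_result == "positive" else 13
    if case.familial_mutation_status == "family_tested_negative":
        return tier_pick(27, 26, 28)
    if case.familial_mutation_status == "family_untested":
        return tier_pick(22, 23, 24)
    # none_known
    if case.relative_pathway == "relative_full_test_positive":
        return 17 if case.test_result == "positive" else 18
    if case.relative_pathway == "relative_full_test_negative":
        return tier_pick(19, 20, 21)
    return tier_pick(14, 15, 16)


_CASE_TEMPLATES: dict[int, CaseRecord] = {
    1: CaseRecord(True, "breast", "none_known", True, "accepts", "full", "positive"),
    2: CaseRecord(True, "breast", "known_in_family", True, "accepts", "predictive", "positive"),
    3: CaseRecord(True, "breast", "known_in_family", True, "accepts", "predictive", "negative"),
    4: CaseRecord(True, "breast", "none_known", True, "declines", family_history_tier="higher"),
    5: CaseRecord(True, "breast", "none_known", True, "declines", family_history_tier="moderate"),
    6: CaseRecord(True, "breast", "none_known", True, "accepts", "full", "negative",
                  family_history_tier="higher"),
    7: CaseRecord(True, "breast", "none_known", True, "accepts", "full", "negative",
                  family_history_tier="moderate"),
    8: CaseRecord(True, "breast", "none_known", False, family_history_tier="population"),
    9: CaseRecord(True, "breast", "none_known", False, family_history_tier="moderate"),
    10: CaseRecord(True, "breast", "none_known", False, family_history_tier="higher"),
    11: CaseRecord(False, "none", "known_in_family", True, "accepts", "predictive", "positive"),
    12: CaseRecord(False, "none", "known_in_family", True, "declines"),
    13: CaseRecord(False, "none", "known_in_family", True, "accepts", "predictive", "negative"),
    14: CaseRecord(False, "none", "none_known", family_history_tier="higher"),
    15: CaseRecord(False, "none", "none_known", family_history_tier="moderate"),
    16: CaseRecord(False, "none", "none_known", family_history_tier="population"),
    17: CaseRecord(False, "none", "none_known", True, "accepts", "predictive", "positive",
                   relative_pathway="relative_full_test_positive"),
    18: CaseRecord(False, "none", "none_known", True, "accepts", "predictive", "negative",
                   relative_pathway="relative_full_test_positive"),
    19: CaseRecord(False, "none", "none_known",
                   relative_pathway="relative_full_test_negative", family_history_tier="higher"),
    20: CaseRecord(False, "none", "none_known",
                   relative_pathway="relative_full_test_negative", family_history_tier="moderate"),
    21: CaseRecord(False, "none", "none_known",
                   relative_pathway="relative_full_test_negative",
                   family_history_tier="population"),
    22: CaseRecord(False, "none", "family_untested",
                   relative_pathway="relative_unavailable", family_history_tier="higher"),
    23: CaseRecord(False, "none", "family_untested",
                   relative_pathway="relative_unavailable", family_history_tier="moderate"),
    24: CaseRecord(False, "none", "family_untested",
                   relative_pathway="relative_unavailable", family_history_tier="population"),
    25: CaseRecord(False, "none", "known_in_family",
                   relative_pathway="intervening_relative_negative"),
    26: CaseRecord(False, "none", "family_tested_negative", family_history_tier="moderate"),
    27: CaseRecord(False, "none", "family_tested_negative", family_history_tier="higher"),
    28: CaseRecord(False, "none", "family_tested_negative", family_history_tier="population"),
}


def case_for_pathway(pathway_id: int) -> CaseRecord:
    """A canonical consistent CaseRecord that classifies to ``pathway_id``."""
    try:
        return _CASE_TEMPLATES[pathway_id]
    except KeyError:
        raise KeyError(f"pathway id must be 1-28, got {pathway_id}") from None
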
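"""Recovery of unprinted component costs from published pathway totals.

The pathway totals are linear in their component unit costs, so components
that never received a printed price (GP referral, predictive test price,
per-tier surveillance aggregates, carrier-management bundles, relative
coordination remainders) can be estimated by least squares against the 28
reference totals.  Penny rounding of the published figures makes the system
slightly inconsistent; residuals are reported per pathway rather than hidden,
and rank deficiency (structurally unidentifiable components) is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .audit_weighting import AuditCounts, weighted_mean
from .cost_engine import CostTable, UnitCost
from .money import Money, gbp
from .pathway_catalog import Catalog

__all__ = [
    "CalibrationError",
    "Constraint",
    "CalibrationProblem",
    "CalibrationResult",
    "build_problem",
    "solve_components",
    "calibrated_cost_table",
    "infer_affected_split",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class Constraint:
    """One linear equation: pathway total = sum of component costs."""

    pathway_id: int
    labels: tuple[str, ...]
    total: Money

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", gbp(self.total))
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class CalibrationProblem:
    knowns: Mapping[str, Money]
    unknowns: tuple[str, ...]
    constraints: tuple[Constraint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "knowns", {k: gbp(v) for k, v in self.knowns.items()})
        object.__setattr__(self, "unknowns", tuple(self.unknowns))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        declared = set(self.knowns) | set(self.unknowns)
        for con in self.constraints:
            stray = set(con.labels) - declared
            if stray:
                raise CalibrationError(
                    f"pathway {con.pathway_id} references undeclared labels {sorted(stray)}"
                )


@dataclass(frozen=True)
class CalibrationResult:
    estimates: Mapping[str, Money]
    residuals: Mapping[int, Money]
    rank: int
    rank_deficient: bool
    unidentifiable: tuple[str, ...] = ()

    @property
    def max_abs_residual(self) -> Money:
        if not self.residuals:
            return Decimal(0)
        return max(abs(r) for r in self.residuals.values())


def build_problem(
    catalog: Catalog,
    costs: CostTable,
    totals: Optional[Mapping[int, Money]] = None,
    unknowns: Optional[Sequence[str]] = None,
) -> CalibrationProblem:
    """Assemble the linear system from a catalogue and a partial cost table.

    Unknowns default to every activity label that has no entry in ``costs``;
    totals default to the catalogue's reference totals.  Pathways without a
    total are skipped.
    """
    if totals is None:
        totals = catalog.reference_totals()
    labels_in_use: set[str] = set()
    for p in catalog:
        labels_in_use.update(a.label for a in p.activities)
    if unknowns is None:
        unknowns = sorted(labels_in_use - set(costs))
    knowns = {label: costs[label].amount for label in sorted(labels_in_use & set(costs))}
    constraints = [
        Constraint(p.id, tuple(a.label for a in p.activities), totals[p.id])
        for p in catalog
        if p.id in totals
    ]
    return CalibrationProblem(knowns, tuple(unknowns), tuple(constraints))


def solve_components(problem: CalibrationProblem) -> CalibrationResult:
    """Least-squares estimates of the unknown components, with residuals.

    Rank deficiency is detected from the design matrix; components with
    support in its null space are reported as unidentifiable (their returned
    values are one valid solution among many, not estimates).
    """
    if not problem.constraints:
        raise CalibrationError("no constraints to solve against")
    if not problem.unknowns:
        raise CalibrationError("no unknown components declared")
    m, n = len(problem.constraints), len(problem.unknowns)
    col = {label: j for j, label in enumerate(problem.unknowns)}
    A = np.zeros((m, n))
    b = np.zeros(m)
    for i, con in enumerate(problem.constraints):
        known_part = Decimal(0)
        for label in con.labels:
            if label in col:
                A[i, col[label]] += 1.0
            else:
                known_part += problem.knowns[label]
        b[i] = float(con.total - known_part)

    solution, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    rank = int(rank)
    rank_deficient = rank < n
    unidentifiable: tuple[str, ...] = ()
    if rank_deficient:
        _, s, vh = np.linalg.svd(A)
        tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
        null_mask = np.zeros(n, dtype=bool)
        for k in range(rank, n):
            null_mask |= np.abs(vh[k]) > 1e-8
        unidentifiable = tuple(label for label, j in col.items() if null_mask[j])

    estimates = {
        label: Decimal(str(round(float(solution[col[label]]), 6))) for label in problem.unknowns
    }
    negative = [label for label, v in estimates.items() if v < Decimal("-0.005")]
    if negative:
        warnings.warn(
            f"negative calibrated component(s) {negative}: likely model-structure problem",
            stacklevel=2,
        )

    residuals: dict[int, Money] = {}
    for con in problem.constraints:
        fitted = Decimal(0)
        for label in con.labels:
            fitted += estimates[label] if label in col else problem.knowns[label]
        residuals[con.pathway_id] = fitted - con.total
    return CalibrationResult(estimates, residuals, int(rank), rank_deficient, unidentifiable)


def calibrated_cost_table(
    costs: CostTable,
    result: CalibrationResult,
    component_meta: Optional[Mapping[str, Mapping[str, object]]] = None,
) -> CostTable:
    """Merge calibrated estimates into the unit-cost table.

    ``component_meta`` supplies category/staff metadata for calibrated labels
    (see ``calibrated_components`` in the model configuration).
    """
    meta = component_meta or {}
    table = costs
    for label, amount in result.estimates.items():
        info = meta.get(label, {})
        table = table.with_entry(
            UnitCost(
                label,
                max(amount, Decimal(0)),
                category=str(info.get("category", "management")),
                staff_time=float(info.get("staff_fraction", 0.0)) > 0,
                source="calibrated against reference pathway totals",
                calibrated=True,
            )
        )
    return table


def infer_affected_split(
    costs: Mapping[int, Money],
    base_counts: AuditCounts,
    target_weighted_mean: Money,
    n_to_split: int = 10,
    positive_id: int = 2,
    negative_id: int = 3,
    tolerance: Money = Decimal("0.005"),
) -> tuple[int, int]:
    """Brute-force the unrecorded split of patients between two pathways.

    Enumerates every integer split of ``n_to_split`` patients between
    ``positive_id`` and ``negative_id``, computes the resulting weighted mean
    over the affected group, and returns the unique split minimising the
    distance to the recorded target mean.  A tie, or a best distance above
    ``tolerance`` (when given), is an explicit error.
    """
    target = gbp(target_weighted_mean)
    ids = [i for i in range(1, 11)]
    best: list[tuple[Decimal, int]] = []
    for k in range(n_to_split + 1):
        trial = dict(base_counts.counts)
        trial[positive_id] = trial.get(positive_id, Decimal(0)) + k
        trial[negative_id] = trial.get(negative_id, Decimal(0)) + (n_to_split - k)
        mean = weighted_mean(costs, AuditCounts(trial), ids)
        best.append((abs(mean - target), k))
    best.sort()
    (d0, k0), (d1, _) = best[0], best[1]
    if d0 == d1:
        raise CalibrationError(
            f"ambiguous split: distances tie at {d0} for more than one allocation"
        )
    if tolerance is not None and d0 > gbp(tolerance):
        raise CalibrationError(
            f"no split reaches the target mean within {tolerance} (best: {d0} at {k0})"
        )
    return k0, n_to_split - k0
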
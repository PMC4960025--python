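"""Synthetic referral cohorts and perturbed cost tables with known truth.

Cohorts are multinomial draws over the 28 pathways (seeded NumPy PCG64
generator), rendered as consistent :class:`~brcapath.pathway_catalog.CaseRecord`
instances that :func:`~brcapath.pathway_catalog.classify` maps back to their
source pathway.  Perturbed cost tables hide named components and regenerate
pathway totals from the truth, giving calibration problems whose answer is
known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

import numpy as np

from .audit_weighting import AuditCounts
from .calibration import CalibrationProblem, Constraint
from .cost_engine import CostTable, pathway_cost
from .money import Money, gbp
from .pathway_catalog import CaseRecord, Catalog, case_for_pathway

__all__ = ["SyntheticError", "CohortSpec", "SyntheticTruth", "sample_cohort", "perturb_cost_table"]

_PROB_TOL = 1e-12


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    pathway_probabilities: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_probabilities", tuple(self.pathway_probabilities))
        if self.n_patients < 0:
            raise SyntheticError("n_patients must be >= 0")
        p = np.asarray(self.pathway_probabilities, dtype=float)
        if p.size != 28:
            raise SyntheticError(f"need 28 pathway probabilities, got {p.size}")
        if (p < 0).any():
            raise SyntheticError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise SyntheticError(f"probabilities must sum to 1 (got {p.sum()!r})")


@dataclass(frozen=True)
class SyntheticTruth:
    true_counts: Optional[AuditCounts] = None
    true_unit_costs: Optional[CostTable] = None
    hidden_labels: tuple[str, ...] = ()
    seed: Optional[int] = None
    generator: str = "numpy.random.default_rng (PCG64)"


def sample_cohort(spec: CohortSpec) -> tuple[list[CaseRecord], SyntheticTruth]:
    """Draw a referral cohort; returns the records and the generating truth.

    Patient order is a seeded shuffle of the pathway assignments; the
    record for each patient is the canonical consistent case for its
    pathway, so classification recovers the true counts exactly.
    """
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_patients, spec.pathway_probabilities)
    assignments = np.repeat(np.arange(1, 29), counts)
    rng.shuffle(assignments)
    records = [case_for_pathway(int(pid)) for pid in assignments]
    truth = SyntheticTruth(
        true_counts=AuditCounts(
            {pid: Decimal(int(c)) for pid, c in zip(range(1, 29), counts)},
            window_label=f"synthetic cohort (seed={spec.seed})",
        ),
        seed=spec.seed,
    )
    return records, truth


def perturb_cost_table(
    table: CostTable,
    catalog: Catalog,
    hidden_labels: Sequence[str],
    noise_scale: Money = Decimal(0),
    seed: int = 0,
) -> tuple[CalibrationProblem, SyntheticTruth]:
    """Build a calibration test instance with known component truth.

    Pathway totals are computed from the full ``table`` (which must price
    every activity), the ``hidden_labels`` are withheld from the knowns, and
    optional bounded noise (uniform on ``[-noise_scale, +noise_scale]``,
    emulating per-item rounding) is added to each total.
    """
    labels_in_use: set[str] = set()
    for p in catalog:
        labels_in_use.update(a.label for a in p.activities)
    missing = [label for label in hidden_labels if label not in labels_in_use]
    if missing:
        raise SyntheticError(f"hidden labels not used by any pathway: {missing}")

    rng = np.random.default_rng(seed)
    noise = gbp(noise_scale)
    constraints = []
    for p in catalog:
        total = pathway_cost(p, table).total
        if noise > 0:
            total += noise * gbp(float(rng.uniform(-1.0, 1.0)))
        constraints.append(Constraint(p.id, tuple(a.label for a in p.activities), total))

    hidden = set(hidden_labels)
    knowns = {
        label: table[label].amount for label in sorted(labels_in_use - hidden)
    }
    problem = CalibrationProblem(knowns, tuple(sorted(hidden)), tuple(constraints))
    truth = SyntheticTruth(
        true_unit_costs=table, hidden_labels=tuple(sorted(hidden)), seed=seed
    )
    return problem, truth
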
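"""Audit counts, pending-test allocation, and weighted cost summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Optional

from .money import Money, ZERO, gbp

__all__ = [
    "AuditError",
    "AuditCounts",
    "PendingAllocation",
    "allocate_pending",
    "subgroup_mean",
    "weighted_mean",
    "service_total",
]


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class AuditCounts:
    """Per-pathway patient counts for an audit window.

    Counts are exact decimals: the 50% pending-test allocation introduces
    fractional counts which are carried unrounded.
    """

    counts: Mapping[int, Decimal]
    window_label: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, Decimal] = {}
        for pid, n in self.counts.items():
            value = gbp(n)
            if value < 0:
                raise AuditError(f"negative count for pathway {pid}: {value}")
            clean[int(pid)] = value
        object.__setattr__(self, "counts", clean)

    def get(self, pathway_id: int) -> Decimal:
        return self.counts.get(pathway_id, Decimal(0))

    def total(self, ids: Optional[Iterable[int]] = None) -> Decimal:
        if ids is None:
            ids = self.counts
        return sum((self.get(i) for i in ids), Decimal(0))

    def scaled(self, factor: Decimal) -> "AuditCounts":
        factor = gbp(factor)
        if factor <= 0:
            raise AuditError("scale factor must be positive")
        return AuditCounts({i: n * factor for i, n in self.counts.items()}, self.window_label)


@dataclass(frozen=True)
class PendingAllocation:
    n_pending: Decimal
    p_positive: Decimal = Decimal("0.5")

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_pending", gbp(self.n_pending))
        object.__setattr__(self, "p_positive", gbp(self.p_positive))
        if self.n_pending < 0:
            raise AuditError("n_pending must be >= 0")
        if not (0 <= self.p_positive <= 1):
            raise AuditError(f"p_positive must be in [0, 1]: {self.p_positive}")


def allocate_pending(
    counts: AuditCounts,
    pending: PendingAllocation,
    positive_id: int,
    negative_id: int,
) -> AuditCounts:
    """Split pending test results between two pathways at ``p_positive``."""
    for pid in (positive_id, negative_id):
        if not 1 <= pid <= 28:
            raise AuditError(f"invalid pathway id {pid}")
    new = dict(counts.counts)
    new[positive_id] = counts.get(positive_id) + pending.n_pending * pending.p_positive
    new[negative_id] = counts.get(negative_id) + pending.n_pending * (1 - pending.p_positive)
    return AuditCounts(new, counts.window_label)


def subgroup_mean(costs: Mapping[int, Money], ids: Iterable[int]) -> Money:
    """Unweighted arithmetic mean of pathway totals over a subset."""
    ids = list(ids)
    if not ids:
        raise AuditError("cannot average an empty subset")
    missing = [i for i in ids if i not in costs]
    if missing:
        raise AuditError(f"no cost for pathway ids {missing}")
    return sum((gbp(costs[i]) for i in ids), ZERO) / Decimal(len(ids))


def weighted_mean(
    costs: Mapping[int, Money],
    counts: AuditCounts,
    ids: Optional[Iterable[int]] = None,
) -> Money:
    """Count-weighted mean of pathway totals over a subset."""
    ids = list(ids) if ids is not None else sorted(costs)
    denom = counts.total(ids)
    if denom <= 0:
        raise AuditError("zero total count over the requested subset")
    missing = [i for i in ids if i not in costs and counts.get(i) > 0]
    if missing:
        raise AuditError(f"no cost for pathway ids {missing}")
    num = sum((counts.get(i) * gbp(costs[i]) for i in ids if counts.get(i) > 0), ZERO)
    return num / denom


def service_total(costs: Mapping[int, Money], counts: AuditCounts) -> Money:
    """Total service cost: sum over pathways of count x pathway cost."""
    total = ZERO
    for pid, n in counts.counts.items():
        if n == 0:
            continue
        if pid not in costs:
            raise AuditError(f"no cost for pathway id {pid}")
        total += n * gbp(costs[pid])
    return total
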
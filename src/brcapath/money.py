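"""Exact decimal pounds sterling.

All monetary amounts are :class:`decimal.Decimal` held at full precision;
rounding to pennies happens only at presentation.  Floats are accepted at
the boundary but converted through ``str`` so the usual binary artefacts
(``0.1 + 0.2``) never enter the arithmetic.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

Money = Decimal

PENNY = Decimal("0.01")
ZERO = Decimal("0")


def gbp(value: object) -> Money:
    """Coerce a value to an exact :class:`~decimal.Decimal` amount."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, bool):
        raise TypeError("booleans are not monetary amounts")
    if isinstance(value, (int, str)):
        return Decimal(value)
    if isinstance(value, float):
        return Decimal(str(value))
    raise TypeError(f"cannot interpret {value!r} as GBP")


def to_pennies(amount: Money) -> Money:
    """Round half-up to two decimal places (display convention)."""
    return gbp(amount).quantize(PENNY, rounding=ROUND_HALF_UP)


def fmt_gbp(amount: Money) -> str:
    return f"£{to_pennies(amount):,}"
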
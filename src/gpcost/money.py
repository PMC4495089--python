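"""Exact money arithmetic in integer euro-cents.

All cost attribution is pure arithmetic on 2008 statutory tariffs, so the
engine works in integer cents end to end; euros appear only at the I/O
boundary.  The single place a fraction of a cent can arise is the statutory
drug reimbursement (tier x line total, e.g. 35 % of 3.33 EUR): it is rounded
half-up to the cent, once per line.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP, InvalidOperation

CENT = Decimal("0.01")


def to_cents(amount) -> int:
    """Convert a euro amount (Decimal, str, int, float) to integer cents.

    Floats are passed through ``str`` first so that 0.07 means 7 cents,
    not 7.000000000000001.
    """
    if isinstance(amount, int):
        return amount * 100
    if isinstance(amount, float):
        amount = str(amount)
    try:
        d = Decimal(amount)
    except InvalidOperation as exc:
        raise ValueError(f"not a money amount: {amount!r}") from exc
    cents = d.quantize(CENT, rounding=ROUND_HALF_UP) * 100
    return int(cents)


def to_euros(cents: int) -> Decimal:
    """Integer cents -> exact Decimal euros (2 decimal places)."""
    return (Decimal(cents) / 100).quantize(CENT)


def fmt_euros(cents: int) -> str:
    """Format integer cents as a 2-decimal euro string, e.g. ``'22.00'``."""
    return f"{to_euros(cents):.2f}"


def round_half_up_cents(value: Decimal) -> int:
    """Round an exact Decimal cent amount to the nearest integer cent, half up."""
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def share_cents(total_cents: int, fraction: float) -> int:
    """fraction x total, in cents, rounded half-up.

    ``fraction`` is a statutory rate such as 0.35, 0.65, 0.70 or 1.0; it is
    converted through ``str`` so the basis-point arithmetic is exact.
    """
    bp = int(Decimal(str(fraction)) * 10000)
    return (total_cents * bp + 5000) // 10000
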
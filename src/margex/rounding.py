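"""Half-up decimal rounding helpers for printed-precision comparisons."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (not banker's)."""
    d = x if isinstance(x, Decimal) else Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def round_ratio(numerator: int, denominator: int, ndigits: int = 2, scale: int = 1) -> float:
    """Exact half-up rounding of ``scale * numerator / denominator``.

    The quotient is formed in decimal arithmetic so boundary cases round on
    the true rational value, not on a binary-float approximation.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    d = Decimal(numerator) * Decimal(scale) / Decimal(denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
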
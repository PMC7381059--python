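"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percentage"]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (half-up), as in reported tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """numerator/denominator as a percentage, half-up rounded.

    Returns ``None`` for an empty denominator (not estimable).
    """
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, decimals)
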
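"""Decimal rounding helpers.

Published Delphi/AHP tables round displayed values with banker's rounding
(half-to-even), while integer risk scores round half-up on the magnitude.
Going through :class:`decimal.Decimal` on the shortest string representation
avoids binary-float artifacts at exact ties (e.g. 0.24525 -> 0.2452).
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_even", "round_half_up"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_even(x: float, ndigits: int = 4) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going to the even digit."""
    return float(Decimal(str(x)).quantize(_quantum(ndigits), rounding=ROUND_HALF_EVEN))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    return float(Decimal(str(x)).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP))
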
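"""Decimal-faithful reporting rounding.

All statistics are kept at full float precision internally; only *reported*
values are rounded, with round-half-to-even applied to the shortest decimal
representation of the float.  Builtin ``round`` operates on the binary value
(``round(0.505, 2) == 0.51`` because the float is slightly above 0.505),
which disagrees with how half-even rounding of the printed decimal behaves;
clinical tables are decimal artifacts, so we round the decimal literal.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

__all__ = ["round_half_even"]


def round_half_even(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties to even, on the decimal literal."""
    if x != x:  # NaN passes through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))
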
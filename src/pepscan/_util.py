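"""Shared helpers: half-up rounding and the package logger."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

logger = logging.getLogger("pepscan")

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def round_half_up(value: float | Fraction, ndigits: int) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's built-in ``round`` is banker's rounding; published composition
    and density tables round 0.5 up, so exact decimal arithmetic is used.
    Pass a :class:`~fractions.Fraction` to avoid float representation error.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int) -> float:
    """Exact ``100 * numerator / denominator`` rounded half-up."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)
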
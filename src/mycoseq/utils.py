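"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; summary tables in
    this package print integers rounded the conventional way.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """100 * part / whole, rounded half-away-from-zero to `ndigits`.

    Returns 0.0 when `whole` is zero (an empty library has no meaningful
    retention percentage, so zero is reported).
    """
    if whole == 0:
        return 0.0
    scale = 10.0**ndigits
    return math.floor(100.0 * part / whole * scale + 0.5) / scale
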
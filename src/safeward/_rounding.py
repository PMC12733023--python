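"""Rounding helpers.

Printed percentages in occupational-safety reports conventionally use
round-half-away-from-zero, which differs from Python's banker's rounding
(``round(0.5) == 0``). All user-facing percentages in this package go
through :func:`round_half_away`.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, ties going away from zero."""
    x = float(x)  # accept numpy scalars
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
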
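"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["round_half_up", "round_report"]

# guard against float representation error just below a .5 boundary
_EPS = 1e-9


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(np.floor(x + 0.5 + _EPS))


def round_report(x: float, decimals: int = 3) -> float:
    """Half-up decimal rounding used for all reported fractions."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
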
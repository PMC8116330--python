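"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Reported percentages use this convention; raw metrics are kept
    unrounded and only rounded at the reporting boundary.
    """
    if x is None:
        raise ValueError("cannot round None")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed (or an existing Generator) to a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
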
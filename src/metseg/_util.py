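"""Small shared helpers."""
from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for reported
    percentages), avoiding banker's rounding surprises at .5 boundaries."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent(x: float, decimals: int = 1) -> float:
    """Express a fraction as a percentage at the given display precision."""
    return round_half_up(100.0 * x, decimals)
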
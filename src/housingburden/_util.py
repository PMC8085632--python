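"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at positive ``x`` (display convention).

    Python's built-in ``round`` uses banker's rounding; printed tables here
    follow the conventional half-up rule (0.55 -> 0.6 at 1 decimal).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    r = math.floor(x * factor + 0.5) / factor
    return r if ndigits > 0 else float(r)


def int_half_up(x: float) -> int:
    """Round to the nearest integer, ties up."""
    return int(math.floor(x + 0.5))
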
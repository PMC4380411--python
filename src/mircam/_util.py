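"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's builtin round() is banker's rounding; published read-count
    tables use conventional half-up rounding, so every reported percentage
    and fold change goes through this helper.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
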
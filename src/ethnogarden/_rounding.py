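"""Half-up decimal rounding used at the reporting layer.

Python's built-in ``round`` is banker's rounding; survey tables in this field
are conventionally printed with ties rounded away from zero, so all reported
values go through :func:`round_half_up`.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties going up (0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
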
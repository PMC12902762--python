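"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention used in the reports).

    ``round_half_up(82.145, 1) == 82.1`` only when the stored decimal digit
    truly is below 5; ties like 78.55 go up to 78.6, unlike banker's
    rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
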
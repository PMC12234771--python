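"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching hand-tabulated percentages.

    Python's builtin round() is banker's rounding; printed shares in the
    reports are conventional half-up values, so all user-facing rounding
    goes through here.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
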
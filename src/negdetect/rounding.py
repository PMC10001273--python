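"""Display rounding helpers.

Report tables round metrics to 3 decimals and percentages to 2, using
half-away-from-zero — the convention every printed cell in the reference
tables follows. Rounding is done on the shortest decimal representation of
the float, so values such as 0.6945 round up deterministically instead of
depending on their binary expansion.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def display_round(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    The value is first snapped to 12 decimals so accumulated binary noise
    (e.g. a mean of 0.7215 stored as 0.72149999...97) does not flip the
    half-way digit.
    """
    q = Decimal(1).scaleb(-ndigits)
    snapped = round(float(x), 12)
    return float(Decimal(repr(snapped)).quantize(q, rounding=ROUND_HALF_UP))


def metric_round(x: float) -> float:
    """Metrics (recall/precision/F1/AP) display at 3 decimals."""
    return display_round(x, 3)


def percent_round(x: float) -> float:
    """Percentages display at 2 decimals."""
    return display_round(x, 2)
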
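"""Display rounding used by published prognostic tables.

Coefficients are printed to one decimal and informativeness to two, with
ties rounded away from zero ("half-up" in the bookkeeping sense), which is
the convention of the spreadsheet software the tables were produced with.
Python's built-in round() is banker's rounding and would disagree on
exact-half values, so all display rounding goes through here.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round to *ndigits* decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
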
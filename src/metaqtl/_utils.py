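"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how the reported tables round.

    Python's builtin ``round`` is banker's rounding; published cM/Mb tables
    round half up, so 26.265 -> 26.27 rather than 26.26.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
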
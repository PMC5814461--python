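"""Small shared helpers."""
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero (report convention), e.g. 2.5 -> 3 at 0 dp."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
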
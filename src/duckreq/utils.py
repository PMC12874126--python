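"""Small shared helpers."""

from __future__ import annotations

import decimal

#: kcal -> kJ (thermochemical calorie, the convention of feed tables)
KJ_PER_KCAL = 4.184


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, the convention of printed feed
    tables (Python's built-in ``round`` is banker's rounding).

    >>> round_half_up(0.125, 2)
    0.13
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def kcal_to_kj(kcal: float) -> float:
    """Convert an energy in kcal (or a density in kcal/kg) to kJ (kJ/kg)."""
    return kcal * KJ_PER_KCAL


def kj_to_kcal(kj: float) -> float:
    """Convert an energy in kJ (or a density in kJ/kg) to kcal (kcal/kg)."""
    return kj / KJ_PER_KCAL
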
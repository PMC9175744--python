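"""Potency unit arithmetic: pIC50 <-> IC50.

pIC50 is defined on the molar scale, pIC50 = -log10(IC50 [M]); an IC50 of
1 uM is pIC50 6.  Conversions are exact internally; a half-up rounding to
3 decimals is provided for reproducing printed potency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP


def _round_half_up(value: float, decimals: int = 3) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ic50_um_from_pic50(pic50: float, rounded: bool = False) -> float:
    """IC50 in micromolar from pIC50: 10^(-pIC50) * 1e6.

    ``rounded=True`` applies half-up rounding to 3 decimals (printed-table
    precision); the default returns the unrounded value.
    """
    if not math.isfinite(pic50):
        raise ValueError(f"pic50 must be finite, got {pic50!r}")
    ic50 = 10.0 ** (-pic50) * 1e6
    return _round_half_up(ic50, 3) if rounded else ic50


def pic50_from_ic50_m(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 [M]); inverse of :func:`ic50_um_from_pic50`."""
    if not (math.isfinite(ic50_molar) and ic50_molar > 0):
        raise ValueError(f"ic50 must be a positive finite molar value, got {ic50_molar!r}")
    return -math.log10(ic50_molar)


def pic50_from_ic50_um(ic50_um: float) -> float:
    """Convenience: pIC50 from an IC50 given in micromolar."""
    return pic50_from_ic50_m(ic50_um * 1e-6)


@dataclass(frozen=True)
class PotencyValue:
    """A potency stated both ways; constructed from either scale."""

    pic50: float
    ic50_micromolar: float

    @classmethod
    def from_pic50(cls, pic50: float) -> "PotencyValue":
        return cls(pic50=pic50, ic50_micromolar=ic50_um_from_pic50(pic50))

    @classmethod
    def from_ic50_um(cls, ic50_um: float) -> "PotencyValue":
        return cls(pic50=pic50_from_ic50_um(ic50_um), ic50_micromolar=ic50_um)

    def __post_init__(self) -> None:
        if self.ic50_micromolar <= 0:
            raise ValueError("ic50 must be positive")
        expected = ic50_um_from_pic50(self.pic50)
        if not math.isclose(expected, self.ic50_micromolar, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent pair: pIC50 {self.pic50} implies "
                f"{expected} uM, got {self.ic50_micromolar}"
            )
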
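"""Redox and protonation speciation: Nernst and Henderson–Hasselbalch forms.

The oxidized/reduced ratio of a thiol couple responds to the ambient redox
potential E' the way a titratable group's deprotonated fraction responds to
pH: the standard reduction potential E0 plays the role of the pKa,

    [ox]/[red] = exp( n F (E' - E0) / (R T) )          (Nernst)
    f_deprot   = 1 / (1 + 10^(pKa - pH))               (Henderson–Hasselbalch)

with n the number of electrons transferred, F the Faraday constant and R the
gas constant. Potentials are in millivolts throughout, the field's
convention. At 298.15 K a one-electron couple shifts one decade in ratio per
(RT ln 10)/F ≈ 59.16 mV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)
STANDARD_TEMPERATURE = 298.15  # K

#: literature standard potentials (mV), quoted values rather than validated
#: measurements: the glutathione GSSG/GSH buffer at pH 7, the ERp57
#: Cys57–Cys60 disulfide, and the thioredoxin Cys32–Cys35 disulfide
E0_GLUTATHIONE = -240.0
E0_ERP57 = -167.0
E0_THIOREDOXIN = -270.0

#: literature pKa values: cysteine thiol ~8.5; sulfenic acid estimated 6-7
#: (sulfinic and sulfonic are <2, outside the physiological range)
PKA_CYSTEINE = 8.5
PKA_SULFENIC_RANGE = (6.0, 7.0)

_MAX_EXPONENT = 700.0  # exp() overflow guard


@dataclass
class RedoxCouple:
    """A two-state redox couple with standard potential E0 (mV)."""

    standard_potential_mv: float
    n_electrons: int = 2
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be a positive integer")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass
class Titratable:
    """A titratable group with a single pKa."""

    pka: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka):
            raise ValueError("pKa must be finite")


def nernst_ratio(couple: RedoxCouple, potential_mv: float) -> float:
    """Oxidized/reduced concentration ratio at ambient potential E' (mV).

    Strictly increasing in E'; equals 1 at E' = E0. The exponent is capped
    (with a warning) so extreme potentials saturate instead of overflowing.
    """
    delta_v = (potential_mv - couple.standard_potential_mv) / 1000.0
    exponent = couple.n_electrons * FARADAY * delta_v / (GAS_CONSTANT * couple.temperature)
    if abs(exponent) > _MAX_EXPONENT:
        warnings.warn(
            f"potential difference {potential_mv - couple.standard_potential_mv:.0f} mV "
            "saturates the Nernst ratio; result capped",
            RuntimeWarning,
            stacklevel=2,
        )
        exponent = math.copysign(_MAX_EXPONENT, exponent)
    return math.exp(exponent)


def potential_from_ratio(couple: RedoxCouple, ratio: float) -> float:
    """Ambient potential E' (mV) at a given oxidized/reduced ratio.

    Exact inverse of :func:`nernst_ratio` (within floating-point error).
    """
    if not ratio > 0:
        raise ValueError("ratio must be positive")
    rt_nf = GAS_CONSTANT * couple.temperature / (couple.n_electrons * FARADAY)
    return couple.standard_potential_mv + 1000.0 * rt_nf * math.log(ratio)


def decade_millivolts(n_electrons: int = 1,
                      temperature: float = STANDARD_TEMPERATURE) -> float:
    """Potential shift (mV) producing a tenfold ratio change: (RT ln10)/(nF)."""
    return 1000.0 * GAS_CONSTANT * temperature * math.log(10.0) / (n_electrons * FARADAY)


def deprotonated_fraction(t: Titratable, ph: float) -> float:
    """Fraction of the group in the deprotonated form at a given pH.

    1/(1 + 10^(pKa - pH)): strictly increasing in pH, 0.5 at pH = pKa, with
    limits 0 and 1 at extreme pH.
    """
    exponent = t.pka - ph
    if exponent > 308:  # 10**309 overflows a double
        return 0.0
    return 1.0 / (1.0 + 10.0 ** exponent)


def speciation_table(couple: RedoxCouple, potentials_mv: list[float]) -> list[dict]:
    """Oxidized fraction across a range of ambient potentials (convenience)."""
    rows = []
    for e in potentials_mv:
        r = nernst_ratio(couple, e)
        rows.append({
            "potential_mv": e,
            "ratio_ox_red": r,
            "fraction_oxidized": r / (1.0 + r),
        })
    return rows
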
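"""Hydrogen sulfide speciation in seawater.

Microsensors respond to the H2S gas species only, while the quantity of
biogeochemical interest is total dissolved sulfide (H2S + HS- + S2-,
written S2- throughout this package).  At seawater pH the second
dissociation is negligible (pK2 >> 9), so the conversion reduces to the
first dissociation equilibrium:

    alpha = [H2S] / ([H2S] + [HS-]) = 1 / (1 + 10**(pH - pK1(T, S)))

The default pK1 is the Millero (1988) seawater formulation with explicit
temperature and salinity dependence,

    ln K1 = 225.838 - 13275.3/T - 34.6435 ln T + 0.3449 sqrt(S) - 0.0274 S

with T in kelvin and S in practical salinity units.  The coefficients are
held in :class:`SpeciationConstants` so an alternative published
formulation can be swapped in through configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciationConstants",
    "MILLERO_1988",
    "pk1",
    "h2s_fraction",
    "total_sulfide",
    "h2s_from_total",
]


@dataclass(frozen=True)
class SpeciationConstants:
    """Coefficients of a seawater H2S first-dissociation-constant formula.

    ``ln K1 = a0 + a1/T + a2*ln(T) + b0*sqrt(S) + b1*S`` with T in kelvin.

    Attributes
    ----------
    a0, a1, a2 : float
        Temperature-dependence coefficients.
    b0, b1 : float
        Salinity-dependence coefficients.
    temp_range_C, salinity_range : tuple of float
        Validity range; inputs outside it trigger a warning, not an error.
    source : str
        Bibliographic label of the formulation.
    """

    a0: float
    a1: float
    a2: float
    b0: float
    b1: float
    temp_range_C: tuple[float, float] = (0.0, 35.0)
    salinity_range: tuple[float, float] = (0.0, 40.0)
    source: str = "unspecified"

    def ln_k1(self, temp_C: float, salinity: float) -> float:
        t_k = temp_C + 273.15
        return (
            self.a0
            + self.a1 / t_k
            + self.a2 * math.log(t_k)
            + self.b0 * math.sqrt(salinity)
            + self.b1 * salinity
        )


#: Millero (1988) H2S first dissociation constant in seawater.
MILLERO_1988 = SpeciationConstants(
    a0=225.838,
    a1=-13275.3,
    a2=-34.6435,
    b0=0.3449,
    b1=-0.0274,
    temp_range_C=(0.0, 35.0),
    salinity_range=(0.0, 40.0),
    source="Millero (1988), seawater H2S first dissociation",
)


def _check_env(temp_C: float, salinity: float, constants: SpeciationConstants) -> None:
    if not (np.isfinite(temp_C) and np.isfinite(salinity)):
        raise ValueError("temperature and salinity must be finite")
    lo, hi = constants.temp_range_C
    if not lo <= temp_C <= hi:
        warnings.warn(
            f"temperature {temp_C} degC outside validity range {constants.temp_range_C} "
            f"of {constants.source}",
            stacklevel=3,
        )
    lo, hi = constants.salinity_range
    if not lo <= salinity <= hi:
        warnings.warn(
            f"salinity {salinity} outside validity range {constants.salinity_range} "
            f"of {constants.source}",
            stacklevel=3,
        )


def pk1(temp_C: float, salinity: float, constants: SpeciationConstants = MILLERO_1988) -> float:
    """Stoichiometric pK1 of H2S at the given temperature (degC) and salinity."""
    _check_env(temp_C, salinity, constants)
    value = -constants.ln_k1(temp_C, salinity) / math.log(10.0)
    if not 5.0 < value < 9.0:
        raise ValueError(
            f"evaluated pK1={value:.3f} outside the plausible (5, 9) window; "
            "check the constants or the T/S inputs"
        )
    return value


def h2s_fraction(
    pH: float,
    temp_C: float,
    salinity: float,
    constants: SpeciationConstants = MILLERO_1988,
) -> float:
    """Fraction alpha = [H2S]/([H2S]+[HS-]) of total sulfide present as H2S.

    pH must lie in [2, 12]; the second dissociation is neglected.
    """
    if not np.isfinite(pH):
        raise ValueError("pH must be finite")
    if not 2.0 <= pH <= 12.0:
        raise ValueError(f"pH={pH} outside supported range [2, 12]")
    return 1.0 / (1.0 + 10.0 ** (pH - pk1(temp_C, salinity, constants)))


def total_sulfide(h2s, pH, temp_C, salinity, constants: SpeciationConstants = MILLERO_1988):
    """Convert measured H2S (uM, scalar or array) to total dissolved sulfide (uM)."""
    h2s = np.asarray(h2s, dtype=float)
    if np.any(h2s < 0) or not np.all(np.isfinite(h2s)):
        raise ValueError("h2s concentrations must be finite and non-negative")
    alpha = h2s_fraction(pH, temp_C, salinity, constants)
    out = h2s / alpha
    return float(out) if out.ndim == 0 else out


def h2s_from_total(total, pH, temp_C, salinity, constants: SpeciationConstants = MILLERO_1988):
    """Inverse correction: total dissolved sulfide (uM) to as-measured H2S (uM)."""
    total = np.asarray(total, dtype=float)
    if np.any(total < 0) or not np.all(np.isfinite(total)):
        raise ValueError("total sulfide concentrations must be finite and non-negative")
    alpha = h2s_fraction(pH, temp_C, salinity, constants)
    out = total * alpha
    return float(out) if out.ndim == 0 else out
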
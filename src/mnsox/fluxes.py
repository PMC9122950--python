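"""Diffusive flux estimation and electron mass balance.

Fick's first law gives the vertical flux sustained by a concentration
gradient, J = D dC/dz (mmol m^-2 s^-1 for a gradient in mmol m^-3 m^-1 and
a diapycnal diffusivity in m^2 s^-1).  In a steady Mn shuttle the downward
MnO2 particle flux equals the upward dissolved-Mn flux, so the electron
supply from Mn reduction can be balanced against the electron demand of
sulfide oxidation:

    supported = (J_Mn * e_Mn) / (J_S * e_S)

with e_Mn electrons released per Mn(IV)->Mn(II) (default 2) and e_S
electrons per S2- -> SO4^2- (default 8).  Chemolithoautotrophs divert part
of the sulfur electrons to CO2 fixation; from a measured Mn(IV)/Mn(II) to
substrate/product molar ratio r the diverted share is

    f_CO2 = 1 - r * e_Mn / e_substrate,

e.g. r = 3.7 for thiosulfate -> sulfate (8 electrons) gives 7.5%.

All stoichiometric constants live in :class:`StoichiometryParams` so
alternative bookkeeping assumptions remain computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import DepthProfile

__all__ = [
    "StoichiometryParams",
    "fick_flux",
    "gradient_from_profile",
    "per_cell_flux",
    "chemosynthesis_fraction_from_ratio",
    "mn_supported_fraction",
]


@dataclass(frozen=True)
class StoichiometryParams:
    """Electron bookkeeping constants for the Mn-S redox couple.

    Attributes
    ----------
    electrons_per_Mn : float
        Electrons accepted per Mn, MnO2 (Mn IV) -> Mn(II): 2.
    electrons_per_S : float
        Electrons released per total-sulfide unit fully oxidized to
        sulfate: 8.
    electrons_per_substrate_unit : float
        Electrons per unit of the growth-experiment substrate couple
        (thiosulfate -> sulfate: 8).
    mn_to_substrate_ratio : float
        Measured Mn(IV)/Mn(II) to substrate/product molar ratio (3.7 from
        growth experiments with the Mn-reducing sulfur oxidizer).
    chemosynthesis_fraction : float
        Share of sulfur electrons diverted to CO2 fixation, in [0, 1].
    """

    electrons_per_Mn: float = 2.0
    electrons_per_S: float = 8.0
    electrons_per_substrate_unit: float = 8.0
    mn_to_substrate_ratio: float = 3.7
    chemosynthesis_fraction: float = 0.075

    def __post_init__(self) -> None:
        for name in (
            "electrons_per_Mn",
            "electrons_per_S",
            "electrons_per_substrate_unit",
            "mn_to_substrate_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.chemosynthesis_fraction <= 1:
            raise ValueError("chemosynthesis_fraction must lie in [0, 1]")


def fick_flux(gradient: float, diffusivity: float) -> float:
    """Diffusive flux magnitude J = gradient * D (mmol m^-2 s^-1).

    ``gradient`` in mmol m^-3 m^-1, ``diffusivity`` in m^2 s^-1.  The sign
    (direction) is the caller's bookkeeping; the magnitude is returned.
    """
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    return abs(gradient) * diffusivity


def gradient_from_profile(
    profile: DepthProfile,
    field: str = "s2_uM",
    depth_window: tuple[float, float] | None = None,
) -> float:
    """Least-squares concentration gradient (mmol m^-3 m^-1) over a depth window.

    Ordinary least-squares slope of concentration versus depth for the
    samples whose depth lies in ``depth_window`` (inclusive); the whole
    profile when no window is given.  uM is numerically mmol m^-3, so no
    unit conversion applies.
    """
    z = profile.depth
    c = profile.column(field)
    if depth_window is not None:
        lo, hi = depth_window
        mask = (z >= lo) & (z <= hi)
        z, c = z[mask], c[mask]
    if len(z) < 2 or np.ptp(z) == 0:
        raise ValueError("gradient needs at least 2 distinct depths in the window")
    return float(np.polyfit(z, c, 1)[0])


def per_cell_flux(flux: float, density: float) -> float:
    """Flux feeding a single cell: flux / density.

    ``flux`` in mmol m^-2 s^-1 and ``density`` in cells m^-3 give
    mmol cell^-1 m^-2 s^-1 multiplied out as the plain quotient, the
    conventional per-cell supply unit for redoxcline budgets.
    """
    if density <= 0:
        raise ValueError("cell density must be positive")
    return flux / density


def chemosynthesis_fraction_from_ratio(params: StoichiometryParams) -> float:
    """Fraction of sulfur electrons routed to CO2 reduction.

    From the measured Mn-to-substrate molar ratio: the electrons accepted by
    Mn per substrate unit are r * e_Mn; the remainder of the substrate's
    electron yield went to CO2 fixation: 1 - r * e_Mn / e_substrate.
    """
    used_by_mn = params.mn_to_substrate_ratio * params.electrons_per_Mn
    if used_by_mn > params.electrons_per_substrate_unit:
        raise ValueError(
            "ratio * electrons_per_Mn exceeds the substrate electron yield "
            "(would imply a negative chemosynthesis fraction)"
        )
    return 1.0 - used_by_mn / params.electrons_per_substrate_unit


def mn_supported_fraction(
    mn_flux: float,
    s_flux: float,
    params: StoichiometryParams = StoichiometryParams(),
    include_chemosynthesis: bool = False,
) -> float:
    """Share of the sulfide electron flux balanced by the MnO2 electron flux.

    (mn_flux * e_Mn) / (s_flux * e_S); with ``include_chemosynthesis`` the
    sulfur-side electron demand is first reduced by the chemosynthesis
    fraction (those electrons go to CO2, not to Mn).
    """
    if s_flux <= 0:
        raise ValueError("s_flux must be positive")
    if mn_flux <= 0:
        raise ValueError("mn_flux must be positive")
    demand = s_flux * params.electrons_per_S
    if include_chemosynthesis:
        demand *= 1.0 - params.chemosynthesis_fraction
    return (mn_flux * params.electrons_per_Mn) / demand
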
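"""One-dimensional reaction-diffusion model of the sulfide profile.

The vertical transport of total dissolved sulfide across a stratified
redoxcline is modelled as diapycnal diffusion with a first-order sink,

    dC/dt = D_x d2C/dx2 + kappa(x) C,        kappa(x) <= 0,

solved on a uniform depth grid with the explicit (forward-time,
centred-space) finite-difference scheme

    C(x, t+dt) = C(x, t) + dt D_x (C(x+dx) - 2 C(x) + C(x-dx)) / dx^2
                         + dt kappa(x) C(x, t).

The sink coefficient is either biological, kappa = k_cell * CA(x) * F
(cell-specific rate coefficient times Campylobacterota abundance times the
*Sulfurimonas* fraction), or chemical, kappa = k_chem (pseudo-first-order
oxidation by MnO2 at fixed MnO2), or both, and is active only at and above
a configurable depth (the upper boundary of euxinic water): below it the
profile is purely diffusive, which is what gives the observed linear deep
sulfide gradient.  Depth is positive downward; concentrations are in uM
(= mmol m^-3, so fluxes need no unit conversion).

The module-level functions (:func:`step`, :func:`run_to_steady_state`,
:func:`oxidation_horizon`, :func:`interpolate_abundance`) are the low-level
API; :class:`SulfideTransportModel` wraps them in a model object whose
:meth:`~SulfideTransportModel.solve` returns a :class:`TransportResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from .profiles import DepthProfile

__all__ = [
    "AbundanceProfile",
    "ModelConfig",
    "ModelResult",
    "stability_timestep",
    "equal_rate_abundance",
    "sink_coefficient_profile",
    "step",
    "run_to_steady_state",
    "oxidation_horizon",
    "interpolate_abundance",
    "SulfideTransportModel",
    "TransportResults",
]


@dataclass
class AbundanceProfile:
    """Effective sulfide-oxidizer abundance on the model grid.

    ``cells_per_l`` is the Campylobacterota count; ``fraction`` the share of
    it attributable to *Sulfurimonas* (scalar or per depth).  The product is
    what multiplies k_cell in the biological sink.
    """

    depth: np.ndarray  # m
    cells_per_l: np.ndarray
    fraction: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.cells_per_l = np.asarray(self.cells_per_l, dtype=float)
        if len(self.depth) != len(self.cells_per_l):
            raise ValueError("depth and cells_per_l must have equal length")
        if np.any(self.cells_per_l < 0):
            raise ValueError("abundances must be non-negative")
        frac = np.asarray(self.fraction, dtype=float)
        if frac.ndim == 0:
            frac = np.full_like(self.depth, float(frac))
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("fraction must lie in [0, 1]")
        self.fraction = frac

    @property
    def effective(self) -> np.ndarray:
        """cells l^-1 weighted by the Sulfurimonas fraction."""
        return self.cells_per_l * self.fraction


@dataclass
class ModelConfig:
    """Full specification of a reaction-diffusion run.

    Defaults are the standard redoxcline scenario: an 80-120 m domain at
    0.2 m resolution, fixed 0 uM at the top and 10 uM at the bottom, sink
    active at and above 106 m, and the two diapycnal diffusivity scenarios
    1e-6 / 4e-6 m^2 s^-1 selectable through ``diffusivity``.
    """

    depth_top: float = 80.0
    depth_bottom: float = 120.0
    dx: float = 0.2
    diffusivity: float | np.ndarray = 1e-6  # m^2 s^-1, scalar or per-depth
    k_cell: float = -1.05e-13  # l cell^-1 s^-1
    k_chem: float = -9.53e-8  # s^-1
    sink_mode: Literal["biological", "chemical", "both", "none"] = "biological"
    sink_max_depth: float = 106.0
    c_bottom: float = 10.0  # uM, Dirichlet
    c_top: float = 0.0  # uM, Dirichlet
    boundary: Literal["dirichlet", "noflux"] = "dirichlet"
    dt: float | None = None  # s; None -> stability rule
    safety: float = 0.4
    tolerance: float = 1e-9  # uM s^-1, max rate of change at convergence
    max_steps: int = 2_000_000

    def __post_init__(self) -> None:
        if self.depth_top >= self.depth_bottom:
            raise ValueError("depth_top must be shallower than depth_bottom")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.sink_mode not in ("biological", "chemical", "both", "none"):
            raise ValueError(f"unknown sink_mode {self.sink_mode!r}")
        if np.any(np.asarray(self.diffusivity) <= 0):
            raise ValueError("diffusivity must be positive")

    @property
    def grid(self) -> np.ndarray:
        """Depth grid, m, increasing downward, inclusive of both boundaries."""
        n = int(round((self.depth_bottom - self.depth_top) / self.dx))
        return self.depth_top + self.dx * np.arange(n + 1)

    def diffusivity_on_grid(self) -> np.ndarray:
        d = np.asarray(self.diffusivity, dtype=float)
        if d.ndim == 0:
            return np.full(len(self.grid), float(d))
        if len(d) != len(self.grid):
            raise ValueError("per-depth diffusivity must match the grid length")
        return d

    def to_dict(self) -> dict:
        out = asdict(self)
        if isinstance(out["diffusivity"], np.ndarray):
            out["diffusivity"] = out["diffusivity"].tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def equal_rate_abundance(k_cell: float = -1.05e-13, k_chem: float = -9.53e-8) -> float:
    """Cell abundance (cells l^-1) at which the biological sulfide oxidation
    rate equals the chemical one: |k_cell| * CA = |k_chem|."""
    if k_cell == 0:
        raise ValueError("k_cell must be nonzero")
    return abs(k_chem) / abs(k_cell)


def sink_coefficient_profile(
    config: ModelConfig, abundance: AbundanceProfile | None = None
) -> np.ndarray:
    """First-order sink coefficient kappa(z) (s^-1, <= 0) on the model grid.

    Biological: kappa = k_cell * CA(z) * F(z); chemical: kappa = k_chem;
    both: their sum.  Active only at depths <= sink_max_depth.
    """
    grid = config.grid
    kappa = np.zeros_like(grid)
    if config.sink_mode in ("biological", "both"):
        if abundance is None:
            raise ValueError("biological sink requires an abundance profile")
        if len(abundance.depth) != len(grid) or not np.allclose(
            abundance.depth, grid, atol=1e-9
        ):
            raise ValueError(
                "abundance profile must be interpolated onto the model grid "
                "(see interpolate_abundance)"
            )
        kappa = kappa + config.k_cell * abundance.effective
    if config.sink_mode in ("chemical", "both"):
        kappa = kappa + config.k_chem
    kappa = np.where(grid <= config.sink_max_depth, kappa, 0.0)
    if np.any(kappa > 0):
        raise ValueError("sink coefficients must be <= 0 (consumption)")
    return kappa


def stability_timestep(
    config: ModelConfig, abundance: AbundanceProfile | None = None
) -> float:
    """Largest stable explicit time step, s: safety * min(dx^2/(2 max D), 1/max|kappa|)."""
    d_max = float(np.max(config.diffusivity_on_grid()))
    dt = config.dx**2 / (2.0 * d_max)
    kappa = sink_coefficient_profile(config, abundance)
    k_max = float(np.max(np.abs(kappa)))
    if k_max > 0:
        dt = min(dt, 1.0 / k_max)
    return config.safety * dt


def _resolve_dt(config: ModelConfig, abundance: AbundanceProfile | None) -> float:
    dt_stable = stability_timestep(config, abundance)
    if config.dt is None:
        return dt_stable
    if config.dt > dt_stable / config.safety:
        raise ValueError(
            f"dt={config.dt} s violates the stability condition "
            f"(limit {dt_stable / config.safety:.3g} s)"
        )
    return config.dt


def step(
    state: np.ndarray,
    config: ModelConfig,
    abundance: AbundanceProfile | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Advance the concentration field by one explicit time step.

    Interior cells receive the centred diffusion stencil plus the local sink
    term; with Dirichlet boundaries the end cells are held fixed, with
    no-flux boundaries they use a mirrored ghost cell (mass-conserving).
    """
    c = np.asarray(state, dtype=float)
    if len(c) != len(config.grid):
        raise ValueError("state length must match the model grid")
    if dt is None:
        dt = _resolve_dt(config, abundance)
    d = config.diffusivity_on_grid()
    kappa = sink_coefficient_profile(config, abundance)
    lam = dt * d / config.dx**2

    out = c.copy()
    out[1:-1] = (
        c[1:-1]
        + lam[1:-1] * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        + dt * kappa[1:-1] * c[1:-1]
    )
    if config.boundary == "dirichlet":
        out[0] = config.c_top
        out[-1] = config.c_bottom
    else:  # noflux: mirrored ghost cells
        out[0] = c[0] + lam[0] * (c[1] - c[0]) + dt * kappa[0] * c[0]
        out[-1] = c[-1] + lam[-1] * (c[-2] - c[-1]) + dt * kappa[-1] * c[-1]
    return out


@dataclass
class ModelResult:
    """Steady-state output of a reaction-diffusion run."""

    depth: np.ndarray  # m
    concentration: np.ndarray  # uM
    oxidation_rate: np.ndarray  # uM s^-1, magnitude of the local sink
    iterations: int
    converged: bool
    dt_used: float
    config: ModelConfig
    linearity_r2: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_m": self.depth,
                "s2_uM": self.concentration,
                "oxidation_rate_uM_per_s": self.oxidation_rate,
            }
        )


def _linearity_below_sink(depth, conc, sink_max_depth) -> float:
    mask = depth >= sink_max_depth
    if mask.sum() < 3:
        return float("nan")
    z, c = depth[mask], conc[mask]
    slope, intercept = np.polyfit(z, c, 1)
    resid = c - (slope * z + intercept)
    tss = float(np.sum((c - c.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0


def run_to_steady_state(
    config: ModelConfig,
    abundance: AbundanceProfile | None = None,
    initial: np.ndarray | None = None,
) -> ModelResult:
    """Iterate the explicit scheme until the field stops changing.

    Convergence is declared when the maximum rate of change max|dC|/dt falls
    below ``config.tolerance`` (uM s^-1).  The default initial condition is
    zero everywhere except the fixed bottom boundary; the steady state does
    not depend on it.  Non-convergence within ``max_steps`` returns a result
    flagged ``converged=False`` rather than raising.
    """
    grid = config.grid
    dt = _resolve_dt(config, abundance)
    d = config.diffusivity_on_grid()
    kappa = sink_coefficient_profile(config, abundance)
    lam = dt * d / config.dx**2

    if initial is None:
        c = np.zeros_like(grid)
        if config.boundary == "dirichlet":
            c[0] = config.c_top
            c[-1] = config.c_bottom
    else:
        c = np.asarray(initial, dtype=float).copy()
        if len(c) != len(grid):
            raise ValueError("initial condition length must match the grid")

    dirichlet = config.boundary == "dirichlet"
    thresh = config.tolerance * dt
    converged = False
    it = 0
    out = np.empty_like(c)
    for it in range(1, config.max_steps + 1):
        np.copyto(out, c)
        out[1:-1] = (
            c[1:-1]
            + lam[1:-1] * (c[2:] - 2.0 * c[1:-1] + c[:-2])
            + dt * kappa[1:-1] * c[1:-1]
        )
        if dirichlet:
            out[0] = config.c_top
            out[-1] = config.c_bottom
        else:
            out[0] = c[0] + lam[0] * (c[1] - c[0]) + dt * kappa[0] * c[0]
            out[-1] = c[-1] + lam[-1] * (c[-2] - c[-1]) + dt * kappa[-1] * c[-1]
        delta = float(np.max(np.abs(out - c)))
        c, out = out, c
        if delta < thresh:
            converged = True
            break

    rate = np.abs(kappa * c)
    return ModelResult(
        depth=grid,
        concentration=c.copy(),
        oxidation_rate=rate,
        iterations=it,
        converged=converged,
        dt_used=dt,
        config=config,
        linearity_r2=_linearity_below_sink(grid, c, config.sink_max_depth),
    )


def oxidation_horizon(result: ModelResult, fraction: float = 0.95) -> tuple[float, float]:
    """Depth interval containing the central ``fraction`` of total oxidation.

    Integrates the oxidation-rate magnitude over depth and returns the
    depths at the (1-fraction)/2 and (1+fraction)/2 quantiles of the
    cumulative integral (2.5th and 97.5th percentiles for the default 95%).
    """
    if not result.converged:
        warnings.warn("computing oxidation horizon on a non-converged result")
    z = result.depth
    r = result.oxidation_rate
    # cumulative trapezoidal integral of the rate over depth
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(z))])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero total oxidation: no horizon is defined")
    lo = (1.0 - fraction) / 2.0 * total
    hi = (1.0 + fraction) / 2.0 * total
    z_top = float(np.interp(lo, cum, z))
    z_bottom = float(np.interp(hi, cum, z))
    return z_top, z_bottom


def interpolate_abundance(
    profile: DepthProfile,
    grid: np.ndarray,
    method: Literal["log-linear", "linear"] = "log-linear",
    abundance_column: str = "ca_epsy914_cells_per_l",
    fraction_column: str = "f_sulfurimonas",
    default_fraction: float = 1.0,
) -> AbundanceProfile:
    """Interpolate sampled cell counts onto the model grid.

    The effective abundance (count times *Sulfurimonas* fraction) is
    interpolated log-linearly by default, because abundances span orders of
    magnitude across a redoxcline; beyond the sampled range the end values
    are extended as constants.
    """
    if len(profile) < 2:
        raise ValueError("abundance interpolation needs at least 2 sampled depths")
    grid = np.asarray(grid, dtype=float)
    z = profile.depth
    counts = profile.column(abundance_column)
    if fraction_column in profile.data.columns:
        frac = profile.column(fraction_column)
    else:
        frac = np.full_like(z, default_fraction)
    eff = counts * frac
    if method == "log-linear":
        tiny = 1e-30
        interp = np.exp(np.interp(grid, z, np.log(np.maximum(eff, tiny))))
        interp[interp <= 10 * tiny] = 0.0
    elif method == "linear":
        interp = np.interp(grid, z, eff)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return AbundanceProfile(depth=grid, cells_per_l=interp, fraction=1.0)


class SulfideTransportModel:
    """Reaction-diffusion model object for the redoxcline sulfide profile.

    Parameters
    ----------
    config : ModelConfig
    profile : DepthProfile, optional
        Water-column observations; required for the biological sink, where
        the sampled abundance is interpolated onto the model grid.

    Examples
    --------
    >>> cfg = ModelConfig(sink_mode="chemical")
    >>> res = SulfideTransportModel(cfg).solve()
    >>> res.horizon()  # doctest: +SKIP
    (97.1, 105.6)
    """

    def __init__(self, config: ModelConfig, profile: DepthProfile | None = None) -> None:
        self.config = config
        self.profile = profile
        if config.sink_mode in ("biological", "both"):
            if profile is None:
                raise ValueError("biological sink requires a depth profile")
            self.abundance = interpolate_abundance(profile, config.grid)
        else:
            self.abundance = None

    def solve(self, initial: np.ndarray | None = None) -> "TransportResults":
        result = run_to_steady_state(self.config, self.abundance, initial=initial)
        return TransportResults(self, result)


class TransportResults:
    """Steady-state profile with oxidation diagnostics and a summary table."""

    def __init__(self, model: SulfideTransportModel, result: ModelResult) -> None:
        self.model = model
        self.result = result

    @property
    def depth(self) -> np.ndarray:
        return self.result.depth

    @property
    def concentration(self) -> np.ndarray:
        return self.result.concentration

    @property
    def oxidation_rate(self) -> np.ndarray:
        return self.result.oxidation_rate

    @property
    def converged(self) -> bool:
        return self.result.converged

    def horizon(self, fraction: float = 0.95) -> tuple[float, float]:
        return oxidation_horizon(self.result, fraction)

    def to_frame(self) -> pd.DataFrame:
        return self.result.to_frame()

    def summary(self) -> str:
        cfg = self.model.config
        res = self.result
        z_top, z_bot = self.horizon() if res.oxidation_rate.sum() > 0 else (np.nan, np.nan)
        lines = [
            "Sulfide reaction-diffusion steady state",
            "=" * 46,
            f"sink mode                {cfg.sink_mode:>12s}",
            f"diffusivity (m^2 s^-1)   {float(np.max(cfg.diffusivity_on_grid())):>12.2e}",
            f"grid                     {cfg.depth_top:.0f}-{cfg.depth_bottom:.0f} m @ {cfg.dx} m",
            f"dt used (s)              {res.dt_used:>12.1f}",
            f"iterations               {res.iterations:>12d}",
            f"converged                {str(res.converged):>12s}",
            f"95% oxidation horizon    {z_top:>7.1f} - {z_bot:.1f} m",
            f"deep-profile linearity   {res.linearity_r2:>12.6f} (R^2 below sink zone)",
        ]
        return "\n".join(lines)

    def plot(self, axes=None):
        """Concentration and oxidation-rate profiles vs depth."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 5), sharey=True)
        ax_c, ax_r = axes
        ax_c.plot(self.concentration, self.depth)
        ax_c.set_xlabel("total sulfide (uM)")
        ax_c.set_ylabel("depth (m)")
        ax_r.plot(self.oxidation_rate, self.depth)
        ax_r.set_xlabel("oxidation rate (uM s$^{-1}$)")
        for ax in (ax_c, ax_r):
            ax.invert_yaxis() if not ax.yaxis_inverted() else None
        return axes
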
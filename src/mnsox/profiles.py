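"""Depth-profile container for water-column observations.

A :class:`DepthProfile` wraps a pandas DataFrame with a mandatory
``depth_m`` column (positive downward, strictly increasing) plus any number
of named observation columns.  The column dialect is fixed: snake_case with
units embedded in the name, e.g. ``s2_uM``, ``o2_uM``, ``mn_diss_nM``,
``ca_epsy914_cells_per_l``, ``f_sulfurimonas``, ``sigma_theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DepthProfile", "CONCENTRATION_SUFFIXES"]

#: column-name suffixes validated as non-negative physical quantities
CONCENTRATION_SUFFIXES = ("_uM", "_nM", "_cells_per_l")


@dataclass
class DepthProfile:
    """Depth-gridded concentrations, cell abundances and optional density.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``depth_m``; depth strictly increasing downward.
        ``sigma_theta`` (potential density anomaly, kg m^-3), where present,
        must also be strictly increasing to serve as a vertical coordinate.
    label : str
        Provenance label for the cast.
    truth : dict or None
        Generator ground truth when the profile is synthetic.
    """

    data: pd.DataFrame
    label: str = ""
    truth: dict | None = None

    def __post_init__(self) -> None:
        if "depth_m" not in self.data.columns:
            raise ValueError("profile requires a depth_m column")
        self.data = self.data.reset_index(drop=True)
        depth = self.data["depth_m"].to_numpy(dtype=float)
        if len(depth) and np.any(np.diff(depth) <= 0):
            raise ValueError("depth_m must be strictly increasing (positive downward)")
        for col in self.data.columns:
            if col.endswith(CONCENTRATION_SUFFIXES):
                vals = self.data[col].to_numpy(dtype=float)
                bad = np.flatnonzero(vals < 0)
                if bad.size:
                    raise ValueError(
                        f"negative value in column {col!r} at row {int(bad[0])}"
                    )
        if "f_sulfurimonas" in self.data.columns:
            f = self.data["f_sulfurimonas"].to_numpy(dtype=float)
            if np.any((f < 0) | (f > 1)):
                raise ValueError("f_sulfurimonas must lie in [0, 1]")

    @property
    def depth(self) -> np.ndarray:
        return self.data["depth_m"].to_numpy(dtype=float)

    @property
    def sigma_theta(self) -> np.ndarray | None:
        if "sigma_theta" not in self.data.columns:
            return None
        return self.data["sigma_theta"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"profile has no column {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "DepthProfile") -> bool:
        if set(self.data.columns) != set(other.data.columns):
            return False
        return all(
            np.allclose(
                self.data[c].to_numpy(dtype=float),
                other.data[c].to_numpy(dtype=float),
                rtol=0,
                atol=1e-12,
                equal_nan=True,
            )
            for c in self.data.columns
        )
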
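"""Density-coordinate alignment of CTD casts.

In a stratified water column, features sit on density surfaces rather than
at fixed depths, and internal waves displace those surfaces between casts.
Casts are therefore aligned by re-assigning each observation the depth at
which the reference cast shows the same potential density anomaly
(sigma-theta), using monotone piecewise-linear interpolation of the
reference's sigma-theta -> depth relation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .profiles import DepthProfile

__all__ = ["align_by_density"]


def _require_sigma(profile: DepthProfile, role: str) -> np.ndarray:
    sigma = profile.sigma_theta
    if sigma is None:
        raise ValueError(f"{role} cast lacks a sigma_theta column")
    if np.any(np.diff(sigma) <= 0):
        raise ValueError(f"{role} cast sigma_theta is not strictly increasing")
    return sigma


def align_by_density(
    casts: list[DepthProfile], reference: DepthProfile
) -> list[DepthProfile]:
    """Re-assign depths in each cast from the reference's density structure.

    Every observation keeps all its non-depth fields; only ``depth_m`` is
    replaced by interpolating the reference sigma-theta -> depth mapping at
    the observation's own sigma-theta.  Values outside the reference density
    range are mapped to the end depths (constant extrapolation) with a
    warning.
    """
    ref_sigma = _require_sigma(reference, "reference")
    ref_depth = reference.depth

    aligned: list[DepthProfile] = []
    for i, cast in enumerate(casts):
        sigma = _require_sigma(cast, f"cast {i}")
        if np.any(sigma < ref_sigma[0]) or np.any(sigma > ref_sigma[-1]):
            warnings.warn(
                f"cast {i} ({cast.label or 'unnamed'}): sigma_theta outside the "
                "reference range; constant-end extrapolation applied",
                stacklevel=2,
            )
        new_depth = np.interp(sigma, ref_sigma, ref_depth)
        # constant-end extrapolation can tie depths at the ends; nudge to keep
        # the depth axis strictly increasing
        for j in range(1, len(new_depth)):
            if new_depth[j] <= new_depth[j - 1]:
                new_depth[j] = new_depth[j - 1] + 1e-9
        data = cast.data.copy()
        data["depth_m"] = new_depth
        aligned.append(DepthProfile(data=data, label=cast.label, truth=cast.truth))
    return aligned
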
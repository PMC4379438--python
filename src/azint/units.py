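"""Radial output-space units for azimuthal integration."""

from __future__ import annotations

import numpy as np

__all__ = ["RADIAL_UNITS", "radial_values", "unit_label"]

#: recognized radial units -> axis label
RADIAL_UNITS = {
    "2th_rad": "2theta (rad)",
    "2th_deg": "2theta (deg)",
    "q_nm^-1": "q (nm^-1)",
    "q_A^-1": "q (A^-1)",
    "r_m": "r (m)",
    "r_mm": "r (mm)",
}


def radial_values(angles, unit: str) -> np.ndarray:
    """Convert a :class:`~azint.geometry.PixelAngles` to the requested unit."""
    if unit == "2th_rad":
        return angles.tth
    if unit == "2th_deg":
        return np.degrees(angles.tth)
    if unit == "q_nm^-1":
        return angles.q
    if unit == "q_A^-1":
        return angles.q * 0.1
    if unit == "r_m":
        return angles.r
    if unit == "r_mm":
        return angles.r * 1e3
    raise ValueError(f"unknown radial unit {unit!r}; known: {sorted(RADIAL_UNITS)}")


def unit_label(unit: str) -> str:
    try:
        return RADIAL_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown radial unit {unit!r}") from None
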
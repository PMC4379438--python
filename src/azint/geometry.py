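"""Six-parameter PONI detector geometry and pixel -> angle transforms.

The experiment frame has its origin at the sample.  Axis 1 is vertical,
axis 2 horizontal and axis 3 points along the incident beam.  A rigid flat
detector is positioned by:

* ``dist``  — sample to PONI distance (metres),
* ``poni1``, ``poni2`` — coordinates of the point of normal incidence in
  the detector frame (metres),
* ``rot1``, ``rot2``, ``rot3`` — rotations (radians) about the vertical
  axis, the horizontal axis and the beam axis, applied in that order.

A detector-frame point ``(c1, c2, c3)`` maps to the lab frame as::

    lab = R3(rot3) @ R2(rot2) @ R1(rot1) @ (c1 - poni1, c2 - poni2, c3 + dist)

With all rotations zero the detector sits in transmission with the beam
orthogonal to its surface and the PONI at ``(0, 0, dist)``.

Rotations are active and right-handed; this sign convention is frozen by
the regression tests.  The azimuth ``chi`` is zero along the horizontal
transverse axis and grows towards vertical, in ``(-pi, pi]``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .detector import Detector, pixel_centers, pixel_corners

__all__ = ["Geometry", "PixelAngles", "lab_coordinates", "pixel_angles",
           "read_poni", "write_poni", "rotation_matrix"]

PONI_KEYS = ("Distance", "Poni1", "Poni2", "Rot1", "Rot2", "Rot3")


@dataclasses.dataclass
class Geometry:
    dist: float
    poni1: float
    poni2: float
    rot1: float = 0.0
    rot2: float = 0.0
    rot3: float = 0.0
    wavelength: Optional[float] = None
    detector: Optional[Detector] = None

    def __post_init__(self) -> None:
        if not (self.dist > 0):
            raise ValueError(f"dist must be > 0, got {self.dist}")
        for name in ("rot1", "rot2", "rot3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.wavelength is not None and not (self.wavelength > 0):
            raise ValueError("wavelength must be > 0 when set")

    def rotation_matrix(self) -> np.ndarray:
        return rotation_matrix(self.rot1, self.rot2, self.rot3)

    def replace(self, **kw) -> "Geometry":
        return dataclasses.replace(self, **kw)

    def param_dict(self) -> dict:
        return {"dist": self.dist, "poni1": self.poni1, "poni2": self.poni2,
                "rot1": self.rot1, "rot2": self.rot2, "rot3": self.rot3,
                "wavelength": self.wavelength}


class PixelAngles:
    """Per-position angular coordinates derived from a geometry.

    ``tth`` is the scattering angle 2-theta (radians, >= 0), ``chi`` the
    azimuth in ``(-pi, pi]``, ``r`` the in-plane radius ``dist * tan(tth)``
    and ``q`` the scattering-vector magnitude ``4 pi sin(tth/2) / lambda``
    reported in inverse nanometres (lazily computed; requires wavelength).
    """

    def __init__(self, tth: np.ndarray, chi: np.ndarray, dist: float,
                 wavelength: Optional[float]):
        self.tth = tth
        self.chi = chi
        self._dist = dist
        self._wavelength = wavelength

    @property
    def r(self) -> np.ndarray:
        return self._dist * np.tan(self.tth)

    @property
    def q(self) -> np.ndarray:
        if self._wavelength is None:
            raise ValueError("q requested but no wavelength is set")
        lam_nm = self._wavelength * 1e9
        return (4.0 * np.pi / lam_nm) * np.sin(0.5 * self.tth)


def rotation_matrix(rot1: float, rot2: float, rot3: float) -> np.ndarray:
    """Composed active rotation R3(rot3) @ R2(rot2) @ R1(rot1)."""
    c1, s1 = math.cos(rot1), math.sin(rot1)
    c2, s2 = math.cos(rot2), math.sin(rot2)
    c3, s3 = math.cos(rot3), math.sin(rot3)
    r1 = np.array([[1, 0, 0], [0, c1, -s1], [0, s1, c1]], dtype=np.float64)
    r2 = np.array([[c2, 0, s2], [0, 1, 0], [-s2, 0, c2]], dtype=np.float64)
    r3 = np.array([[c3, -s3, 0], [s3, c3, 0], [0, 0, 1]], dtype=np.float64)
    return r3 @ r2 @ r1


def lab_coordinates(geom: Geometry, positions: np.ndarray) -> np.ndarray:
    """Map detector-frame points (..., 3) to lab-frame points (metres)."""
    p = np.asarray(positions, dtype=np.float64)
    t = np.empty_like(p)
    t[..., 0] = p[..., 0] - geom.poni1
    t[..., 1] = p[..., 1] - geom.poni2
    t[..., 2] = p[..., 2] + geom.dist
    return t @ geom.rotation_matrix().T


def angles_of_points(geom: Geometry, positions: np.ndarray) -> PixelAngles:
    """Angular coordinates of arbitrary detector-frame points (..., 3)."""
    lab = lab_coordinates(geom, positions)
    transverse = np.hypot(lab[..., 0], lab[..., 1])
    tth = np.arctan2(transverse, lab[..., 2])
    chi = np.arctan2(lab[..., 0], lab[..., 1])
    # fold chi into (-pi, pi]: arctan2 yields [-pi, pi]; move -pi to +pi
    chi = np.where(chi <= -np.pi, np.pi, chi)
    return PixelAngles(tth, chi, geom.dist, geom.wavelength)


def pixel_angles(geom: Geometry, at: str = "centers") -> PixelAngles:
    """Angular coordinates of every pixel centre or corner.

    ``at='centers'`` returns arrays of shape (Ny, Nx); ``at='corners'``
    of shape (Ny, Nx, 4).
    """
    if geom.detector is None:
        raise ValueError("geometry has no detector attached")
    if at == "centers":
        pos = pixel_centers(geom.detector)
    elif at == "corners":
        pos = pixel_corners(geom.detector)
    else:
        raise ValueError(f"at must be 'centers' or 'corners', got {at!r}")
    return angles_of_points(geom, pos)


def detector_coords_of_angles(geom: Geometry, tth, chi) -> np.ndarray:
    """Invert the pixel->angle map: detector-frame (c1, c2) hit by the
    scattered ray at (tth, chi).  Closed form for a flat detector; rays
    pointing away from the detector plane yield NaN.
    """
    tth = np.asarray(tth, dtype=np.float64)
    chi = np.asarray(chi, dtype=np.float64)
    v = np.stack([np.sin(tth) * np.sin(chi),
                  np.sin(tth) * np.cos(chi),
                  np.cos(tth) * np.ones_like(chi)], axis=-1)
    w = v @ geom.rotation_matrix()          # R^T v for each row
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(w[..., 2] > 0, geom.dist / w[..., 2], np.nan)
    c1 = geom.poni1 + s * w[..., 0]
    c2 = geom.poni2 + s * w[..., 1]
    return np.stack([c1, c2], axis=-1)


# ---------------------------------------------------------------------------
# PONI text format
# ---------------------------------------------------------------------------

def write_poni(geom: Geometry, path) -> None:
    """Write the geometry as a PONI text file (SI units, one key per line)."""
    lines = ["# Detector geometry (PONI format, SI units: metres / radians)"]
    if geom.detector is not None:
        det = geom.detector
        lines.append("Detector: flat")
        lines.append(f"Shape1: {det.shape[0]:d}")
        lines.append(f"Shape2: {det.shape[1]:d}")
        lines.append(f"PixelSize1: {float(det.pixel1)!r}")
        lines.append(f"PixelSize2: {float(det.pixel2)!r}")
    lines.append(f"Distance: {float(geom.dist)!r}")
    lines.append(f"Poni1: {float(geom.poni1)!r}")
    lines.append(f"Poni2: {float(geom.poni2)!r}")
    lines.append(f"Rot1: {float(geom.rot1)!r}")
    lines.append(f"Rot2: {float(geom.rot2)!r}")
    lines.append(f"Rot3: {float(geom.rot3)!r}")
    if geom.wavelength is not None:
        lines.append(f"Wavelength: {float(geom.wavelength)!r}")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_poni(path) -> Geometry:
    """Parse a PONI text file written by :func:`write_poni`.

    '#' lines are comments; missing mandatory keys or non-numeric values
    raise ``ValueError`` naming the offending key/line.
    """
    values: dict = {}
    with open(path) as f:
        for lineno, raw in enumerate(f, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: expected 'Key: value', got {line!r}")
            key, _, val = line.partition(":")
            values[key.strip()] = (val.strip(), lineno)

    def _num(key: str) -> float:
        val, lineno = values[key]
        try:
            return float(val)
        except ValueError:
            raise ValueError(
                f"non-numeric value {val!r} for key {key} (line {lineno})"
            ) from None

    for key in PONI_KEYS:
        if key not in values:
            raise ValueError(f"missing mandatory key {key} in PONI file {path}")

    detector = None
    if "PixelSize1" in values and "Shape1" in values:
        detector = Detector(
            (int(_num("Shape1")), int(_num("Shape2"))),
            _num("PixelSize1"), _num("PixelSize2"))
    wavelength = _num("Wavelength") if "Wavelength" in values else None
    return Geometry(dist=_num("Distance"), poni1=_num("Poni1"),
                    poni2=_num("Poni2"), rot1=_num("Rot1"), rot2=_num("Rot2"),
                    rot3=_num("Rot3"), wavelength=wavelength, detector=detector)
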
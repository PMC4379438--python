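"""Calibrant bookkeeping and synthetic diffraction-image generation.

A calibrant is an ordered list of lattice d-spacings (angstroms).  Combined
with a wavelength it yields the ring apertures ``2theta_n = 2 asin(lambda /
2 d_n)``.  This module is also the package's fixture engine: it regenerates
2-D images from 1-D patterns under the isotropy assumption (`calcfrom1d`)
and produces synthetic continuous-ring and spotty-ring calibration images
with known ground truth.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import units as _units
from .geometry import Geometry

logger = logging.getLogger(__name__)

__all__ = ["Calibrant", "CagliotiParams", "ring_angles", "calcfrom1d",
           "fake_calibration_image", "spotty_rings_image", "load_calibrant"]


@dataclasses.dataclass
class Calibrant:
    """Named list of d-spacings (angstroms, strictly decreasing)."""

    name: str
    dspacing: Sequence[float]
    wavelength: Optional[float] = None  # metres

    def __post_init__(self) -> None:
        d = sorted({float(x) for x in self.dspacing}, reverse=True)
        if not d or d[-1] <= 0:
            raise ValueError("d-spacings must be positive")
        self.dspacing = d

    @classmethod
    def from_file(cls, path, wavelength: Optional[float] = None) -> "Calibrant":
        """Load d values from a text file, one value (angstroms) per line,
        '#' comments allowed."""
        d: List[float] = []
        with open(path) as f:
            for raw in f:
                line = raw.split("#", 1)[0].strip()
                if line:
                    d.append(float(line.split()[0]))
        name = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
        return cls(name, d, wavelength)

    def ring_angles(self) -> np.ndarray:
        return ring_angles(self)


def load_calibrant(name: str, wavelength: Optional[float] = None) -> Calibrant:
    """Load one of the bundled calibrant fixture files (e.g. ``LaB6``)."""
    ref = importlib.resources.files("azint").joinpath(f"data/{name}.D")
    with importlib.resources.as_file(ref) as path:
        return Calibrant.from_file(path, wavelength)


@dataclasses.dataclass
class CagliotiParams:
    """Resolution function: FWHM^2(2theta) = U tan^2(theta) + V tan(theta) + W.

    U, V, W are expressed so that the FWHM comes out in radians of 2theta
    (the unit in which 1-D patterns are generated internally).
    """

    U: float = 0.0
    V: float = 0.0
    W: float = 1e-6

    def fwhm(self, tth) -> np.ndarray:
        t = np.tan(np.asarray(tth, dtype=np.float64) / 2.0)
        fwhm2 = self.U * t * t + self.V * t + self.W
        if np.any(fwhm2 <= 0):
            raise ValueError("Caglioti FWHM^2 must be > 0 over the rings used")
        return np.sqrt(fwhm2)

    def sigma(self, tth) -> np.ndarray:
        return self.fwhm(tth) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def ring_angles(cal: Calibrant) -> np.ndarray:
    """Ring apertures 2theta_n = 2 asin(lambda / 2 d_n), ascending (radians).

    Rings with ``lambda > 2 d`` are unreachable and silently excluded
    (with a log notice).
    """
    if cal.wavelength is None:
        raise ValueError("calibrant has no wavelength set")
    lam_A = cal.wavelength * 1e10
    d = np.asarray(cal.dspacing, dtype=np.float64)
    x = lam_A / (2.0 * d)
    reachable = x <= 1.0
    if not np.all(reachable):
        logger.info("%s: %d unreachable rings excluded (lambda > 2d)",
                    cal.name, int(np.sum(~reachable)))
    tth = 2.0 * np.arcsin(x[reachable])
    return np.sort(tth)


def calcfrom1d(geom: Geometry, radial_grid: np.ndarray, intensity: np.ndarray,
               unit: str = "2th_rad") -> np.ndarray:
    """Regenerate a 2-D image from a 1-D pattern assuming azimuthal isotropy.

    Each pixel takes the linear interpolation of the pattern at its
    centre's radial coordinate; pixels outside the grid and masked pixels
    are set to 0.
    """
    from .geometry import pixel_angles

    radial_grid = np.asarray(radial_grid, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if radial_grid.ndim != 1 or radial_grid.shape != intensity.shape:
        raise ValueError(
            f"grid shape {radial_grid.shape} and intensity shape "
            f"{intensity.shape} must be equal 1-D")
    if np.any(np.diff(radial_grid) <= 0):
        raise ValueError("radial grid must be strictly increasing")
    coord = _units.radial_values(pixel_angles(geom, at="centers"), unit)
    img = np.interp(coord, radial_grid, intensity, left=0.0, right=0.0)
    img[geom.detector.mask] = 0.0
    return img


def _ring_pattern(cal: Calibrant, geom: Geometry, caglioti: CagliotiParams,
                  Imax: float) -> Tuple[np.ndarray, np.ndarray]:
    """1-D pattern: unit-area Gaussian at every reachable ring, rescaled so
    the tallest peak reaches ~Imax."""
    from .geometry import pixel_angles

    tth_rings = ring_angles(cal)
    tth_max = float(np.max(pixel_angles(geom, at="centers").tth))
    if tth_rings.size == 0 or float(tth_rings[0]) > tth_max:
        raise ValueError("no calibrant ring falls inside the detector acceptance")
    sigmas = caglioti.sigma(tth_rings)
    hi = min(float(tth_rings[-1]) + 8 * float(sigmas[-1]), tth_max + 8 * float(sigmas[-1]))
    step = float(np.min(sigmas)) / 8.0
    npt = min(int(hi / step) + 2, 200_000)
    grid = np.linspace(0.0, hi, npt)
    pattern = np.zeros_like(grid)
    for t0, s in zip(tth_rings, sigmas):
        pattern += np.exp(-0.5 * ((grid - t0) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    pattern *= Imax / pattern.max()
    return grid, pattern


def fake_calibration_image(cal: Calibrant, geom: Geometry,
                           caglioti: Optional[CagliotiParams] = None,
                           Imax: float = 1e4,
                           poisson_noise: bool = False,
                           seed: Optional[int] = None) -> np.ndarray:
    """Synthetic Debye-Scherrer ring image.

    Every reachable ring carries the same integrated intensity (unit-area
    Gaussian peaks in 2theta with Caglioti widths, globally rescaled so the
    tallest peak reaches ~``Imax``).  With ``poisson_noise`` the image is
    resampled pixel-wise from a Poisson law seeded by ``seed``.
    """
    if caglioti is None:
        caglioti = CagliotiParams(W=(2e-3) ** 2)
    grid, pattern = _ring_pattern(cal, geom, caglioti, Imax)
    img = calcfrom1d(geom, grid, pattern, unit="2th_rad")
    if poisson_noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(np.float64)
    return img


def spotty_rings_image(cal: Calibrant, geom: Geometry,
                       n_spots_per_ring: int,
                       spot_sigma: float = 2.0,
                       seed: Optional[int] = None,
                       Imax: float = 1e4,
                       min_sep: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Spotty-ring fixture: isolated Gaussian spots at random azimuths on
    each reachable ring.

    Returns ``(image, centers)`` where ``centers`` is an ``(n, 3)`` array of
    ground-truth ``(ring_index, y, x)`` subpixel spot centres (pixel-centre
    convention) for peak-picking tests.  With ``min_sep`` > 0, spots closer
    than that many pixels to an already placed one are skipped (keeps the
    ground truth unambiguous for peak-matching tests).
    """
    from .geometry import detector_coords_of_angles, pixel_angles

    det = geom.detector
    ny, nx = det.shape
    img = np.zeros((ny, nx), dtype=np.float64)
    rng = np.random.default_rng(seed)
    tth_rings = ring_angles(cal)
    tth_max = float(np.max(pixel_angles(geom, at="centers").tth))
    centers: List[Tuple[int, float, float]] = []
    for n, tth in enumerate(tth_rings):
        if tth > tth_max:
            continue
        chis = rng.uniform(-np.pi, np.pi, size=n_spots_per_ring)
        pos = detector_coords_of_angles(geom, np.full_like(chis, tth), chis)
        y = pos[:, 0] / det.pixel1 - 0.5
        x = pos[:, 1] / det.pixel2 - 0.5
        margin = 4.0 * spot_sigma + 2.0
        ok = (np.isfinite(y) & np.isfinite(x)
              & (y > margin) & (y < ny - 1 - margin)
              & (x > margin) & (x < nx - 1 - margin))
        for yc, xc in zip(y[ok], x[ok]):
            if min_sep > 0 and any(
                    (yc - c[1]) ** 2 + (xc - c[2]) ** 2 < min_sep ** 2
                    for c in centers):
                continue
            _add_gaussian_spot(img, yc, xc, spot_sigma, Imax)
            centers.append((n, yc, xc))
    return img, np.array(centers, dtype=np.float64).reshape(-1, 3)


def _add_gaussian_spot(img: np.ndarray, yc: float, xc: float,
                       sigma: float, amplitude: float) -> None:
    rad = int(math.ceil(5 * sigma))
    y0 = max(int(yc) - rad, 0)
    y1 = min(int(yc) + rad + 2, img.shape[0])
    x0 = max(int(xc) - rad, 0)
    x1 = min(int(xc) + rad + 2, img.shape[1])
    yy = np.arange(y0, y1, dtype=np.float64)[:, None]
    xx = np.arange(x0, x1, dtype=np.float64)[None, :]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * (((yy - yc) / sigma) ** 2 + ((xx - xc) / sigma) ** 2))
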
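"""Isotropic / Bragg decomposition and phase-correlation validation.

``separate`` performs a 2-D azimuthal integration, filters each radial bin
with a percentile (default the median) along the azimuth to obtain a 1-D
pattern free of sharp Bragg spots, re-projects that pattern through
``calcfrom1d`` and subtracts: ``input = isotropic + bragg`` exactly on
unmasked pixels.

``measure_offset`` recovers the (dy, dx) displacement between two images
by classical phase correlation with subpixel refinement, and
``validate_calibration`` uses it to score a geometry by comparing an image
with its own integrate-then-regenerate round trip.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Tuple

import numpy as np

from .calibrant import calcfrom1d
from .geometry import Geometry
from .integrate import integrate1d, integrate2d
from .peakpick import refine_subpixel

__all__ = ["SeparationResult", "separate", "measure_offset",
           "validate_calibration", "frame_score"]


@dataclasses.dataclass
class SeparationResult:
    isotropic: np.ndarray
    bragg: np.ndarray
    radial: np.ndarray
    pattern: np.ndarray
    npt_rad: int
    npt_azim: int
    percentile: float


def separate(img: np.ndarray, geom: Geometry,
             npt_rad: int = 1024, npt_azim: int = 512,
             percentile: float = 50.0,
             mask: Optional[np.ndarray] = None,
             unit: str = "2th_rad") -> SeparationResult:
    """Split an image into an azimuthally symmetric component and the rest.

    The percentile (linear interpolation definition) is taken over the
    nonempty azimuthal bins of each radial bin of a full-split 2-D
    integration.  Radial bins with no azimuthal coverage are interpolated
    from their neighbours with a warning.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    img = np.asarray(img, dtype=np.float64)
    res2 = integrate2d(img, geom, npt_rad=npt_rad, npt_azim=npt_azim,
                       unit=unit, scheme="fullsplit", method="csr", mask=mask)
    # intensity has shape (npt_azim, npt_rad); filter along the azimuth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pattern = np.nanpercentile(res2.intensity, percentile, axis=0)
    bad = ~np.isfinite(pattern)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} radial bins with no azimuthal "
                      "coverage; interpolated from neighbours")
        good = ~bad
        pattern = np.interp(np.arange(pattern.size),
                            np.nonzero(good)[0], pattern[good])
    radial = res2.radial
    # constant-extend to the grid edges so the outermost half-bins are
    # reprojected instead of zeroed
    edges = res2.grid.radial_edges
    grid_ext = np.concatenate([[edges[0]], radial, [edges[-1]]])
    pattern_ext = np.concatenate([[pattern[0]], pattern, [pattern[-1]]])
    isotropic = calcfrom1d(geom, grid_ext, pattern_ext, unit=unit)
    if mask is not None:
        isotropic = isotropic.copy()
        isotropic[np.asarray(mask, dtype=bool)] = 0.0
    bragg = img - isotropic
    full_mask = geom.detector.mask.copy()
    if mask is not None:
        full_mask |= np.asarray(mask, dtype=bool)
    bragg[full_mask] = 0.0
    return SeparationResult(isotropic=isotropic, bragg=bragg, radial=radial,
                            pattern=pattern, npt_rad=npt_rad,
                            npt_azim=npt_azim, percentile=percentile)


def measure_offset(img_a: np.ndarray, img_b: np.ndarray) -> Tuple[float, float]:
    """Subpixel (dy, dx) displacement of ``img_b`` relative to ``img_a``
    by normalized cross-power-spectrum phase correlation.

    ``img_b approx shift(img_a, (dy, dx))`` (circular); the correlation
    peak is refined on its 3x3 neighbourhood.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("phase correlation undefined for a constant image")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    cross = np.where(mag > 0, cross / np.where(mag > 0, mag, 1.0), 0.0)
    # Gaussian low-pass weight: turns the sinc-like correlation peak into a
    # near-Gaussian one so the 3x3 quadratic refinement is unbiased
    ky = np.fft.fftfreq(a.shape[0])[:, None]
    kx = np.fft.fftfreq(a.shape[1])[None, :]
    cross = cross * np.exp(-(ky ** 2 + kx ** 2) / (2 * 0.1 ** 2))
    corr = np.fft.ifft2(cross).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    # recentre the peak so its 3x3 neighbourhood is interior
    shift_to_center = (a.shape[0] // 2 - peak[0], a.shape[1] // 2 - peak[1])
    rolled = np.roll(corr, shift_to_center, axis=(0, 1))
    center = (a.shape[0] // 2, a.shape[1] // 2)
    patch = rolled[center[0] - 1:center[0] + 2, center[1] - 1:center[1] + 2]
    if np.all(patch > 0):
        # log of a Gaussian peak is exactly quadratic
        work = np.zeros_like(rolled)
        work[center[0] - 1:center[0] + 2, center[1] - 1:center[1] + 2] = (
            np.log(patch) - np.log(patch).min() + 1.0)
        pos = refine_subpixel(work, center)
    else:
        pos = refine_subpixel(rolled, center)
    dy = pos[0] - shift_to_center[0]
    dx = pos[1] - shift_to_center[1]
    # map to the centred branch
    if dy > a.shape[0] / 2:
        dy -= a.shape[0]
    if dx > a.shape[1] / 2:
        dx -= a.shape[1]
    return float(dy), float(dx)


def validate_calibration(img: np.ndarray, geom: Geometry, npt: int = 1024,
                         mask: Optional[np.ndarray] = None) -> float:
    """Magnitude (pixels) of the offset between an image and the image
    regenerated from its own azimuthally integrated pattern.  Small values
    indicate an accurate PONI localization."""
    res = integrate1d(img, geom, npt=npt, unit="2th_rad", scheme="fullsplit",
                      method="csr", mask=mask)
    pattern = np.nan_to_num(res.intensity, nan=0.0)
    edges = res.grid.radial_edges
    grid_ext = np.concatenate([[edges[0]], res.radial, [edges[-1]]])
    pattern_ext = np.concatenate([[pattern[0]], pattern, [pattern[-1]]])
    regen = calcfrom1d(geom, grid_ext, pattern_ext, unit="2th_rad")
    dy, dx = measure_offset(img, regen)
    return float(np.hypot(dy, dx))


def frame_score(result: SeparationResult, k: float = 4.0) -> float:
    """Serial-crystallography triage statistic: summed positive Bragg
    intensity above ``k`` standard deviations of the isotropic level.
    (Extension: the underlying use case only names frame selection.)"""
    level = np.std(result.isotropic)
    excess = result.bragg - k * level
    return float(excess[excess > 0].sum())
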
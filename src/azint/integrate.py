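"""1-D / 2-D azimuthal integration with three pixel-splitting schemes.

Two execution paths produce algebraically identical results:

* ``method="direct"`` — one-pass scatter histogramming over the pixels;
* ``method="csr"`` — a precomputed pixel->bin coefficient matrix in CSR
  layout (:class:`Rebinner`), applied as a sparse-matrix-vector product.

Splitting schemes: ``nosplit`` (pixel centre into one bin), ``bbox``
(axis-aligned bounding box in (radial, azimuth) space, separable overlap
fractions) and ``fullsplit`` (polygon clipping of the pixel quadrilateral
against bin rectangles).

Error models (``sigma`` output):

* ``poisson`` — per-pixel variance equal to the (clipped >= 0) raw signal,
  propagated as ``sigma_b^2 = sum(c^2 var) / (sum c)^2``;
* ``azimuthal`` — weighted sample variance of the contributing pixel
  signals divided by the effective count ``(sum c)^2 / sum(c^2)``;
* ``variance`` — like ``poisson`` but with a user-supplied per-pixel
  variance array.

Caveat: any pixel-splitting scheme introduces serial correlation between
neighbouring bins, so the propagated sigma overestimates the true error
slightly; this is noted in the ASCII output header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from . import _kernels
from . import units as _units
from .detector import quad_areas
from .geometry import Geometry, pixel_angles

__all__ = ["BinGrid", "Rebinner", "IntegrationResult", "corrections",
           "bbox_fractions", "polygon_fractions", "build_rebinner",
           "integrate1d", "integrate2d", "propagate_errors"]

SCHEMES = {"nosplit": 0, "bbox": 1, "fullsplit": 2}
ERROR_MODELS = ("none", "poisson", "azimuthal", "variance")


@dataclasses.dataclass
class BinGrid:
    """Output bin grid: equal-width radial edges, optional azimuthal edges."""

    radial_edges: np.ndarray
    azim_edges: Optional[np.ndarray] = None
    unit: str = "2th_rad"

    def __post_init__(self) -> None:
        self.radial_edges = np.asarray(self.radial_edges, dtype=np.float64)
        if self.radial_edges.ndim != 1 or self.radial_edges.size < 2:
            raise ValueError("radial_edges must be 1-D with >= 2 entries")
        if np.any(np.diff(self.radial_edges) <= 0):
            raise ValueError("radial_edges must be strictly increasing")
        if self.azim_edges is not None:
            self.azim_edges = np.asarray(self.azim_edges, dtype=np.float64)
            if np.any(np.diff(self.azim_edges) <= 0):
                raise ValueError("azim_edges must be strictly increasing")

    @property
    def npt_rad(self) -> int:
        return self.radial_edges.size - 1

    @property
    def npt_azim(self) -> int:
        return 0 if self.azim_edges is None else self.azim_edges.size - 1

    @property
    def radial_centers(self) -> np.ndarray:
        return 0.5 * (self.radial_edges[:-1] + self.radial_edges[1:])

    @property
    def azim_centers(self) -> Optional[np.ndarray]:
        if self.azim_edges is None:
            return None
        return 0.5 * (self.azim_edges[:-1] + self.azim_edges[1:])

    def _kernel_params(self) -> Tuple[float, float, int, float, float, int, bool]:
        rlo = float(self.radial_edges[0])
        dr = float((self.radial_edges[-1] - self.radial_edges[0]) / self.npt_rad)
        if self.azim_edges is None:
            return rlo, dr, self.npt_rad, 0.0, 1.0, 0, False
        alo = float(self.azim_edges[0])
        na = self.npt_azim
        da = float((self.azim_edges[-1] - alo) / na)
        wrap = bool(abs(self.azim_edges[-1] - alo - 2 * np.pi) < 1e-9)
        return rlo, dr, self.npt_rad, alo, da, na, wrap


@dataclasses.dataclass
class Rebinner:
    """Precomputed pixel->bin CSR coefficient matrix for one geometry,
    splitting scheme and bin grid."""

    csr: sp.csr_matrix          # shape (nbins, npix)
    scheme: str
    grid: BinGrid
    mask: np.ndarray            # flat boolean, True = excluded
    fingerprint: str

    @property
    def nbins(self) -> int:
        return self.csr.shape[0]

    def bin_weights(self) -> np.ndarray:
        return np.asarray(self.csr.sum(axis=1)).ravel()


@dataclasses.dataclass
class IntegrationResult:
    radial: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray]
    weight: np.ndarray
    count: np.ndarray
    unit: str
    grid: BinGrid
    azimuthal: Optional[np.ndarray] = None


def _geometry_fingerprint(geom: Geometry) -> str:
    det = geom.detector
    h = hashlib.sha1()
    for v in (geom.dist, geom.poni1, geom.poni2, geom.rot1, geom.rot2,
              geom.rot3, geom.wavelength or 0.0,
              det.pixel1, det.pixel2, *det.shape):
        h.update(repr(v).encode())
    h.update(det.mask.tobytes())
    if det.corners is not None:
        h.update(hashlib.sha1(det.corners.tobytes()).digest())
    return h.hexdigest()[:16]


def _unwrap_corner_azimuth(ca: np.ndarray) -> np.ndarray:
    """Bring each pixel's 4 corner azimuths within pi of their circular mean
    so that boxes straddling the +-pi cut stay compact."""
    mean = np.arctan2(np.sin(ca).mean(axis=-1), np.cos(ca).mean(axis=-1))
    return ca - 2 * np.pi * np.round((ca - mean[..., None]) / (2 * np.pi))


def _pixel_coordinates(geom: Geometry, unit: str, scheme: str):
    """Flat per-pixel coordinate arrays for the kernels.

    Returns (cr, ca, rc, ac): corner radial (npix, 4), unwrapped corner
    azimuth (npix, 4), centre radial (npix,), centre azimuth (npix,).
    """
    npix = geom.detector.size
    cang = pixel_angles(geom, at="centers")
    rc = _units.radial_values(cang, unit).reshape(npix)
    ac = cang.chi.reshape(npix)
    if scheme == "nosplit":
        z4 = np.zeros((npix, 4))
        return z4, z4, rc, ac
    kang = pixel_angles(geom, at="corners")
    cr = _units.radial_values(kang, unit).reshape(npix, 4)
    ca = _unwrap_corner_azimuth(kang.chi).reshape(npix, 4)
    return np.ascontiguousarray(cr), np.ascontiguousarray(ca), rc, ac


def _effective_mask(geom: Geometry, img: Optional[np.ndarray],
                    mask: Optional[np.ndarray],
                    dummy: Optional[float], delta_dummy: float) -> np.ndarray:
    m = geom.detector.mask.copy()
    if mask is not None:
        m |= np.asarray(mask, dtype=bool)
    if img is not None:
        img = np.asarray(img)
        m |= ~np.isfinite(img)
        if dummy is not None:
            m |= np.abs(img - dummy) <= delta_dummy
    return m


def _default_grid(geom: Geometry, unit: str, scheme: str, npt: int,
                  npt_azim: int, mask: np.ndarray,
                  radial_range: Optional[Tuple[float, float]]) -> BinGrid:
    """Default radial range: [min, max] of the relevant coordinate over
    unmasked pixels (corner-based for splitting schemes)."""
    if radial_range is None:
        at = "centers" if scheme == "nosplit" else "corners"
        coord = _units.radial_values(pixel_angles(geom, at=at), unit)
        valid = ~mask if at == "centers" else ~mask[..., None]
        sel = np.broadcast_to(valid, coord.shape)
        lo = float(coord[sel].min())
        hi = float(coord[sel].max())
    else:
        lo, hi = map(float, radial_range)
    if not hi > lo:
        raise ValueError("empty radial range")
    redges = np.linspace(lo, hi, npt + 1)
    aedges = np.linspace(-np.pi, np.pi, npt_azim + 1) if npt_azim else None
    return BinGrid(redges, aedges, unit)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def solid_angle_map(geom: Geometry) -> np.ndarray:
    """Relative solid angle cos^3(alpha), alpha = angle between the pixel
    direction and the detector normal; 1 at the PONI."""
    from .detector import pixel_centers
    from .geometry import lab_coordinates

    lab = lab_coordinates(geom, pixel_centers(geom.detector))
    n = geom.rotation_matrix()[:, 2]
    norm = np.sqrt(np.sum(lab * lab, axis=-1))
    cosa = (lab @ n) / norm
    return cosa ** 3


def polarization_map(geom: Geometry, factor: float) -> np.ndarray:
    """Kahn-style polarization factor
    P = 0.5 (1 + cos^2(2th) - f cos(2 chi) sin^2(2th))."""
    ang = pixel_angles(geom, at="centers")
    c2 = np.cos(ang.tth) ** 2
    s2 = 1.0 - c2
    return 0.5 * (1.0 + c2 - factor * np.cos(2.0 * ang.chi) * s2)


def corrections(img: np.ndarray, geom: Geometry,
                dark: Optional[np.ndarray] = None,
                flat: Optional[np.ndarray] = None,
                solidangle: bool = False,
                polarization_factor: Optional[float] = None,
                mask: Optional[np.ndarray] = None,
                dummy: Optional[float] = None,
                delta_dummy: float = 0.0) -> np.ndarray:
    """Per-pixel corrected signal (img - dark) / (flat * Omega * P).

    Masked / dummy / non-finite pixels are set to 0 in the output.
    """
    img = np.asarray(img, dtype=np.float64)
    for name, arr in (("dark", dark), ("flat", flat), ("mask", mask)):
        if arr is not None and np.shape(arr) != img.shape:
            raise ValueError(f"{name} shape {np.shape(arr)} != image shape {img.shape}")
    m = _effective_mask(geom, img, mask, dummy, delta_dummy)
    signal = img.copy()
    if dark is not None:
        signal = signal - np.asarray(dark, dtype=np.float64)
    denom = np.ones_like(signal)
    if flat is not None:
        flat = np.asarray(flat, dtype=np.float64)
        if np.any((flat == 0) & ~m):
            raise ValueError("flat field contains zeros on unmasked pixels")
        denom = denom * flat
    if solidangle:
        denom = denom * solid_angle_map(geom)
    if polarization_factor is not None:
        denom = denom * polarization_map(geom, polarization_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        signal = signal / denom
    signal[m] = 0.0
    return signal


# ---------------------------------------------------------------------------
# per-pixel fraction reference operations
# ---------------------------------------------------------------------------

def _grid_for_pixel(grid: BinGrid):
    rlo, dr, nr, alo, da, na, wrap = grid._kernel_params()
    return rlo, dr, nr, alo, da, na, wrap


def bbox_fractions(corner_radial, corner_azim, grid: BinGrid) -> np.ndarray:
    """Bounding-box fractions of one pixel over the grid.

    Returns a dense array of shape ``(npt_rad,)`` (1-D grid) or
    ``(npt_rad, npt_azim)``.
    """
    return _single_pixel_fractions(1, corner_radial, corner_azim, grid)


def polygon_fractions(corner_radial, corner_azim, grid: BinGrid) -> np.ndarray:
    """Full polygon-clipping fractions of one pixel quadrilateral.

    Rejects self-intersecting quadrilaterals.
    """
    cr = np.asarray(corner_radial, dtype=np.float64)
    ca = np.asarray(corner_azim, dtype=np.float64)
    if _quad_self_intersects(cr, ca):
        raise ValueError("self-intersecting pixel quadrilateral")
    return _single_pixel_fractions(2, cr, ca, grid)


def _single_pixel_fractions(scheme: int, cr, ca, grid: BinGrid) -> np.ndarray:
    cr = np.ascontiguousarray(cr, dtype=np.float64).reshape(4)
    ca = np.ascontiguousarray(ca, dtype=np.float64).reshape(4)
    rlo, dr, nr, alo, da, na, wrap = grid._kernel_params()
    nbins = nr * max(na, 1)
    sb = np.empty(max(nbins, 16), np.int64)
    sc = np.empty(max(nbins, 16), np.float64)
    m = _kernels._emit_pixel(scheme, cr, ca, float(cr.mean()), float(ca.mean()),
                             rlo, dr, nr, alo, da, na, wrap, sb, sc)
    if m < 0:
        sb = np.empty(-m + 16, np.int64)
        sc = np.empty(-m + 16, np.float64)
        m = _kernels._emit_pixel(scheme, cr, ca, float(cr.mean()), float(ca.mean()),
                                 rlo, dr, nr, alo, da, na, wrap, sb, sc)
    out = np.zeros(nbins, dtype=np.float64)
    np.add.at(out, sb[:m], sc[:m])
    if na:
        return out.reshape(nr, na)
    return out


def _quad_self_intersects(cr: np.ndarray, ca: np.ndarray) -> bool:
    pts = np.stack([cr, ca], axis=1)

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def seg_cross(p, q, a, b):
        d1 = cross2(q - p, a - p)
        d2 = cross2(q - p, b - p)
        d3 = cross2(b - a, p - a)
        d4 = cross2(b - a, q - a)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    # opposite edges (0-1 vs 2-3) and (1-2 vs 3-0)
    return (seg_cross(pts[0], pts[1], pts[2], pts[3])
            or seg_cross(pts[1], pts[2], pts[3], pts[0]))


# ---------------------------------------------------------------------------
# rebinner / integration
# ---------------------------------------------------------------------------

def build_rebinner(geom: Geometry, grid: BinGrid, scheme: str = "bbox",
                   mask: Optional[np.ndarray] = None) -> Rebinner:
    """Precompute the CSR pixel->bin coefficient matrix."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; known: {sorted(SCHEMES)}")
    if grid.npt_rad < 1:
        raise ValueError("empty bin grid")
    m = _effective_mask(geom, None, mask, None, 0.0).reshape(-1)
    cr, ca, rc, ac = _pixel_coordinates(geom, grid.unit, scheme)
    rlo, dr, nr, alo, da, na, wrap = grid._kernel_params()
    pix, bins, coefs = _kernels.build_coo(
        SCHEMES[scheme], cr, ca, rc, ac, m, rlo, dr, nr, alo, da, na, wrap)
    nbins = nr * max(na, 1)
    csr = sp.csr_matrix((coefs, (bins, pix)), shape=(nbins, rc.size))
    return Rebinner(csr=csr, scheme=scheme, grid=grid, mask=m,
                    fingerprint=_geometry_fingerprint(geom))


def propagate_errors(signal: np.ndarray, rebinner: Rebinner, model: str,
                     raw_img: Optional[np.ndarray] = None,
                     variance: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-bin sigma for a precomputed rebinner (CSR path)."""
    _check_error_model(model, variance)
    a = rebinner.csr
    signal = np.asarray(signal, dtype=np.float64).reshape(-1)
    sum_w = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        if model in ("poisson", "variance"):
            var = _pixel_variance(model, raw_img, variance, signal.size)
            a2 = a.multiply(a)
            sig2 = np.asarray(a2 @ var).ravel() / sum_w ** 2
        else:  # azimuthal
            mean = np.asarray(a @ signal).ravel() / sum_w
            mean = np.where(sum_w > 0, mean, 0.0)
            dev2 = _kernels.csr_spread(a.indptr, a.indices, a.data, signal, mean)
            sum_c2 = np.asarray(a.multiply(a).sum(axis=1)).ravel()
            n_eff = sum_w ** 2 / sum_c2
            sig2 = (dev2 / sum_w) / n_eff
    sig2 = np.where(sum_w > 0, sig2, np.nan)
    return np.sqrt(np.maximum(sig2, 0.0))


def _check_error_model(model: str, variance) -> None:
    if model not in ERROR_MODELS:
        raise ValueError(f"unknown error model {model!r}; known: {ERROR_MODELS}")
    if model == "variance" and variance is None:
        raise ValueError("error model 'variance' requires a variance array")


def _pixel_variance(model: str, raw_img, variance, npix: int) -> np.ndarray:
    if model == "variance":
        return np.asarray(variance, dtype=np.float64).reshape(npix)
    raw = np.asarray(raw_img, dtype=np.float64).reshape(npix)
    if np.any(raw < 0):
        warnings.warn("negative raw values clipped at 0 for Poisson variance")
    return np.maximum(raw, 0.0)


def _integrate(img: np.ndarray, geom: Geometry, grid: BinGrid, scheme: str,
               method: str, error_model: str,
               dark, flat, solidangle, polarization_factor, mask, dummy,
               delta_dummy, variance):
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; known: {sorted(SCHEMES)}")
    if method not in ("direct", "csr"):
        raise ValueError(f"method must be 'direct' or 'csr', got {method!r}")
    _check_error_model(error_model, variance)
    img = np.asarray(img, dtype=np.float64)
    m = _effective_mask(geom, img, mask, dummy, delta_dummy)
    if m.all():
        raise ValueError("all pixels are masked")
    signal = corrections(img, geom, dark=dark, flat=flat, solidangle=solidangle,
                         polarization_factor=polarization_factor, mask=mask,
                         dummy=dummy, delta_dummy=delta_dummy).reshape(-1)
    mflat = m.reshape(-1)
    var = np.zeros_like(signal)
    if error_model in ("poisson", "variance"):
        var = _pixel_variance(error_model, img, variance, signal.size)

    rlo, dr, nr, alo, da, na, wrap = grid._kernel_params()
    nbins = nr * max(na, 1)
    if method == "csr":
        reb = build_rebinner(geom, grid, scheme, mask=m)
        a = reb.csr
        sum_w = np.asarray(a.sum(axis=1)).ravel()
        sum_wi = np.asarray(a @ signal).ravel()
        count = np.asarray((a > 0).sum(axis=1)).ravel()
        sigma = None
        if error_model != "none":
            sigma = propagate_errors(signal, reb, error_model,
                                     raw_img=img, variance=variance)
    else:
        cr, ca, rc, ac = _pixel_coordinates(geom, grid.unit, scheme)
        sum_w, sum_wi, sum_c2, sum_c2v, count = _kernels.direct_accumulate(
            SCHEMES[scheme], signal, var, cr, ca, rc, ac, mflat,
            rlo, dr, nr, alo, da, na, wrap)
        sigma = None
        with np.errstate(divide="ignore", invalid="ignore"):
            if error_model in ("poisson", "variance"):
                sig2 = sum_c2v / sum_w ** 2
                sigma = np.sqrt(np.maximum(np.where(sum_w > 0, sig2, np.nan), 0.0))
            elif error_model == "azimuthal":
                mean = np.where(sum_w > 0, sum_wi / sum_w, 0.0)
                dev2 = _kernels.direct_spread(
                    SCHEMES[scheme], signal, mean, cr, ca, rc, ac, mflat,
                    rlo, dr, nr, alo, da, na, wrap)
                n_eff = sum_w ** 2 / sum_c2
                sig2 = (dev2 / sum_w) / n_eff
                sigma = np.sqrt(np.maximum(np.where(sum_w > 0, sig2, np.nan), 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = np.where(sum_w > 0, sum_wi / sum_w, np.nan)
    return intensity, sigma, sum_w, count, nbins


def integrate1d(img: np.ndarray, geom: Geometry, npt: int = 1000,
                unit: str = "2th_deg", scheme: str = "bbox",
                method: str = "csr",
                dark: Optional[np.ndarray] = None,
                flat: Optional[np.ndarray] = None,
                solidangle: bool = False,
                polarization_factor: Optional[float] = None,
                mask: Optional[np.ndarray] = None,
                dummy: Optional[float] = None,
                delta_dummy: float = 0.0,
                error_model: str = "none",
                variance: Optional[np.ndarray] = None,
                radial_range: Optional[Tuple[float, float]] = None,
                grid: Optional[BinGrid] = None) -> IntegrationResult:
    """Azimuthally integrate an image into ``npt`` radial bins."""
    m = _effective_mask(geom, img, mask, dummy, delta_dummy)
    if m.all():
        raise ValueError("all pixels are masked")
    if grid is None:
        grid = _default_grid(geom, unit, scheme, npt, 0, m, radial_range)
    intensity, sigma, weight, count, _ = _integrate(
        img, geom, grid, scheme, method, error_model, dark, flat, solidangle,
        polarization_factor, mask, dummy, delta_dummy, variance)
    return IntegrationResult(radial=grid.radial_centers, intensity=intensity,
                             sigma=sigma, weight=weight, count=count,
                             unit=grid.unit, grid=grid)


def integrate2d(img: np.ndarray, geom: Geometry, npt_rad: int = 1000,
                npt_azim: int = 360, unit: str = "2th_deg",
                scheme: str = "bbox", method: str = "csr",
                dark: Optional[np.ndarray] = None,
                flat: Optional[np.ndarray] = None,
                solidangle: bool = False,
                polarization_factor: Optional[float] = None,
                mask: Optional[np.ndarray] = None,
                dummy: Optional[float] = None,
                delta_dummy: float = 0.0,
                error_model: str = "none",
                variance: Optional[np.ndarray] = None,
                radial_range: Optional[Tuple[float, float]] = None,
                grid: Optional[BinGrid] = None) -> IntegrationResult:
    """2-D integration: (radial x azimuth) map.

    Output arrays have shape ``(npt_azim, npt_rad)`` (azimuth along rows).
    """
    m = _effective_mask(geom, img, mask, dummy, delta_dummy)
    if m.all():
        raise ValueError("all pixels are masked")
    if grid is None:
        grid = _default_grid(geom, unit, scheme, npt_rad, npt_azim, m,
                             radial_range)
    intensity, sigma, weight, count, _ = _integrate(
        img, geom, grid, scheme, method, error_model, dark, flat, solidangle,
        polarization_factor, mask, dummy, delta_dummy, variance)
    nr, na = grid.npt_rad, grid.npt_azim
    reshape = lambda v: None if v is None else v.reshape(nr, na).T
    return IntegrationResult(radial=grid.radial_centers,
                             azimuthal=grid.azim_centers,
                             intensity=reshape(intensity),
                             sigma=reshape(sigma),
                             weight=reshape(weight), count=reshape(count),
                             unit=grid.unit, grid=grid)
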
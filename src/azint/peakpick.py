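"""Control-point extraction from ring images.

Three stages, usable independently:

* :func:`massif_extract` — segments the image into "massifs": connected
  regions where the image exceeds a Gaussian-blurred version of itself.
  Local maxima sampled within one region belong to the same ring.
* :func:`refine_subpixel` — second-order Taylor refinement of a local
  maximum on its 3x3 neighbourhood (``delta = -H^-1 g``), falling back to
  the intensity-weighted centre of mass when the step exceeds one pixel or
  the Hessian is singular.
* :func:`blob_detect` — difference-of-Gaussians scale-space maxima with a
  factor-2 Gaussian pyramid; position, scale and intensity refined by the
  3-D analogue of the Taylor step.  Peaks narrower than ~3 px FWHM fall
  below the detection floor (the scale series starts at sigma = 1 and only
  interior scale levels can host a maximum).

:func:`extract_for_rings` combines blob detection with an approximate
geometry and a calibrant to produce ring-labelled control points for the
least-squares geometry refinement.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .calibrant import Calibrant, ring_angles
from .geometry import Geometry, angles_of_points

logger = logging.getLogger(__name__)

__all__ = ["PeakNeighborhood", "ControlPointSet", "ScaleSpace",
           "massif_extract", "refine_subpixel", "blob_detect",
           "extract_for_rings"]

#: scale-series ratio (geometric, brackets 1 and 2)
SCALE_RATIO = math.sqrt(2.0)
#: per-octave absolute blur widths: 1, sqrt2, 2, 2 sqrt2, 4
OCTAVE_SIGMAS = tuple(2.0 ** (k / 2.0) for k in range(5))
#: Gaussian kernels truncated at +-4 sigma
KERNEL_TRUNCATE = 4.0


@dataclasses.dataclass
class PeakNeighborhood:
    """3x3 neighbourhood of a local maximum with its Taylor refinement."""

    I: np.ndarray          # 3x3 patch
    g: np.ndarray          # gradient at the centre (central differences)
    H: np.ndarray          # Hessian at the centre
    x_max: np.ndarray      # integer position (y, x)
    delta: np.ndarray      # subpixel displacement x_opt - x_max

    @classmethod
    def from_image(cls, img: np.ndarray, x_max) -> "PeakNeighborhood":
        y, x = int(x_max[0]), int(x_max[1])
        if not (1 <= y < img.shape[0] - 1 and 1 <= x < img.shape[1] - 1):
            raise ValueError(f"peak at ({y}, {x}) touches the image border")
        p = np.asarray(img[y - 1:y + 2, x - 1:x + 2], dtype=np.float64)
        g = np.array([(p[2, 1] - p[0, 1]) / 2.0,
                      (p[1, 2] - p[1, 0]) / 2.0])
        hyy = p[2, 1] - 2.0 * p[1, 1] + p[0, 1]
        hxx = p[1, 2] - 2.0 * p[1, 1] + p[1, 0]
        hyx = (p[2, 2] - p[2, 0] - p[0, 2] + p[0, 0]) / 4.0
        H = np.array([[hyy, hyx], [hyx, hxx]])
        delta = _taylor_or_centroid(p, g, H)
        return cls(I=p, g=g, H=H, x_max=np.array([y, x]), delta=delta)


def _patch_centroid(patch: np.ndarray) -> np.ndarray:
    """Intensity-weighted centre of mass of a (3,)*ndim patch, as an offset
    from the centre; zero when the patch has no positive weight."""
    w = np.maximum(patch, 0.0)
    total = w.sum()
    if total <= 0:
        return np.zeros(patch.ndim)
    off = np.meshgrid(*[np.arange(-1.0, 2.0)] * patch.ndim, indexing="ij")
    return np.array([(w * o).sum() / total for o in off])


def _taylor_or_centroid(patch: np.ndarray, g: np.ndarray,
                        H: np.ndarray) -> np.ndarray:
    try:
        delta = -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        return _patch_centroid(patch)
    if np.any(np.abs(delta) > 1.0) or not np.all(np.isfinite(delta)):
        return _patch_centroid(patch)
    return delta


def refine_subpixel(img: np.ndarray, x_max) -> np.ndarray:
    """Subpixel position of a local maximum: ``x_max - H^-1 g`` with
    central-difference derivatives on the 3x3 patch; centre-of-mass
    fallback when the Taylor step exceeds one pixel."""
    nb = PeakNeighborhood.from_image(img, x_max)
    return nb.x_max + nb.delta


# ---------------------------------------------------------------------------
# massif extraction
# ---------------------------------------------------------------------------

def default_massif_sigma(shape: Tuple[int, int]) -> float:
    """Heuristic blur width: max(3, min(image dims) / 100) px."""
    return max(3.0, min(shape) / 100.0)


@dataclasses.dataclass
class MassifResult:
    labels: np.ndarray                       # region map, 0 = background
    n_regions: int
    peaks: List[Tuple[int, np.ndarray]]      # (region label, subpixel (y, x))


def _fill_masked(img: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        return np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("all pixels are masked")
    out = np.asarray(img, dtype=np.float64).copy()
    out[mask] = np.median(out[~mask])
    return out


def massif_extract(img: np.ndarray, sigma: Optional[float] = None,
                   mask: Optional[np.ndarray] = None) -> MassifResult:
    """Segment ring regions and collect their refined local maxima.

    Regions are connected components of ``img - blur(img, sigma) > 0``
    restricted to unmasked pixels; within each region every strict 3x3
    local maximum is refined by :func:`refine_subpixel`.
    """
    if sigma is None:
        sigma = default_massif_sigma(img.shape)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    work = _fill_masked(img, mask)
    blurred = ndimage.gaussian_filter(work, sigma, mode="reflect",
                                      truncate=KERNEL_TRUNCATE)
    positive = work - blurred > 0
    if mask is not None:
        positive &= ~np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(positive)
    peaks: List[Tuple[int, np.ndarray]] = []
    for y, x in _local_maxima(work, positive):
        pos = refine_subpixel(work, (y, x))
        peaks.append((int(labels[y, x]), pos))
    return MassifResult(labels=labels, n_regions=n, peaks=peaks)


def _local_maxima(img: np.ndarray, where: np.ndarray) -> np.ndarray:
    """Strict interior 3x3 local maxima inside ``where``; plateaus keep
    only their lexicographically smallest pixel."""
    maxf = ndimage.maximum_filter(img, size=3, mode="reflect")
    cand = (img == maxf) & where
    cand[0, :] = cand[-1, :] = False
    cand[:, 0] = cand[:, -1] = False
    if not cand.any():
        return np.empty((0, 2), dtype=np.int64)
    # collapse plateaus of equal value: one representative per component
    lab, n = ndimage.label(cand)
    out = []
    for sl, idx in zip(ndimage.find_objects(lab), range(1, n + 1)):
        ys, xs = np.nonzero(lab[sl] == idx)
        k = np.lexsort((xs, ys))[0]
        out.append((ys[k] + sl[0].start, xs[k] + sl[1].start))
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# blob detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Octave:
    base_sigma: float            # absolute sigma of level 0 in original px
    factor: int                  # downsampling factor vs the original image
    sigmas: np.ndarray           # absolute level sigmas in octave pixels
    dogs: np.ndarray             # (nlevels - 1, H, W), finer minus coarser


@dataclasses.dataclass
class ScaleSpace:
    octaves: List[Octave]

    @property
    def sigmas(self) -> np.ndarray:
        """All absolute blur widths (original-image pixels), ascending."""
        out = []
        for o in self.octaves:
            out.extend(o.sigmas * o.factor)
        return np.unique(np.round(np.array(out), 12))


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    v = img[:h, :w]
    return 0.25 * (v[0::2, 0::2] + v[1::2, 0::2] + v[0::2, 1::2] + v[1::2, 1::2])


def build_scale_space(img: np.ndarray, min_size: int = 16) -> ScaleSpace:
    """Gaussian pyramid of DoG stacks.

    Each octave blurs at sigmas 1, sqrt2, 2, 2 sqrt2, 4 (separable real-space
    kernels, reflect boundaries) and stores DoG = finer - coarser so bright
    blobs are maxima; the level blurred at sigma = 2 is binned 2x2 to seed
    the next octave.
    """
    img = np.asarray(img, dtype=np.float64)
    octaves: List[Octave] = []
    current = img
    factor = 1
    while min(current.shape) >= min_size:
        blurs = [ndimage.gaussian_filter(current, s, mode="reflect",
                                         truncate=KERNEL_TRUNCATE)
                 for s in OCTAVE_SIGMAS]
        dogs = np.stack([blurs[k] - blurs[k + 1]
                         for k in range(len(blurs) - 1)])
        octaves.append(Octave(base_sigma=factor * OCTAVE_SIGMAS[0],
                              factor=factor,
                              sigmas=np.array(OCTAVE_SIGMAS), dogs=dogs))
        current = _downsample2(blurs[2])     # sigma 2 -> 1 after binning
        factor *= 2
    if not octaves:
        raise ValueError(f"image smaller than the minimum kernel support ({min_size} px)")
    return ScaleSpace(octaves)


def _refine_3d(dogs: np.ndarray, k: int, y: int, x: int):
    """Taylor refinement over (scale, y, x); centroid fallback as in 2-D."""
    p = dogs[k - 1:k + 2, y - 1:y + 2, x - 1:x + 2].astype(np.float64)
    g = 0.5 * np.array([p[2, 1, 1] - p[0, 1, 1],
                        p[1, 2, 1] - p[1, 0, 1],
                        p[1, 1, 2] - p[1, 1, 0]])
    c = p[1, 1, 1]
    H = np.empty((3, 3))
    H[0, 0] = p[2, 1, 1] - 2 * c + p[0, 1, 1]
    H[1, 1] = p[1, 2, 1] - 2 * c + p[1, 0, 1]
    H[2, 2] = p[1, 1, 2] - 2 * c + p[1, 1, 0]
    H[0, 1] = H[1, 0] = 0.25 * (p[2, 2, 1] - p[2, 0, 1] - p[0, 2, 1] + p[0, 0, 1])
    H[0, 2] = H[2, 0] = 0.25 * (p[2, 1, 2] - p[2, 1, 0] - p[0, 1, 2] + p[0, 1, 0])
    H[1, 2] = H[2, 1] = 0.25 * (p[1, 2, 2] - p[1, 2, 0] - p[1, 0, 2] + p[1, 0, 0])
    delta = _taylor_or_centroid(p, g, H)
    value = c + 0.5 * float(g @ delta)
    return delta, value


def blob_detect(img: np.ndarray, mask: Optional[np.ndarray] = None
                ) -> np.ndarray:
    """DoG scale-space keypoints.

    Returns an ``(n, 4)`` array of ``(y, x, sigma, intensity)`` with
    subpixel positions in original-image pixel coordinates and the refined
    blob scale (absolute sigma, original pixels).  Peaks narrower than
    ~3 px FWHM are below the detection floor.
    """
    work = _fill_masked(img, mask)
    space = build_scale_space(work)
    near_mask = None
    if mask is not None:
        near_mask = ndimage.binary_dilation(np.asarray(mask, dtype=bool),
                                            iterations=2)
    found: List[Tuple[float, float, float, float]] = []
    for octave in space.octaves:
        dogs = octave.dogs
        interior = dogs[1:-1]
        maxf = ndimage.maximum_filter(dogs, size=3, mode="reflect")[1:-1]
        cand = (interior == maxf) & (interior > 0)
        cand[:, :1, :] = cand[:, -1:, :] = False
        cand[:, :, :1] = cand[:, :, -1:] = False
        for kk, y, x in zip(*np.nonzero(cand)):
            k = kk + 1
            # strictness against equal neighbours (plateaus)
            patch = dogs[k - 1:k + 2, y - 1:y + 2, x - 1:x + 2]
            if np.count_nonzero(patch == dogs[k, y, x]) > 1:
                continue
            delta, value = _refine_3d(dogs, k, y, x)
            sigma_o = octave.sigmas[k] * (SCALE_RATIO ** delta[0])
            yy = (y + delta[1] + 0.5) * octave.factor - 0.5
            xx = (x + delta[2] + 0.5) * octave.factor - 0.5
            if not (0 <= yy < img.shape[0] and 0 <= xx < img.shape[1]):
                continue
            if near_mask is not None and near_mask[
                    min(int(round(yy)), img.shape[0] - 1),
                    min(int(round(xx)), img.shape[1] - 1)]:
                continue
            found.append((yy, xx, sigma_o * octave.factor, value))
    if not found:
        return np.empty((0, 4))
    return _deduplicate(np.array(found, dtype=np.float64))


def _deduplicate(kps: np.ndarray, radius: float = 2.0) -> np.ndarray:
    """Collapse keypoints closer than ``radius`` px (adjacent scale levels
    and octave overlaps respond to the same blob); strongest DoG wins."""
    order = np.argsort(kps[:, 3])[::-1]
    cells: dict = {}
    kept: List[int] = []
    r2 = radius * radius
    for i in order:
        y, x = kps[i, 0], kps[i, 1]
        cy, cx = int(y // radius), int(x // radius)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for j in cells.get((cy + dy, cx + dx), ()):
                    if (y - kps[j, 0]) ** 2 + (x - kps[j, 1]) ** 2 < r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(i)
            cells.setdefault((cy, cx), []).append(i)
    return kps[np.sort(np.array(kept, dtype=np.int64))]


# ---------------------------------------------------------------------------
# ring assignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ControlPointSet:
    """Ring-labelled subpixel peak positions."""

    groups: List[Tuple[int, np.ndarray]]   # (ring index, (n, 2) array of (y, x))
    shape: Tuple[int, int]

    @property
    def n_points(self) -> int:
        return sum(pts.shape[0] for _, pts in self.groups)

    def all_points(self) -> Tuple[np.ndarray, np.ndarray]:
        """Concatenated (ring_indices, positions)."""
        rings = np.concatenate([np.full(pts.shape[0], n, dtype=np.int64)
                                for n, pts in self.groups])
        pos = np.concatenate([pts for _, pts in self.groups])
        return rings, pos

    def save(self, path) -> None:
        with open(path, "w") as f:
            f.write("# control points: ring_index y x (pixel-centre convention)\n")
            for n, pts in self.groups:
                for y, x in pts:
                    f.write(f"{n} {float(y)!r} {float(x)!r}\n")

    @classmethod
    def load(cls, path, shape=(0, 0)) -> "ControlPointSet":
        rows = []
        with open(path) as f:
            for raw in f:
                line = raw.split("#", 1)[0].strip()
                if line:
                    n, y, x = line.split()
                    rows.append((int(n), float(y), float(x)))
        groups = {}
        for n, y, x in rows:
            groups.setdefault(n, []).append((y, x))
        return cls(groups=[(n, np.array(v)) for n, v in sorted(groups.items())],
                   shape=tuple(shape))


def _points_tth(geom: Geometry, points: np.ndarray) -> np.ndarray:
    """2-theta at fractional pixel positions (pixel-centre convention),
    evaluated through the exact geometry transform."""
    det = geom.detector
    pos = np.zeros(points.shape[:-1] + (3,))
    pos[..., 0] = (points[..., 0] + 0.5) * det.pixel1
    pos[..., 1] = (points[..., 1] + 0.5) * det.pixel2
    return angles_of_points(geom, pos).tth


def extract_for_rings(img: np.ndarray, geom_approx: Geometry, cal: Calibrant,
                      tol_2th: float,
                      mask: Optional[np.ndarray] = None) -> ControlPointSet:
    """Blob-detect and assign keypoints to calibrant rings.

    A keypoint is kept when its 2-theta under the approximate geometry is
    within ``tol_2th`` (radians) of the nearest ring aperture.
    """
    rings = ring_angles(cal)
    kps = blob_detect(img, mask=mask)
    if kps.shape[0] == 0:
        raise ValueError("no keypoint detected in image")
    if kps.shape[0] >= 10:
        # drop scale outliers: responses at scales far from the median are
        # cluster/noise artefacts, not single-peak detections
        med = np.median(kps[:, 2])
        kps = kps[(kps[:, 2] > med / 3.0) & (kps[:, 2] < 2.5 * med)]
    tth = _points_tth(geom_approx, kps[:, :2])
    idx = np.searchsorted(rings, tth)
    idx = np.clip(idx, 0, rings.size - 1)
    idx_lo = np.clip(idx - 1, 0, rings.size - 1)
    nearer = np.where(np.abs(tth - rings[idx_lo]) < np.abs(tth - rings[idx]),
                      idx_lo, idx)
    keep = np.abs(tth - rings[nearer]) < tol_2th
    if not keep.any():
        raise ValueError("no keypoint assigned to any ring "
                         f"(tolerance {tol_2th} rad)")
    groups = []
    for n in np.unique(nearer[keep]):
        sel = keep & (nearer == n)
        groups.append((int(n), kps[sel, :2].copy()))
    return ControlPointSet(groups=groups, shape=img.shape)
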
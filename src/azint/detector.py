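"""Area-detector model: a field of pixel-corner coordinates.

A detector is described by its pixel grid (``shape``, ``pixel1``/``pixel2``
extents in metres along the slow and fast axes), an optional boolean mask
(``True`` = invalid pixel) and, for irregular layouts such as gapped
multi-module assemblies, an explicit rank-4 corner array of shape
``(Ny, Nx, 4, 3)`` giving every pixel-corner position in the detector frame.

Detector-frame conventions
--------------------------
* axis 1: slow/vertical direction (row index ``i``), coordinate ``c1``
* axis 2: fast/horizontal direction (column index ``j``), coordinate ``c2``
* axis 3: normal to the detector plane (0 for flat detectors)
* origin at the lower-left pixel corner as seen from the sample; all
  lengths in metres.
* corners of pixel ``(i, j)`` are stored counter-clockwise starting at the
  ``(i, j)`` corner: offsets ``(0,0), (0,1), (1,1), (1,0)`` in ``(di, dj)``.

The last axis of a corner array holds ``(c1, c2, c3)``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import h5py
import numpy as np

__all__ = [
    "Detector",
    "pixel_corners",
    "pixel_centers",
    "bin_detector",
    "save_hdf5",
    "load_hdf5",
    "two_module_detector",
]

#: corner offsets (di, dj), counter-clockwise starting at the (i, j) corner
CORNER_OFFSETS = np.array([(0, 0), (0, 1), (1, 1), (1, 0)], dtype=np.int64)

FORMAT_VERSION = "1.0"


@dataclasses.dataclass
class Detector:
    shape: Tuple[int, int]
    pixel1: float
    pixel2: float
    mask: Optional[np.ndarray] = None
    corners: Optional[np.ndarray] = None
    binning: Tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        ny, nx = self.shape
        if ny < 1 or nx < 1:
            raise ValueError(f"invalid detector shape {self.shape}")
        if self.pixel1 <= 0 or self.pixel2 <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != tuple(self.shape):
                raise ValueError(
                    f"mask shape {self.mask.shape} != detector shape {self.shape}"
                )
        if self.corners is not None:
            self.corners = np.ascontiguousarray(self.corners, dtype=np.float64)
            if self.corners.ndim != 4 or self.corners.shape[2] != 4 or self.corners.shape[3] != 3:
                raise ValueError(
                    f"corner array must have shape (Ny, Nx, 4, 3), got {self.corners.shape}"
                )
            if self.corners.shape[:2] != tuple(self.shape):
                raise ValueError(
                    f"corner array leading dims {self.corners.shape[:2]} != shape {self.shape}"
                )

    # conveniences used throughout the package ------------------------------
    @property
    def size(self) -> int:
        return self.shape[0] * self.shape[1]

    def pixel_corners(self) -> np.ndarray:
        return pixel_corners(self)

    def pixel_centers(self) -> np.ndarray:
        return pixel_centers(self)

    def bin(self, b1: int, b2: int) -> "Detector":
        return bin_detector(self, b1, b2)


def pixel_corners(det: Detector) -> np.ndarray:
    """Per-pixel corner coordinates, shape ``(Ny, Nx, 4, 3)`` in metres.

    Returns the explicit corner array when the detector carries one,
    otherwise the corners implied by the regular grid.
    """
    if det.corners is not None:
        return det.corners
    ny, nx = det.shape
    i = np.arange(ny, dtype=np.float64)
    j = np.arange(nx, dtype=np.float64)
    out = np.zeros((ny, nx, 4, 3), dtype=np.float64)
    for c, (di, dj) in enumerate(CORNER_OFFSETS):
        out[:, :, c, 0] = (i[:, None] + di) * det.pixel1
        out[:, :, c, 1] = (j[None, :] + dj) * det.pixel2
    return out


def pixel_centers(det: Detector) -> np.ndarray:
    """Per-pixel centre coordinates (mean of the 4 corners), ``(Ny, Nx, 3)``."""
    # exact mean of corners (bit-for-bit consistent with pixel_corners)
    return pixel_corners(det).mean(axis=2)


def bin_detector(det: Detector, b1: int, b2: int) -> Detector:
    """Merge ``b1 x b2`` blocks of pixels into super-pixels.

    The binned mask follows the conservative any-masked rule; explicit
    corner arrays keep the outer corner envelope of each block.  The PONI
    is expressed in metres, so no geometry change is required after binning.
    """
    ny, nx = det.shape
    if b1 < 1 or b2 < 1:
        raise ValueError("binning factors must be >= 1")
    if ny % b1 or nx % b2:
        raise ValueError(
            f"binning factors ({b1}, {b2}) do not divide detector shape ({ny}, {nx})"
        )
    if b1 == 1 and b2 == 1:
        return Detector(det.shape, det.pixel1, det.pixel2,
                        mask=det.mask.copy(),
                        corners=None if det.corners is None else det.corners.copy(),
                        binning=det.binning)
    my, mx = ny // b1, nx // b2
    mask = det.mask.reshape(my, b1, mx, b2).any(axis=(1, 3))
    corners = None
    if det.corners is not None:
        c = det.corners
        corners = np.empty((my, mx, 4, 3), dtype=np.float64)
        # outer envelope: take the matching extreme corner of each block
        corners[:, :, 0] = c[::b1, ::b2, 0]
        corners[:, :, 1] = c[::b1, b2 - 1::b2, 1]
        corners[:, :, 2] = c[b1 - 1::b1, b2 - 1::b2, 2]
        corners[:, :, 3] = c[b1 - 1::b1, ::b2, 3]
    return Detector((my, mx), det.pixel1 * b1, det.pixel2 * b2,
                    mask=mask, corners=corners,
                    binning=(det.binning[0] * b1, det.binning[1] * b2))


def save_hdf5(det: Detector, path) -> None:
    """Persist the detector to HDF5 (group ``detector``).

    Datasets: ``pixel_corners`` float64 (Ny, Nx, 4, 3) metres and ``mask``
    uint8 (Ny, Nx); attributes ``pixel1``, ``pixel2``, ``format_version``.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("detector")
        g.attrs["pixel1"] = float(det.pixel1)
        g.attrs["pixel2"] = float(det.pixel2)
        g.attrs["format_version"] = FORMAT_VERSION
        g.attrs["explicit_corners"] = bool(det.corners is not None)
        g.create_dataset("pixel_corners", data=pixel_corners(det))
        g.create_dataset("mask", data=det.mask.astype(np.uint8))


def load_hdf5(path) -> Detector:
    """Restore a detector written by :func:`save_hdf5`."""
    with h5py.File(path, "r") as f:
        if "detector" not in f:
            raise ValueError("missing group 'detector' in file")
        g = f["detector"]
        for name, rank in (("pixel_corners", 4), ("mask", 2)):
            if name not in g:
                raise ValueError(f"missing dataset '{name}' in detector file")
            if g[name].ndim != rank:
                raise ValueError(
                    f"dataset '{name}' has rank {g[name].ndim}, expected {rank}"
                )
        corners = np.asarray(g["pixel_corners"], dtype=np.float64)
        mask = np.asarray(g["mask"]).astype(bool)
        pixel1 = float(g.attrs["pixel1"])
        pixel2 = float(g.attrs["pixel2"])
        explicit = bool(g.attrs.get("explicit_corners", True))
    det = Detector(corners.shape[:2], pixel1, pixel2, mask=mask,
                   corners=corners if explicit else None)
    return det


def two_module_detector(module_shape: Tuple[int, int] = (32, 64),
                        gap: int = 3,
                        pixel1: float = 1e-4,
                        pixel2: float = 1e-4) -> Detector:
    """Gapped two-module fixture: two modules stacked along the slow axis
    separated by ``gap`` pixel rows of dead space (explicit corner array).
    """
    m1, nx = module_shape
    ny = 2 * m1
    shape = (ny, nx)
    i = np.arange(ny, dtype=np.float64)
    # physical row coordinate: second module shifted down-stream by the gap
    row0 = np.where(i >= m1, i + gap, i)
    j = np.arange(nx, dtype=np.float64)
    corners = np.zeros((ny, nx, 4, 3), dtype=np.float64)
    for c, (di, dj) in enumerate(CORNER_OFFSETS):
        corners[:, :, c, 0] = (row0[:, None] + di) * pixel1
        corners[:, :, c, 1] = (j[None, :] + dj) * pixel2
    return Detector(shape, pixel1, pixel2, corners=corners)


def quad_areas(corners: np.ndarray) -> np.ndarray:
    """Shoelace area of each pixel quadrilateral, shape ``(Ny, Nx)``.

    Uses the (c1, c2) in-plane coordinates; assumes simple quadrilaterals.
    """
    y = corners[..., 0]
    x = corners[..., 1]
    y2 = np.roll(y, -1, axis=-1)
    x2 = np.roll(x, -1, axis=-1)
    return 0.5 * np.abs(np.sum(x * y2 - x2 * y, axis=-1))
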
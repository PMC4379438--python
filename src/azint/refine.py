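"""Least-squares refinement of the detector geometry from control points.

The cost is the sum over all ring-labelled control points of the squared
difference between the model 2-theta at the (subpixel) point position and
the calibrant ring aperture.  Any subset of {dist, poni1, poni2, rot1,
rot2, rot3, wavelength} can be refined, the rest staying fixed; bounded
minimization uses a trust-region least-squares solver on the per-point
residual vector (a bounded quasi-Newton equivalent of sequential
least-squares programming on the summed cost).

Note: rot3 (the rotation about the beam axis) leaves every scattering
angle invariant, so it is unidentifiable from a 2-theta cost and is
excluded from the default free set; it can still be freed explicitly
(e.g. together with an azimuth-sensitive constraint added by the caller).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .calibrant import Calibrant, ring_angles
from .geometry import Geometry
from .peakpick import ControlPointSet, extract_for_rings, _points_tth

logger = logging.getLogger(__name__)

__all__ = ["RefinementProblem", "cost", "refine", "recalibrate",
           "PARAM_NAMES"]

PARAM_NAMES = ("dist", "poni1", "poni2", "rot1", "rot2", "rot3", "wavelength")

#: convergence: cost change below 1e-12 x initial or 500 iterations
FTOL_REL = 1e-12
MAX_ITER = 500


def _default_bounds(start: Geometry) -> Dict[str, Tuple[float, float]]:
    det = start.detector
    extent1 = det.shape[0] * det.pixel1
    extent2 = det.shape[1] * det.pixel2
    wl = start.wavelength or 1e-10
    return {
        "dist": (1e-6, 10.0),
        "poni1": (start.poni1 - extent1, start.poni1 + extent1),
        "poni2": (start.poni2 - extent2, start.poni2 + extent2),
        "rot1": (-np.pi / 2, np.pi / 2),
        "rot2": (-np.pi / 2, np.pi / 2),
        "rot3": (-np.pi / 2, np.pi / 2),
        "wavelength": (wl * 0.5, wl * 2.0),
    }


@dataclasses.dataclass
class RefinementProblem:
    points: ControlPointSet
    calibrant: Calibrant
    start: Geometry
    free: Sequence[str] = ("dist", "poni1", "poni2", "rot1", "rot2")
    bounds: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter set must not be empty")
        for name in self.free:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
        rings = ring_angles(self._calibrant_with_wavelength(self.start))
        ring_idx, _ = self.points.all_points()
        if ring_idx.max() >= rings.size:
            raise ValueError(
                f"control points reference ring {ring_idx.max()} but the "
                f"calibrant only has {rings.size} reachable rings")
        full = _default_bounds(self.start)
        if self.bounds:
            full.update(self.bounds)
        self.bounds = full

    def _calibrant_with_wavelength(self, geom: Geometry) -> Calibrant:
        wl = geom.wavelength or self.calibrant.wavelength
        if wl is None:
            raise ValueError("no wavelength available for the calibrant")
        return Calibrant(self.calibrant.name, self.calibrant.dspacing, wl)

    def geometry_for(self, params: Dict[str, float]) -> Geometry:
        kw = {k: params[k] for k in params if k != "wavelength"}
        geom = self.start.replace(**kw)
        if "wavelength" in params:
            geom = geom.replace(wavelength=params["wavelength"])
        return geom

    def residuals(self, params: Dict[str, float]) -> np.ndarray:
        geom = self.geometry_for(params)
        rings = ring_angles(self._calibrant_with_wavelength(geom))
        ring_idx, pos = self.points.all_points()
        tth = _points_tth(geom, pos)
        return tth - rings[ring_idx]


def cost(problem: RefinementProblem, params: Dict[str, float]) -> float:
    """Sum of squared 2-theta residuals over all control points."""
    r = problem.residuals(params)
    return float(np.dot(r, r))


def refine(problem: RefinementProblem):
    """Bounded least-squares refinement of the free parameters.

    Returns ``(geometry, final_cost, per_ring_stats)`` where the stats map
    each ring index to ``{"n", "rms", "max"}`` of its residuals (radians).
    The refined cost never exceeds the starting cost.
    """
    free = list(problem.free)
    n_points = problem.points.n_points
    if n_points < len(free):
        raise ValueError(
            f"under-determined: {n_points} control points for "
            f"{len(free)} free parameters")
    if "wavelength" in free:
        if len(problem.points.groups) < 2:
            raise ValueError(
                "refining the wavelength requires control points on at "
                "least 2 distinct rings (single-ring d/lambda degeneracy)")
        if problem.start.wavelength is None:
            raise ValueError("wavelength refinement requires a starting value")

    start_params = problem.start.param_dict()
    x0 = np.array([start_params[k] for k in free], dtype=np.float64)
    lo = np.array([problem.bounds[k][0] for k in free])
    hi = np.array([problem.bounds[k][1] for k in free])
    x0 = np.clip(x0, lo, hi)
    # scale columns so the solver sees O(1) parameters
    scales = np.array([max(abs(v), 1e-3) if k != "wavelength" else abs(v)
                       for k, v in zip(free, x0)])

    def fun(x):
        return problem.residuals(dict(zip(free, x)))

    c0 = float(np.dot(fun(x0), fun(x0)))
    res = least_squares(fun, x0, bounds=(lo, hi), x_scale=scales,
                        ftol=max(FTOL_REL, 1e-15), xtol=1e-15, gtol=1e-15,
                        max_nfev=MAX_ITER * max(len(free), 1))
    c1 = float(2 * res.cost)
    if c1 <= c0:
        x_best = res.x
    else:                      # never report a worse point than the start
        x_best, c1 = x0, c0
    logger.info("refine: cost %.3e -> %.3e (%s, %d points, status %d)",
                c0, c1, ",".join(free), n_points, res.status)
    best = dict(zip(free, x_best))
    geom = problem.geometry_for(best)
    r = problem.residuals(best)
    ring_idx, _ = problem.points.all_points()
    stats = {}
    for n in np.unique(ring_idx):
        rn = r[ring_idx == n]
        stats[int(n)] = {"n": int(rn.size),
                         "rms": float(np.sqrt(np.mean(rn ** 2))),
                         "max": float(np.max(np.abs(rn)))}
    return geom, c1, stats


def recalibrate(img: np.ndarray, geom_approx: Geometry, cal: Calibrant,
                tol_2th: float,
                mask: Optional[np.ndarray] = None,
                free: Sequence[str] = ("dist", "poni1", "poni2",
                                       "rot1", "rot2")):
    """Two-round recalibration: extract control points around the rings
    predicted by the approximate geometry, refine, re-extract with the
    tolerance halved, refine again.

    Returns ``(geometry, control_points)``.
    """
    cps = extract_for_rings(img, geom_approx, cal, tol_2th, mask=mask)
    geom, cost1, _ = refine(RefinementProblem(cps, cal, geom_approx, free=free))
    cps2 = extract_for_rings(img, geom, cal, tol_2th / 2.0, mask=mask)
    geom2, cost2, stats = refine(RefinementProblem(cps2, cal, geom, free=free))
    logger.info("recalibrate: round costs %.3e, %.3e (%d -> %d points)",
                cost1, cost2, cps.n_points, cps2.n_points)
    return geom2, cps2
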
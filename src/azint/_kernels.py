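"""Numba kernels for pixel-splitting coefficient generation.

Pixels are distributed over an output bin grid according to one of three
schemes:

* ``0`` — no splitting: full weight into the bin holding the pixel centre;
* ``1`` — bounding box: the pixel is abstracted by its axis-aligned box in
  (radial, azimuth) space and the weight is the separable product of
  overlap ratios;
* ``2`` — full polygon splitting: the pixel quadrilateral is clipped
  against each candidate bin rectangle (Sutherland-Hodgman) and the weight
  is the clipped-area ratio.

The same per-pixel emitter feeds two execution paths: a one-pass scatter
accumulation ("direct histogramming") and a COO list that Python-side code
wraps into a CSR sparse matrix ("gather"), which are algebraically
identical.

Bin assignment is half-open ``[lo, hi)`` except the last bin, which is
closed.  When the azimuthal grid spans the full circle (``wrap``), bin
indices past the ends wrap around modulo ``na``; corner azimuths are
pre-unwrapped to within pi of their circular mean by the caller.
"""

import math

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _point_bin(c, lo, w, n):
    """Index of the bin containing c, or -1 when outside the grid."""
    i = int(math.floor((c - lo) / w))
    if i == n and c <= lo + w * n:
        i = n - 1
    if i < 0 or i >= n:
        return -1
    return i


@njit(cache=True)
def _clip_axis(poly, n, axis, val, sign, out):
    """Clip polygon against the half-plane sign*(x[axis] - val) >= 0."""
    m = 0
    for k in range(n):
        kk = k + 1
        if kk == n:
            kk = 0
        c0 = sign * (poly[k, axis] - val)
        c1 = sign * (poly[kk, axis] - val)
        if c0 >= 0.0:
            out[m, 0] = poly[k, 0]
            out[m, 1] = poly[k, 1]
            m += 1
        if (c0 >= 0.0) != (c1 >= 0.0):
            t = c0 / (c0 - c1)
            out[m, 0] = poly[k, 0] + t * (poly[kk, 0] - poly[k, 0])
            out[m, 1] = poly[k, 1] + t * (poly[kk, 1] - poly[k, 1])
            m += 1
    return m


@njit(cache=True)
def _poly_area(poly, n):
    s = 0.0
    for k in range(n):
        kk = k + 1
        if kk == n:
            kk = 0
        s += poly[k, 0] * poly[kk, 1] - poly[kk, 0] * poly[k, 1]
    return 0.5 * abs(s)


@njit(cache=True)
def _quad_rect_area(quad, r0, r1, a0, a1, use_azim):
    """Area of quad intersected with [r0, r1] x [a0, a1] (radial axis 0)."""
    buf1 = np.empty((16, 2), np.float64)
    buf2 = np.empty((16, 2), np.float64)
    n = _clip_axis(quad, 4, 0, r0, 1.0, buf1)
    if n == 0:
        return 0.0
    n = _clip_axis(buf1, n, 0, r1, -1.0, buf2)
    if n == 0:
        return 0.0
    if not use_azim:
        return _poly_area(buf2, n)
    n = _clip_axis(buf2, n, 1, a0, 1.0, buf1)
    if n == 0:
        return 0.0
    n = _clip_axis(buf1, n, 1, a1, -1.0, buf2)
    if n == 0:
        return 0.0
    return _poly_area(buf2, n)



@njit(cache=True)
def _emit_point(rc, ac, rlo, dr, nr, alo, da, na, sb, sc):
    i = _point_bin(rc, rlo, dr, nr)
    if i < 0:
        return 0
    b = i
    if na > 0:
        j = _point_bin(ac, alo, da, na)
        if j < 0:
            return 0
        b = i * na + j
    if sb.size < 1:
        return -1
    sb[0] = b
    sc[0] = 1.0
    return 1


@njit(cache=True)
def _emit_pixel(scheme, cr, ca, rc, ac,
                rlo, dr, nr, alo, da, na, wrap,
                sb, sc):
    """Write (bin, coefficient) pairs for one pixel into sb/sc.

    Returns the number of entries, or -(needed scratch size) when the
    scratch buffers are too small.  ``cr``/``ca`` are the 4 corner radial /
    azimuthal coordinates; ``rc``/``ac`` the centre coordinates.
    """
    if scheme == 0:
        return _emit_point(rc, ac, rlo, dr, nr, alo, da, na, sb, sc)

    rmin = cr[0]
    rmax = cr[0]
    amin = ca[0]
    amax = ca[0]
    for k in range(1, 4):
        if cr[k] < rmin:
            rmin = cr[k]
        if cr[k] > rmax:
            rmax = cr[k]
        if ca[k] < amin:
            amin = ca[k]
        if ca[k] > amax:
            amax = ca[k]
    rwidth = rmax - rmin
    if rwidth < _EPS * max(abs(rmax), 1.0):
        # degenerate box: behave like a point
        return _emit_point(0.5 * (rmin + rmax), 0.5 * (amin + amax),
                           rlo, dr, nr, alo, da, na, sb, sc)
    rhi = rlo + dr * nr
    if rmax <= rlo or rmin >= rhi:
        return 0
    i0 = int(math.floor((rmin - rlo) / dr))
    i1 = int(math.floor((rmax - rlo) / dr))
    if i0 < 0:
        i0 = 0
    if i1 > nr - 1:
        i1 = nr - 1

    if na == 0:
        need = i1 - i0 + 1
        if need > sb.size:
            return -need
        m = 0
        if scheme == 1:
            for i in range(i0, i1 + 1):
                e0 = rlo + i * dr
                ov = min(rmax, e0 + dr) - max(rmin, e0)
                if ov > 0.0:
                    sb[m] = i
                    sc[m] = ov / rwidth
                    m += 1
        else:
            quad = np.empty((4, 2), np.float64)
            for k in range(4):
                quad[k, 0] = cr[k]
                quad[k, 1] = ca[k]
            area = _poly_area(quad, 4)
            if area < _EPS * rwidth * rwidth:
                return _emit_point(0.5 * (rmin + rmax), 0.5 * (amin + amax),
                                   rlo, dr, nr, alo, da, na, sb, sc)
            for i in range(i0, i1 + 1):
                e0 = rlo + i * dr
                a = _quad_rect_area(quad, e0, e0 + dr, 0.0, 0.0, False)
                if a > 0.0:
                    sb[m] = i
                    sc[m] = a / area
                    m += 1
        return m

    # 2-D grid ------------------------------------------------------------
    awidth = amax - amin
    degenerate_a = awidth < _EPS
    if wrap:
        j0 = int(math.floor((amin - alo) / da))
        j1 = int(math.floor((amax - alo) / da))
    else:
        ahi = alo + da * na
        if amax <= alo or amin >= ahi:
            return 0
        j0 = int(math.floor((amin - alo) / da))
        j1 = int(math.floor((amax - alo) / da))
        if j0 < 0:
            j0 = 0
        if j1 > na - 1:
            j1 = na - 1
    need = (i1 - i0 + 1) * (j1 - j0 + 1)
    if need > sb.size:
        return -need
    m = 0
    if scheme == 1:
        for i in range(i0, i1 + 1):
            e0 = rlo + i * dr
            ovr = min(rmax, e0 + dr) - max(rmin, e0)
            if ovr <= 0.0:
                continue
            fr = ovr / rwidth
            for j in range(j0, j1 + 1):
                f0 = alo + j * da
                if degenerate_a:
                    fa = 1.0 if (amin >= f0 and amin < f0 + da) else 0.0
                else:
                    ova = min(amax, f0 + da) - max(amin, f0)
                    fa = ova / awidth if ova > 0.0 else 0.0
                if fa > 0.0:
                    jj = j % na
                    if jj < 0:
                        jj += na
                    sb[m] = i * na + jj
                    sc[m] = fr * fa
                    m += 1
    else:
        quad = np.empty((4, 2), np.float64)
        for k in range(4):
            quad[k, 0] = cr[k]
            quad[k, 1] = ca[k]
        area = _poly_area(quad, 4)
        if area < _EPS * rwidth * rwidth:
            return _emit_point(0.5 * (rmin + rmax), 0.5 * (amin + amax),
                               rlo, dr, nr, alo, da, na, sb, sc)
        for i in range(i0, i1 + 1):
            e0 = rlo + i * dr
            for j in range(j0, j1 + 1):
                f0 = alo + j * da
                a = _quad_rect_area(quad, e0, e0 + dr, f0, f0 + da, True)
                if a > 0.0:
                    jj = j % na
                    if jj < 0:
                        jj += na
                    sb[m] = i * na + jj
                    sc[m] = a / area
                    m += 1
    return m


@njit(cache=True)
def build_coo(scheme, cr, ca, rc, ac, mask,
              rlo, dr, nr, alo, da, na, wrap):
    """COO triplet (pixel, bin, coefficient) for the whole detector."""
    npix = rc.size
    cap = npix * 4 + 16
    pix = np.empty(cap, np.int64)
    bins = np.empty(cap, np.int64)
    coefs = np.empty(cap, np.float64)
    sb = np.empty(1024, np.int64)
    sc = np.empty(1024, np.float64)
    nnz = 0
    for p in range(npix):
        if mask[p]:
            continue
        m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                        rlo, dr, nr, alo, da, na, wrap, sb, sc)
        if m < 0:
            sb = np.empty(-m + 16, np.int64)
            sc = np.empty(-m + 16, np.float64)
            m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                            rlo, dr, nr, alo, da, na, wrap, sb, sc)
        if nnz + m > cap:
            newcap = cap * 2 + m
            npx = np.empty(newcap, np.int64)
            nbn = np.empty(newcap, np.int64)
            ncf = np.empty(newcap, np.float64)
            npx[:nnz] = pix[:nnz]
            nbn[:nnz] = bins[:nnz]
            ncf[:nnz] = coefs[:nnz]
            pix, bins, coefs, cap = npx, nbn, ncf, newcap
        for k in range(m):
            pix[nnz] = p
            bins[nnz] = sb[k]
            coefs[nnz] = sc[k]
            nnz += 1
    return pix[:nnz], bins[:nnz], coefs[:nnz]


@njit(cache=True)
def direct_accumulate(scheme, signal, var, cr, ca, rc, ac, mask,
                      rlo, dr, nr, alo, da, na, wrap):
    """One-pass scatter accumulation (the 'direct histogram' path)."""
    nbins = nr * (na if na > 0 else 1)
    sum_w = np.zeros(nbins, np.float64)
    sum_wi = np.zeros(nbins, np.float64)
    sum_c2 = np.zeros(nbins, np.float64)
    sum_c2v = np.zeros(nbins, np.float64)
    count = np.zeros(nbins, np.int64)
    sb = np.empty(1024, np.int64)
    sc = np.empty(1024, np.float64)
    npix = rc.size
    for p in range(npix):
        if mask[p]:
            continue
        m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                        rlo, dr, nr, alo, da, na, wrap, sb, sc)
        if m < 0:
            sb = np.empty(-m + 16, np.int64)
            sc = np.empty(-m + 16, np.float64)
            m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                            rlo, dr, nr, alo, da, na, wrap, sb, sc)
        for k in range(m):
            b = sb[k]
            c = sc[k]
            sum_w[b] += c
            sum_wi[b] += c * signal[p]
            sum_c2[b] += c * c
            sum_c2v[b] += c * c * var[p]
            count[b] += 1
    return sum_w, sum_wi, sum_c2, sum_c2v, count


@njit(cache=True)
def direct_spread(scheme, signal, mean, cr, ca, rc, ac, mask,
                  rlo, dr, nr, alo, da, na, wrap):
    """Second scatter pass: weighted squared deviation from per-bin means."""
    nbins = nr * (na if na > 0 else 1)
    out = np.zeros(nbins, np.float64)
    sb = np.empty(1024, np.int64)
    sc = np.empty(1024, np.float64)
    npix = rc.size
    for p in range(npix):
        if mask[p]:
            continue
        m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                        rlo, dr, nr, alo, da, na, wrap, sb, sc)
        if m < 0:
            sb = np.empty(-m + 16, np.int64)
            sc = np.empty(-m + 16, np.float64)
            m = _emit_pixel(scheme, cr[p], ca[p], rc[p], ac[p],
                            rlo, dr, nr, alo, da, na, wrap, sb, sc)
        for k in range(m):
            b = sb[k]
            d = signal[p] - mean[b]
            out[b] += sc[k] * d * d
    return out


@njit(cache=True)
def csr_spread(indptr, indices, data, signal, mean):
    """Per-bin weighted squared deviation, gathered through CSR rows."""
    nbins = indptr.size - 1
    out = np.zeros(nbins, np.float64)
    for b in range(nbins):
        s = 0.0
        for k in range(indptr[b], indptr[b + 1]):
            d = signal[indices[k]] - mean[b]
            s += data[k] * d * d
        out[b] = s
    return out
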
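import numpy as np
import pytest

import azint as az
from azint.integrate import (BinGrid, polarization_map, solid_angle_map,
                             _default_grid)


@pytest.fixture(scope="module")
def rand_image(geom256):
    rng = np.random.default_rng(42)
    return rng.uniform(0, 100, geom256.detector.shape)


class TestCorrections:
    def test_dark_equals_image(self, geom256, rand_image):
        out = az.corrections(rand_image, geom256, dark=rand_image)
        assert np.all(out == 0.0)

    def test_solid_angle_unity_at_poni(self, geom256):
        omega = solid_angle_map(geom256)
        # pixel whose centre is closest to the PONI
        centers = az.pixel_centers(geom256.detector)
        d = np.hypot(centers[..., 0] - geom256.poni1,
                     centers[..., 1] - geom256.poni2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        assert omega[i, j] == pytest.approx(1.0, abs=1e-4)

    def test_solid_angle_cos_cubed_at_45deg(self):
        det = az.Detector((3, 3), 1e-4, 1e-4)
        g = az.Geometry(dist=1e-4, poni1=1.5e-4, poni2=1.5e-4, detector=det)
        # pixel centre offset dist along axis1 -> alpha = 45 deg
        from azint.geometry import lab_coordinates
        omega = solid_angle_map(g)
        assert omega[2, 1] == pytest.approx(np.cos(np.pi / 4) ** 3, rel=1e-12)
        assert omega[2, 1] == pytest.approx(0.35355339, abs=1e-6)

    def test_polarization_formula(self, geom256):
        f = 0.8
        p = polarization_map(geom256, f)
        ang = az.pixel_angles(geom256)
        expect = 0.5 * (1 + np.cos(ang.tth) ** 2
                        - f * np.cos(2 * ang.chi) * np.sin(ang.tth) ** 2)
        np.testing.assert_allclose(p, expect, atol=1e-12)

    def test_flat_with_zeros_rejected(self, geom256, rand_image):
        flat = np.ones_like(rand_image)
        flat[3, 4] = 0.0
        with pytest.raises(ValueError, match="flat"):
            az.corrections(rand_image, geom256, flat=flat)

    def test_dummy_pixels_zeroed(self, geom256):
        img = np.full(geom256.detector.shape, 5.0)
        img[10, 10] = -10.0
        out = az.corrections(img, geom256, dummy=-10.0)
        assert out[10, 10] == 0.0
        assert out[0, 0] == 5.0


def grid1d(lo, hi, n, unit="2th_rad"):
    return BinGrid(np.linspace(lo, hi, n + 1), unit=unit)


def grid2d(rlo, rhi, nr, na):
    return BinGrid(np.linspace(rlo, rhi, nr + 1),
                   np.linspace(-np.pi, np.pi, na + 1))


class TestBboxFractions:
    def test_inside_single_bin(self):
        g = grid1d(0.0, 10.0, 10)
        f = az.bbox_fractions([2.2, 2.2, 2.8, 2.8], [0.1, 0.2, 0.1, 0.2], g)
        assert f[2] == pytest.approx(1.0)
        assert f.sum() == pytest.approx(1.0)

    def test_straddle_half_half(self):
        g = grid1d(0.0, 10.0, 10)
        f = az.bbox_fractions([2.5, 2.5, 3.5, 3.5], [0.0, 0.1, 0.0, 0.1], g)
        assert f[2] == pytest.approx(0.5)
        assert f[3] == pytest.approx(0.5)

    def test_2d_separable_product(self):
        g = grid2d(0.0, 10.0, 10, 8)
        f = az.bbox_fractions([2.5, 2.5, 3.5, 3.5],
                              [0.1, 0.1, 0.5, 0.5], g)
        assert f.shape == (10, 8)
        assert f.sum() == pytest.approx(1.0)

    def test_random_boxes_vs_rasterization_oracle(self):
        rng = np.random.default_rng(3)
        g = grid2d(0.0, 1.0, 7, 9)
        for _ in range(25):
            r0, a0 = rng.uniform(0.1, 0.7), rng.uniform(-2.5, 1.5)
            dr, da = rng.uniform(0.02, 0.2), rng.uniform(0.02, 0.5)
            cr = np.array([r0, r0, r0 + dr, r0 + dr])
            ca = np.array([a0, a0 + da, a0, a0 + da])
            f = az.bbox_fractions(cr, ca, g)
            # dense rasterization oracle (1000x oversampling per axis)
            rr = np.linspace(r0, r0 + dr, 1000)
            aa = np.linspace(a0, a0 + da, 1000)
            hist, _, _ = np.histogram2d(
                np.repeat(rr, 1000), np.tile(aa, 1000),
                bins=[g.radial_edges, g.azim_edges])
            oracle = hist / 1e6
            assert np.max(np.abs(f - oracle)) < 2e-3


class TestPolygonFractions:
    def test_square_inside(self):
        g = grid2d(0.0, 10.0, 10, 4)
        f = az.polygon_fractions([2.1, 2.1, 2.9, 2.9],
                                 [0.1, 0.9, 0.9, 0.1], g)
        assert f.sum() == pytest.approx(1.0)
        assert f.max() == pytest.approx(1.0)

    def test_square_split_in_half(self):
        g = grid1d(0.0, 10.0, 10)
        f = az.polygon_fractions([2.5, 2.5, 3.5, 3.5],
                                 [0.0, 1.0, 1.0, 0.0], g)
        assert f[2] == pytest.approx(0.5)
        assert f[3] == pytest.approx(0.5)

    def test_rotated_square_quarters(self):
        # 45deg-rotated square centred on the crossing of a 2x2 grid
        g = BinGrid(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        s = 0.5
        f = az.polygon_fractions([1.0, 1.0 + s, 1.0, 1.0 - s],
                                 [1.0 - s, 1.0, 1.0 + s, 1.0], g)
        np.testing.assert_allclose(f, 0.25, atol=1e-12)

    def test_self_intersecting_rejected(self):
        g = grid1d(0.0, 10.0, 10)
        with pytest.raises(ValueError, match="self-intersecting"):
            az.polygon_fractions([0.0, 1.0, 0.0, 1.0],
                                 [0.0, 1.0, 1.0, 0.0], g)

    def test_random_quads_vs_monte_carlo(self):
        from matplotlib.path import Path
        rng = np.random.default_rng(11)
        g = grid2d(0.0, 1.0, 5, 6)
        nmc = 100_000
        for _ in range(100):
            # jittered rectangle: always a simple quadrilateral
            cy, cx = rng.uniform(0.2, 0.8), rng.uniform(-2.0, 2.0)
            hr, ha = rng.uniform(0.05, 0.2), rng.uniform(0.05, 0.3)
            jr = rng.uniform(-0.4, 0.4, 4) * hr
            ja = rng.uniform(-0.4, 0.4, 4) * ha
            cr = cy + np.array([-hr, -hr, hr, hr]) + jr
            ca = cx + np.array([-ha, ha, ha, -ha]) + ja
            f = az.polygon_fractions(cr, ca, g)
            poly = Path(np.column_stack([cr, ca]), closed=False)
            lo = [cr.min(), ca.min()]
            span = [cr.max() - cr.min(), ca.max() - ca.min()]
            pts = rng.uniform(0, 1, (nmc, 2)) * span + lo
            inside = poly.contains_points(pts)
            n_in = inside.sum()
            if n_in < 100:
                continue
            hist, _, _ = np.histogram2d(pts[inside, 0], pts[inside, 1],
                                        bins=[g.radial_edges, g.azim_edges])
            oracle = hist / n_in
            p = np.clip(oracle, 1e-9, 1)
            sigma = np.sqrt(p * (1 - p) / n_in)
            # fractions are of total quad area; MC is of in-grid area
            scale = f.sum()
            assert np.all(np.abs(f / max(scale, 1e-12) - oracle)
                          <= 3 * sigma + 3e-3)


class TestRebinner:
    def test_nosplit_single_unit_coefficient(self, geom256):
        g = _default_grid(geom256, "2th_rad", "nosplit", 100, 0,
                         geom256.detector.mask, None)
        reb = az.build_rebinner(geom256, g, "nosplit")
        colsum = np.asarray(reb.csr.sum(axis=0)).ravel()
        nnz_per_col = np.diff(reb.csr.tocsc().indptr)
        assert np.all(nnz_per_col == 1)
        np.testing.assert_allclose(colsum, 1.0)

    def test_masked_pixel_zero_row(self, lab6):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 12] = True
        det = az.Detector((64, 64), 1e-4, 1e-4, mask=mask)
        g = az.Geometry(dist=0.01, poni1=0.0032, poni2=0.0032,
                        wavelength=1e-10, detector=det)
        grid = _default_grid(g, "2th_rad", "bbox", 50, 0, mask, None)
        reb = az.build_rebinner(g, grid, "bbox")
        col = reb.csr.tocsc()[:, 10 * 64 + 12]
        assert col.nnz == 0

    @pytest.mark.parametrize("scheme", ["nosplit", "bbox", "fullsplit"])
    def test_coefficients_sum_to_one(self, geom256, scheme):
        grid = _default_grid(geom256, "2th_rad", scheme, 200, 0,
                            geom256.detector.mask, None)
        reb = az.build_rebinner(geom256, grid, scheme)
        colsum = np.asarray(reb.csr.sum(axis=0)).ravel()
        assert np.all(np.abs(colsum - 1.0) < 1e-9)
        if scheme != "nosplit":
            # global conservation
            assert abs(reb.csr.sum() - geom256.detector.size) \
                / geom256.detector.size < 1e-6

    def test_2d_wraparound_conservation(self, geom256):
        # full-circle azimuthal grid: pixels straddling +-pi still sum to 1
        for scheme in ("bbox", "fullsplit"):
            grid = _default_grid(geom256, "2th_rad", scheme, 60, 32,
                                geom256.detector.mask, None)
            reb = az.build_rebinner(geom256, grid, scheme)
            colsum = np.asarray(reb.csr.sum(axis=0)).ravel()
            assert np.all(np.abs(colsum - 1.0) < 1e-9), scheme

    def test_unknown_scheme(self, geom256):
        grid = grid1d(0.0, 0.5, 10)
        with pytest.raises(ValueError, match="scheme"):
            az.build_rebinner(geom256, grid, "magic")


class TestIntegrate1d:
    @pytest.mark.parametrize("scheme", ["nosplit", "bbox", "fullsplit"])
    @pytest.mark.parametrize("method", ["direct", "csr"])
    def test_constant_image(self, geom256, scheme, method):
        img = np.full(geom256.detector.shape, 3.25)
        res = az.integrate1d(img, geom256, npt=80, unit="2th_rad",
                             scheme=scheme, method=method)
        vals = res.intensity[res.weight > 0]
        np.testing.assert_allclose(vals, 3.25, rtol=1e-12)

    @pytest.mark.parametrize("scheme", ["nosplit", "bbox", "fullsplit"])
    def test_direct_equals_csr(self, geom256, rand_image, scheme):
        a = az.integrate1d(rand_image, geom256, npt=300, unit="2th_rad",
                           scheme=scheme, method="direct")
        b = az.integrate1d(rand_image, geom256, npt=300, unit="2th_rad",
                           scheme=scheme, method="csr")
        sel = b.weight > 0
        ref = np.abs(b.intensity[sel]).max()
        assert np.nanmax(np.abs(a.intensity[sel] - b.intensity[sel])) \
            < 1e-10 * ref

    def test_roundtrip_smooth_pattern(self, geom256):
        rng = np.random.default_rng(1)
        tth = np.linspace(0.001, 0.65, 3000)
        pat = np.full_like(tth, 20.0)
        for c, w, a in zip(rng.uniform(0.1, 0.6, 8),
                           rng.uniform(0.01, 0.05, 8),
                           rng.uniform(50, 200, 8)):
            pat += a * np.exp(-0.5 * ((tth - c) / w) ** 2)
        img = az.calcfrom1d(geom256, tth, pat, unit="2th_rad")
        res = az.integrate1d(img, geom256, npt=2000, unit="2th_rad",
                             scheme="fullsplit")
        expect = np.interp(res.radial, tth, pat)
        interior = slice(40, -40)
        rel = np.abs(res.intensity[interior] - expect[interior]) \
            / expect[interior]
        assert np.nanmax(rel) < 1e-2

    def test_scheme_consistency_coarse_bins(self, geom256):
        tth = np.linspace(0.001, 0.7, 2000)
        pat = 100 + 50 * np.sin(tth * 10) ** 2
        img = az.calcfrom1d(geom256, tth, pat, unit="2th_rad")
        out = {}
        for scheme in ("nosplit", "bbox", "fullsplit"):
            out[scheme] = az.integrate1d(img, geom256, npt=20,
                                         unit="2th_rad", scheme=scheme,
                                         radial_range=(0.05, 0.45)).intensity
        for a in ("nosplit", "bbox"):
            rel = np.nanmax(np.abs(out[a] - out["fullsplit"])
                            / np.abs(out["fullsplit"]))
            assert rel < 1e-3, a

    def test_masking_equals_deleted_coefficients(self, geom256, rand_image):
        mask = np.zeros(geom256.detector.shape, dtype=bool)
        mask[100:110, 120:130] = True
        grid = _default_grid(geom256, "2th_rad", "bbox", 100, 0, mask, None)
        a = az.build_rebinner(geom256, grid, "bbox", mask=mask)
        b = az.build_rebinner(geom256, grid, "bbox")
        keep = ~mask.reshape(-1)
        sig = rand_image.reshape(-1)
        lhs = a.csr @ sig
        rhs = b.csr.tocsc()[:, keep] @ sig[keep]
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_empty_bins_are_nan(self, geom256, rand_image):
        res = az.integrate1d(rand_image, geom256, npt=50, unit="2th_rad",
                             scheme="nosplit", radial_range=(0.0, 2.0))
        assert np.any(res.weight == 0)
        assert np.all(np.isnan(res.intensity[res.weight == 0]))

    def test_all_masked_rejected(self, geom256, rand_image):
        with pytest.raises(ValueError, match="masked"):
            az.integrate1d(rand_image, geom256,
                           mask=np.ones_like(rand_image, dtype=bool))

    def test_smoothness_ordering(self, geom256, lab6):
        img, _ = az.spotty_rings_image(lab6, geom256, 30, spot_sigma=1.5,
                                       seed=2)
        tv = {}
        for scheme in ("nosplit", "bbox", "fullsplit"):
            r = az.integrate1d(img, geom256, npt=400, unit="2th_rad",
                               scheme=scheme, radial_range=(0.05, 0.5))
            tv[scheme] = np.nansum(np.abs(np.diff(
                np.nan_to_num(r.intensity))))
        # splitting smooths; bbox and fullsplit are within a few % of
        # each other (see decisions ledger)
        assert tv["fullsplit"] <= 1.05 * tv["bbox"]
        assert tv["bbox"] <= 1.05 * tv["nosplit"]
        assert tv["fullsplit"] < tv["nosplit"]

    def test_q_unit_requires_wavelength(self, rand_image):
        det = az.Detector((256, 256), 1e-4, 1e-4)
        g = az.Geometry(dist=0.035, poni1=0.0128, poni2=0.0127, detector=det)
        with pytest.raises(ValueError, match="wavelength"):
            az.integrate1d(rand_image, g, unit="q_nm^-1")


class TestIntegrate2d:
    def test_isotropic_rows_constant(self, geom256):
        tth = np.linspace(0.001, 0.8, 2000)
        pat = 100 + 80 * np.exp(-0.5 * ((tth - 0.25) / 0.08) ** 2)
        img = az.calcfrom1d(geom256, tth, pat, unit="2th_rad")
        res = az.integrate2d(img, geom256, npt_rad=48, npt_azim=60,
                             unit="2th_rad", scheme="fullsplit",
                             radial_range=(0.12, 0.38))
        full = np.all(res.weight > 0.5, axis=0)
        sub = res.intensity[:, full]
        spread = (np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)) \
            / np.nanmean(sub, axis=0)
        assert np.max(spread) < 0.02

    @pytest.mark.parametrize("scheme", ["nosplit", "bbox", "fullsplit"])
    def test_chi_marginal_equals_1d(self, geom256, rand_image, scheme):
        rr = (0.05, 0.5)
        r2 = az.integrate2d(rand_image, geom256, npt_rad=120, npt_azim=90,
                            unit="2th_rad", scheme=scheme, radial_range=rr)
        r1 = az.integrate1d(rand_image, geom256, npt=120, unit="2th_rad",
                            scheme=scheme, radial_range=rr)
        w = np.nan_to_num(r2.weight)
        wi = np.nan_to_num(r2.intensity * r2.weight)
        with np.errstate(invalid="ignore"):
            marg = wi.sum(axis=0) / w.sum(axis=0)
        sel = r1.weight > 0
        ref = np.abs(r1.intensity[sel]).max()
        assert np.nanmax(np.abs(marg[sel] - r1.intensity[sel])) < 1e-10 * ref

    def test_half_plane_support(self, geom256):
        img = np.zeros(geom256.detector.shape)
        centers = az.pixel_centers(geom256.detector)
        upper = centers[..., 0] > geom256.poni1  # chi in (0, pi)
        img[upper] = 50.0
        res = az.integrate2d(img, geom256, npt_rad=40, npt_azim=36,
                             unit="2th_rad", scheme="nosplit",
                             radial_range=(0.05, 0.4))
        chi = res.azimuthal
        lower = chi < -0.1
        vals = np.nan_to_num(res.intensity[lower, :])
        assert np.all(vals == 0.0)


class TestErrorPropagation:
    def _grid(self, geom):
        return _default_grid(geom, "2th_rad", "nosplit", 60, 0,
                            geom.detector.mask, None)

    def test_single_pixel_sqrt_v(self):
        det = az.Detector((8, 8), 1e-4, 1e-4)
        g = az.Geometry(dist=0.01, poni1=4e-4, poni2=4e-4, detector=det)
        grid = BinGrid(np.array([0.0, 1.0]))  # one bin catches everything
        reb = az.build_rebinner(g, grid, "nosplit")
        var = np.full(64, 0.0)
        var[10] = 9.0
        # keep only pixel 10 contributing
        import scipy.sparse as sp
        keep = sp.csr_matrix(
            (np.array([1.0]), (np.array([0]), np.array([10]))),
            shape=reb.csr.shape)
        reb.csr = keep
        sigma = az.propagate_errors(np.zeros(64), reb, "variance",
                                    variance=var)
        assert sigma[0] == pytest.approx(3.0)

    def test_equal_pixels_sqrt_v_over_n(self, geom256):
        n_expected = geom256.detector.size
        grid = BinGrid(np.array([0.0, 10.0]))  # single bin, all pixels
        reb = az.build_rebinner(geom256, grid, "nosplit")
        v = 4.0
        img = np.full(geom256.detector.shape, v)  # Poisson: var = raw = 4
        res = az.integrate1d(img, geom256, npt=1, grid=grid,
                             scheme="nosplit", error_model="poisson")
        assert res.sigma[0] == pytest.approx(np.sqrt(v / n_expected))

    def test_azimuthal_zero_on_constant(self, geom256):
        img = np.full(geom256.detector.shape, 7.0)
        res = az.integrate1d(img, geom256, npt=50, unit="2th_rad",
                             scheme="bbox", error_model="azimuthal")
        sel = res.weight > 0
        assert np.all(res.sigma[sel] < 1e-8)

    @pytest.mark.parametrize("scheme", ["bbox", "fullsplit"])
    @pytest.mark.parametrize("model", ["poisson", "azimuthal"])
    def test_direct_equals_csr_sigma(self, geom256, rand_image, scheme,
                                     model):
        a = az.integrate1d(rand_image, geom256, npt=100, unit="2th_rad",
                           scheme=scheme, method="direct", error_model=model)
        b = az.integrate1d(rand_image, geom256, npt=100, unit="2th_rad",
                           scheme=scheme, method="csr", error_model=model)
        sel = b.weight > 0
        np.testing.assert_allclose(a.sigma[sel], b.sigma[sel],
                                   rtol=1e-8, atol=1e-12)

    def test_negative_raw_warns(self, geom256):
        img = np.full(geom256.detector.shape, -1.0)
        with pytest.warns(UserWarning, match="clipped"):
            az.integrate1d(img, geom256, npt=20, unit="2th_rad",
                           error_model="poisson")

    def test_variance_model_requires_array(self, geom256, rand_image):
        with pytest.raises(ValueError, match="variance"):
            az.integrate1d(rand_image, geom256, error_model="variance")


class TestOutputUnits:
    @pytest.mark.parametrize("unit", ["2th_deg", "q_nm^-1", "q_A^-1", "r_m"])
    def test_units_run(self, geom256, rand_image, unit):
        res = az.integrate1d(rand_image, geom256, npt=50, unit=unit)
        assert res.unit == unit
        assert np.all(np.diff(res.radial) > 0)

    def test_q_nm_vs_A(self, geom256, rand_image):
        a = az.integrate1d(rand_image, geom256, npt=50, unit="q_nm^-1")
        b = az.integrate1d(rand_image, geom256, npt=50, unit="q_A^-1")
        np.testing.assert_allclose(a.radial * 0.1, b.radial, rtol=1e-12)
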
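"""Phantom rendering, nodule specs and sinogram noise."""

import numpy as np
import pytest

import ctrecon as cr
from ctrecon.phantom import MM6TO30, SUB6MM


class TestSheppLogan:
    def test_center_pixel_is_sum_of_containing_ellipses(self):
        # At the origin only the outer ellipse (+2.0) and the big interior
        # ellipse (-0.98) contain the point (membership inequalities evaluated
        # by hand on the standard parameter table), so the value is 1.02.
        img = cr.make_shepp_logan(64)
        assert img.pixels[32, 32] == pytest.approx(1.02, abs=1e-12)

    def test_corner_background_is_zero(self):
        img = cr.make_shepp_logan(64)
        assert img.pixels[0, 0] == 0.0
        assert img.pixels[-1, -1] == 0.0

    def test_resolutions_consistent_after_downsampling(self):
        hi = cr.make_shepp_logan(128).pixels.reshape(64, 2, 64, 2).mean(axis=(1, 3))
        lo = cr.make_shepp_logan(64).pixels
        r = np.corrcoef(hi.ravel(), lo.ravel())[0, 1]
        assert r > 0.9

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            cr.make_shepp_logan(8)


class TestRenderPhantom:
    def test_empty_spec_renders_zero(self):
        img = cr.render_phantom(cr.PhantomSpec(grid_size=32))
        assert not img.pixels.any()

    def test_disk_area_matches_pi_r_squared(self, disk_image):
        r = 14.0
        img = disk_image(n=64, r=r)
        count = np.count_nonzero(img.pixels == 1.0)
        assert count == pytest.approx(np.pi * r**2, rel=0.05)

    def test_overlapping_disks_add(self):
        spec = cr.PhantomSpec(
            grid_size=64,
            ellipses=[
                cr.EllipseSpec((0.0, 0.0), (10.0, 10.0), 0.0, 1.0),
                cr.EllipseSpec((5.0, 0.0), (10.0, 10.0), 0.0, 1.0),
            ],
        )
        img = cr.render_phantom(spec)
        assert img.pixels[32, 32] == 2.0  # origin inside both disks

    def test_rendering_is_additive_over_spec_union(self, rng):
        e1 = [cr.EllipseSpec((-10.0, 5.0), (8.0, 4.0), 0.3, 0.7)]
        e2 = [cr.EllipseSpec((6.0, -9.0), (5.0, 11.0), -0.9, -0.4)]
        both = cr.render_phantom(cr.PhantomSpec(grid_size=48, ellipses=e1 + e2))
        parts = (
            cr.render_phantom(cr.PhantomSpec(grid_size=48, ellipses=e1)).pixels
            + cr.render_phantom(cr.PhantomSpec(grid_size=48, ellipses=e2)).pixels
        )
        np.testing.assert_array_equal(both.pixels, parts)

    def test_nodule_changes_only_its_disk(self):
        base = cr.lung_phantom_spec(n=64, pixel_size=2.0)
        nod = cr.NoduleSpec(center_ab=(-20.0, 6.0), diameter=12.0, contrast=0.014)
        with_nod = cr.lung_phantom_spec(n=64, pixel_size=2.0, nodules=[nod])
        delta = cr.render_phantom(with_nod).pixels - cr.render_phantom(base).pixels
        img = cr.ImageGrid(delta, 2.0)
        a2 = (np.arange(64)[None, :] - 32) * 2.0
        b2 = (32 - np.arange(64)[:, None]) * 2.0
        outside = np.hypot(a2 + 20.0, b2 - 6.0) > nod.radius
        assert not delta[outside].any()
        np.testing.assert_allclose(delta[~outside], 0.014, rtol=1e-12)

    def test_out_of_grid_nodule_warns(self):
        spec = cr.PhantomSpec(
            grid_size=32,
            nodules=[cr.NoduleSpec((15.0, 0.0), 10.0, 0.01)],
        )
        with pytest.warns(UserWarning, match="clipped"):
            cr.render_phantom(spec)

    def test_yaml_round_trip(self):
        spec = cr.sample_lung_phantom(3)
        back = cr.PhantomSpec.from_yaml(spec.to_yaml())
        assert back.grid_size == spec.grid_size
        assert len(back.ellipses) == len(back.ellipses)
        np.testing.assert_allclose(
            cr.render_phantom(back).pixels, cr.render_phantom(spec).pixels
        )


class TestNoduleSpec:
    @pytest.mark.parametrize(
        "diameter,expected", [(3.0, SUB6MM), (5.99, SUB6MM), (6.0, MM6TO30), (25.0, MM6TO30)]
    )
    def test_size_class_follows_diameter(self, diameter, expected):
        assert cr.NoduleSpec((0, 0), diameter, 0.01).size_class == expected

    def test_inconsistent_size_class_rejected(self):
        with pytest.raises(ValueError, match="size_class"):
            cr.NoduleSpec((0, 0), 3.0, 0.01, size_class=MM6TO30)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            cr.NoduleSpec((0, 0), 0.0, 0.01)


class TestSinogramNoise:
    @pytest.fixture
    def sino(self, disk_image):
        geom = cr.default_geometry(32, 12)
        return cr.radon_forward(disk_image(n=32, r=10.0), geom)

    def test_zero_level_gaussian_is_identity(self, sino):
        out = cr.add_sinogram_noise(sino, "gaussian", 0.0, seed=1)
        np.testing.assert_array_equal(out.values, sino.values)

    @pytest.mark.parametrize("model,level", [("gaussian", 0.1), ("poisson", 1e4)])
    def test_seed_reproducible(self, sino, model, level):
        a = cr.add_sinogram_noise(sino, model, level, seed=7)
        b = cr.add_sinogram_noise(sino, model, level, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = cr.add_sinogram_noise(sino, model, level, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_gaussian_level_calibrated(self):
        geom = cr.ProjectionGeometry(np.linspace(0, 3, 100, endpoint=False), 100)
        zero = cr.Sinogram(np.zeros((100, 100)), geom)
        noisy = cr.add_sinogram_noise(zero, "gaussian", 0.1, seed=2)
        assert 0.095 <= noisy.values.std() <= 0.105

    def test_poisson_zero_count_clamped_with_warning(self, sino):
        # absurdly low photon count forces zero counts somewhere
        with pytest.warns(UserWarning, match="starvation"):
            out = cr.add_sinogram_noise(sino, "poisson", 1.5, seed=3)
        assert np.all(np.isfinite(out.values))

    def test_negative_level_rejected(self, sino):
        with pytest.raises(ValueError):
            cr.add_sinogram_noise(sino, "gaussian", -1.0, seed=0)

    def test_unknown_model_rejected(self, sino):
        with pytest.raises(ValueError):
            cr.add_sinogram_noise(sino, "salt-pepper", 0.1, seed=0)
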
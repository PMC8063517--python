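"""MIL sampling, ellipsoid fitting and degree of anisotropy."""

import numpy as np
import pytest

from trabecula3d import (
    BinaryMask,
    Calibration,
    degree_of_anisotropy,
    fit_ellipsoid,
    sample_mil,
)
from trabecula3d.anisotropy import mil_for_direction

from .conftest import make_phantom


def stripes_mask(n=32, period=8, fg=4):
    vox = np.zeros((n, n, n), bool)
    for z in range(0, n, period):
        vox[z : z + fg] = True
    return BinaryMask(vox, Calibration())


class TestMILSampling:
    def test_mil_across_stripes_is_chord_length(self, rng):
        m = stripes_mask()
        mil = mil_for_direction(m, (1, 0, 0), 400, 0.25, rng)
        # half-weighting of border-touching runs biases slightly upward
        assert mil == pytest.approx(4.0, rel=0.25)

    def test_mil_along_stripes_is_stack_scale(self, rng):
        m = stripes_mask()
        mil = mil_for_direction(m, (0, 0, 1), 400, 0.25, rng)
        assert mil > 16  # bounded by the stack, far above the 4-voxel chord

    def test_seeded_cloud_is_reproducible(self):
        m = stripes_mask()
        a = sample_mil(m, 20, 50, 1.0, rng_seed=7)
        b = sample_mil(m, 20, 50, 1.0, rng_seed=7)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.n_directions == 20

    def test_uniform_masks_rejected(self):
        with pytest.raises(ValueError):
            sample_mil(BinaryMask(np.ones((8, 8, 8), bool)), 10, 10, 1.0, 0)
        with pytest.raises(ValueError):
            sample_mil(BinaryMask(np.zeros((8, 8, 8), bool)), 10, 10, 1.0, 0)


class TestFitEllipsoid:
    @staticmethod
    def sphere_points(n, rng):
        u = rng.normal(size=(n, 3))
        return u / np.linalg.norm(u, axis=1, keepdims=True)

    def test_recovers_sphere(self, rng):
        pts = 2.0 * self.sphere_points(100, rng)
        e = fit_ellipsoid(pts)
        np.testing.assert_allclose(e.semi_axes, (2, 2, 2), atol=1e-6)
        np.testing.assert_allclose(e.centre, 0, atol=1e-6)

    def test_recovers_axis_aligned_ellipsoid(self, rng):
        pts = self.sphere_points(200, rng) * np.array([1.0, 2.0, 3.0])
        e = fit_ellipsoid(pts)
        np.testing.assert_allclose(e.semi_axes, (1, 2, 3), atol=1e-6)

    def test_recovers_rotated_offset_ellipsoid(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        pts = (self.sphere_points(300, rng) * np.array([1.5, 2.5, 4.0])) @ q.T + np.array([5, -3, 2])
        e = fit_ellipsoid(pts)
        np.testing.assert_allclose(e.semi_axes, (1.5, 2.5, 4.0), atol=1e-6)
        np.testing.assert_allclose(e.centre, (5, -3, 2), atol=1e-6)

    def test_coplanar_points_rejected(self, rng):
        pts = np.column_stack([rng.normal(size=(9, 2)), np.zeros(9)])
        with pytest.raises(ValueError):
            fit_ellipsoid(pts)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ellipsoid(self.sphere_points(8, rng))


class TestDegreeOfAnisotropy:
    def test_da_formula_on_exact_clouds(self, rng):
        u = TestFitEllipsoid.sphere_points(200, rng)
        e = fit_ellipsoid(u * np.array([1.0, 2.0, 4.0]))
        assert 1 - e.semi_axes[0] / e.semi_axes[2] == pytest.approx(0.75, abs=1e-9)
        iso = fit_ellipsoid(u * 1.0)
        assert 1 - iso.semi_axes[0] / iso.semi_axes[2] == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_noise_low_da(self):
        hits = 0
        for seed in range(10):
            noise = make_phantom("blurred_noise", (48, 48, 48), rng_seed=seed).mask
            res = degree_of_anisotropy(noise, 150, 300, 1.0, rng_seed=seed)
            hits += res.da < 0.15
            assert 0 <= res.da < 1
        assert hits == 10

    def test_plates_high_da(self):
        hits = 0
        for seed in range(10):
            plates = make_phantom("slab_stack", (48, 48, 48), thickness=4, gap=8).mask
            res = degree_of_anisotropy(plates, 150, 300, 1.0, rng_seed=seed)
            hits += res.da > 0.5
        assert hits == 10

    def test_da_invariant_under_right_angle_rotation(self):
        plates = make_phantom("slab_stack", (48, 48, 48), thickness=4, gap=8).mask
        rotated = BinaryMask(np.rot90(plates.voxels, axes=(0, 2)).copy(), plates.calibration)
        da0 = degree_of_anisotropy(plates, 200, 300, 1.0, rng_seed=1).da
        da1 = degree_of_anisotropy(rotated, 200, 300, 1.0, rng_seed=1).da
        assert da1 == pytest.approx(da0, abs=0.1)

    def test_more_directions_tighten_the_estimate(self):
        noise = make_phantom("blurred_noise", (40, 40, 40), rng_seed=3).mask
        spreads = []
        for n_dir in (40, 160):
            das = [
                degree_of_anisotropy(noise, n_dir, 200, 1.0, rng_seed=s).da
                for s in range(8)
            ]
            spreads.append(np.std(das))
        assert spreads[1] < spreads[0]
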
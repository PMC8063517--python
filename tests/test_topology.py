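"""Euler characteristic, edge correction and connectivity density."""

from fractions import Fraction

import numpy as np
import pytest

from trabecula3d import (
    BinaryMask,
    Calibration,
    connectivity_density,
    connectivity_from_chi,
    corrected_euler,
    edge_correction,
    euler_characteristic,
)
from trabecula3d.topology import octant_lut

from .conftest import make_phantom
from .oracles import chi_corrected_oracle, chi_oracle


def mask_of(vox, spacing=1.0, unit=""):
    return BinaryMask(np.asarray(vox, bool), Calibration((spacing,) * 3, unit))


class TestEulerCharacteristic:
    def test_all_256_octant_configurations_match_oracle(self):
        for cfg in range(256):
            vox = np.array([(cfg >> b) & 1 for b in range(8)], bool).reshape(2, 2, 2)
            assert euler_characteristic(mask_of(vox)) == chi_oracle(vox), cfg

    def test_random_6cube_masks_match_oracle(self, rng):
        for _ in range(1000):
            vox = rng.random((6, 6, 6)) < rng.random()
            m = mask_of(vox)
            chi = euler_characteristic(m)
            assert chi == chi_oracle(vox)
            assert chi == corrected_euler(m).chi  # octant sum == weighted-cell path

    def test_elementary_shapes(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        assert euler_characteristic(mask_of(single)) == 1

        two = np.zeros((3, 3, 5), bool)
        two[1, 1, 1] = two[1, 1, 3] = True
        assert euler_characteristic(mask_of(two)) == 2

        # 8-voxel square ring: a solid loop (torus topology)
        ring = np.zeros((3, 5, 5), bool)
        ring[1, 1:4, 1:4] = True
        ring[1, 2, 2] = False
        assert euler_characteristic(mask_of(ring)) == 0

    def test_solid_and_hollow_cube(self):
        solid = np.ones((5, 5, 5), bool)
        assert euler_characteristic(mask_of(solid)) == 1
        hollow = solid.copy()
        hollow[1:4, 1:4, 1:4] = False
        assert euler_characteristic(mask_of(hollow)) == 2  # genus-0 closed shell

    def test_additivity_for_disjoint_masks(self, rng):
        for _ in range(25):
            a = np.zeros((6, 6, 14), bool)
            b = np.zeros((6, 6, 14), bool)
            a[:, :, :6] = rng.random((6, 6, 6)) < 0.5
            b[:, :, 8:] = rng.random((6, 6, 6)) < 0.5
            chi_a = euler_characteristic(mask_of(a))
            chi_b = euler_characteristic(mask_of(b))
            assert euler_characteristic(mask_of(a | b)) == chi_a + chi_b

    def test_lut_is_generated_not_degenerate(self):
        lut = octant_lut()
        assert lut.shape == (256,)
        assert lut[0] == 0 and lut.min() < 0 < lut.max()


class TestEdgeCorrection:
    def test_interior_structure_needs_no_correction(self, ball_mask):
        assert edge_correction(ball_mask) == 0

    def test_corner_voxel(self):
        vox = np.zeros((4, 4, 4), bool)
        vox[0, 0, 0] = True
        res = corrected_euler(mask_of(vox))
        # a corner voxel is shared by 8 abutting subvolumes
        assert res.chi_corrected == Fraction(1, 8)
        assert res.delta_chi == Fraction(7, 8)

    def test_matches_weighted_cell_oracle_on_random_masks(self, rng):
        for _ in range(30):
            vox = rng.random((5, 5, 5)) < 0.5
            res = corrected_euler(mask_of(vox))
            assert res.chi_corrected == chi_corrected_oracle(vox)
            assert res.chi - res.delta_chi == res.chi_corrected

    def test_granularity_is_eighths(self, rng):
        vox = rng.random((6, 6, 6)) < 0.5
        assert (corrected_euler(mask_of(vox)).delta_chi * 8).denominator == 1


class TestConnectivity:
    def test_printed_corrected_euler_gives_printed_connectivity(self):
        res = connectivity_from_chi(Fraction(-238375, 1000), 62.21983)
        assert res.connectivity == Fraction(239375, 1000)
        assert round(res.conn_density, 5) == 3.84725

    def test_empty_mask_formula(self):
        res = connectivity_density(mask_of(np.zeros((10, 10, 10), bool)))
        assert res.euler.chi == 0 and res.euler.delta_chi == 0
        assert res.connectivity == 1
        assert res.conn_density == pytest.approx(0.001)

    def test_conn_density_scales_inverse_cubed_with_spacing(self, rng):
        vox = rng.random((8, 8, 8)) < 0.3
        vox[4, 4, 4] = True
        fine = connectivity_density(mask_of(vox, spacing=0.5))
        coarse = connectivity_density(mask_of(vox, spacing=1.0))
        assert fine.conn_density == pytest.approx(coarse.conn_density * 8)

    def test_ring_phantom_has_one_connection(self):
        ring = make_phantom("ring", (16, 16, 16)).mask
        res = connectivity_density(ring)
        assert res.euler.chi == 0
        assert res.connectivity == 1
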
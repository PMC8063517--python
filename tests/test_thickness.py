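"""Local thickness / separation maps and their statistics."""

import numpy as np
import pytest

from trabecula3d import (
    BinaryMask,
    Calibration,
    local_thickness,
    spacing_map,
    thickness_stats,
)
from trabecula3d.thickness import ThicknessMap, distance_ridge

from .conftest import make_phantom


def mask_of(vox, spacing=1.0):
    return BinaryMask(np.asarray(vox, bool), Calibration((spacing,) * 3))


class TestLocalThickness:
    def test_slab_interior_equals_slab_thickness(self, slab_mask):
        st = thickness_stats(local_thickness(slab_mask))
        assert st.mean == pytest.approx(5.0, abs=1.0)
        assert st.max == pytest.approx(5.0, abs=1.0)
        assert st.sd == pytest.approx(0.0, abs=1e-9)

    def test_slab_scales_with_spacing(self):
        slab = make_phantom("slab", (20, 40, 40), thickness=5, spacing=0.01, unit="mm").mask
        st = thickness_stats(local_thickness(slab))
        assert st.mean == pytest.approx(0.05, abs=0.01)

    def test_ball_max_diameter(self, ball_mask):
        st = thickness_stats(local_thickness(ball_mask))
        assert st.max == pytest.approx(20.0, abs=1.0)

    def test_background_is_nan_and_values_bounded(self, ball_mask):
        tm = local_thickness(ball_mask)
        assert np.isnan(tm.map[~ball_mask.voxels]).all()
        finite = tm.map[np.isfinite(tm.map)]
        assert (finite > 0).all()
        assert finite.max() <= np.linalg.norm(ball_mask.shape)

    def test_empty_mask_and_anisotropic_calibration_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_thickness(mask_of(np.zeros((4, 4, 4))))
        aniso = BinaryMask(np.ones((4, 4, 4), bool), Calibration((1, 1, 2)))
        with pytest.raises(ValueError, match="isotropic"):
            local_thickness(aniso)

    def test_deterministic(self, ball_mask):
        a = local_thickness(ball_mask).map
        b = local_thickness(ball_mask).map
        np.testing.assert_array_equal(a, b)

    def test_invariant_under_translation_and_permutation(self):
        vox = np.zeros((24, 24, 24), bool)
        z, y, x = np.indices(vox.shape)
        vox |= (z - 8) ** 2 + (y - 10) ** 2 + (x - 9) ** 2 <= 25
        base = thickness_stats(local_thickness(mask_of(vox)))
        rolled = thickness_stats(local_thickness(mask_of(np.roll(vox, (4, 3, 5), (0, 1, 2)))))
        permuted = thickness_stats(local_thickness(mask_of(vox.transpose(1, 2, 0))))
        assert rolled == base and permuted == base

    def test_mean_monotone_in_slab_thickness(self):
        means = []
        for t in (3, 5, 7):
            slab = make_phantom("slab", (20, 30, 30), thickness=t).mask
            means.append(thickness_stats(local_thickness(slab)).mean)
        assert means[0] < means[1] < means[2]

    def test_mask_artefacts_restricts_to_phase(self, slab_mask):
        raw = local_thickness(slab_mask, mask_artefacts=False)
        masked = local_thickness(slab_mask, mask_artefacts=True)
        assert np.isfinite(raw.map).sum() >= np.isfinite(masked.map).sum()
        assert np.isnan(masked.map[~slab_mask.voxels]).all()


class TestSpacingMap:
    def test_interior_gap_recovered(self):
        stack = make_phantom("slab_stack", (27, 40, 40), thickness=4, gap=7).mask
        sm = spacing_map(stack)
        st = thickness_stats(sm)
        assert sm.phase == "background"
        assert st.max == pytest.approx(7.0, abs=1.0)

    def test_full_foreground_rejected(self):
        with pytest.raises(ValueError, match="no background"):
            spacing_map(mask_of(np.ones((4, 4, 4))))

    def test_complement_involution(self, slab_mask):
        via_spacing = spacing_map(slab_mask.inverted())
        direct = local_thickness(slab_mask)
        np.testing.assert_array_equal(via_spacing.map, direct.map)


class TestStatsAndRidge:
    def test_stats_arithmetic(self):
        m = np.full((1, 1, 4), np.nan)
        m[0, 0, 0], m[0, 0, 2] = 2.0, 4.0
        st = thickness_stats(ThicknessMap(m, Calibration()))
        assert st.mean == 3.0 and st.max == 4.0 and st.sd == 1.0

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            thickness_stats(ThicknessMap(np.full((2, 2, 2), np.nan), Calibration()))

    def test_ridge_of_ball_contains_centre(self, ball_mask):
        # the local (neighbour-wise) containment criterion keeps a superset
        # of the global ridge; the globally maximal sphere must survive it
        ridge = distance_ridge(ball_mask)
        assert ridge[15, 15, 15]
        assert ridge.sum() < ball_mask.foreground_count  # surface largely pruned
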
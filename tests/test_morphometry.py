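"""Maximal-inscribed-ball thickness, separation, density functions, census."""

import numpy as np
import pytest
from scipy import ndimage

from sasmorph import morphometry, phantom
from sasmorph.grids import BinaryMask
from sasmorph.morphometry import (brute_force_thickness, count_intertrabecular_spaces,
                                  local_thickness, pdf_mode_um, separation,
                                  thickness_pdf)

from conftest import digitized_ball, random_blob_mask


def analytic_shapes():
    """Small closed-form foregrounds for oracle validation."""
    shapes = {}
    shapes["ball_r10"] = digitized_ball(10, pad=2).data
    single = np.zeros((7, 7, 7), bool)
    single[3, 3, 3] = True
    shapes["single_voxel"] = single
    slab = np.zeros((13, 20, 20), bool)
    slab[4:9] = True
    shapes["slab_t5"] = slab
    two = np.zeros((22, 22, 40), bool)
    zz, yy, xx = np.indices(two.shape)
    two |= ((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 8) ** 2) <= 16
    two |= ((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 28) ** 2) <= 64
    shapes["two_balls_r4_r8"] = two
    box = np.zeros((16, 16, 16), bool)
    box[3:12, 3:12, 3:12] = True
    shapes["box_9"] = box
    return shapes


class TestLocalThickness:
    def test_single_voxel_has_unit_diameter(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        tm = local_thickness(BinaryMask(m))
        assert tm.thickness_um[2, 2, 2] == pytest.approx(1.0)

    def test_ball_interior_thickness_near_diameter(self):
        bm = digitized_ball(10, pad=2)
        tm = local_thickness(bm).thickness_um
        c = bm.shape[0] // 2
        zz, yy, xx = np.indices(bm.shape)
        interior = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= 9**2
        assert (np.abs(tm[interior] - 20.0) <= 1.0).all()

    def test_slab_thickness_everywhere(self):
        slab = np.zeros((13, 24, 24), bool)
        slab[4:9] = True
        tm = local_thickness(BinaryMask(slab))
        # plate model: the inscribed ball diameter equals the slab thickness
        vals = tm.thickness_um[slab]
        assert (np.abs(vals - 5.0) <= 1.0).all()

    def test_oracle_equivalence_on_random_masks(self):
        for seed in range(10):
            bm = random_blob_mask(seed)
            if not bm.data.any():
                continue
            fast = local_thickness(bm).thickness_um
            slow = brute_force_thickness(bm).thickness_um
            assert np.array_equal(fast, slow), f"mismatch at seed {seed}"

    def test_oracle_equivalence_on_analytic_shapes(self):
        for name, m in analytic_shapes().items():
            bm = BinaryMask(m)
            fast = local_thickness(bm).thickness_um
            slow = brute_force_thickness(bm).thickness_um
            assert np.array_equal(fast, slow), f"mismatch for {name}"

    def test_invariant_bounds(self):
        for seed in (1, 5):
            bm = random_blob_mask(seed)
            if not bm.data.any():
                continue
            tm = local_thickness(bm)
            edt = ndimage.distance_transform_edt(bm.data)
            fg = bm.data
            assert (tm.thickness_um[fg] >= 2 * edt[fg] - 1 - 1e-9).all()
            assert tm.thickness_um.max() <= tm.max_um() + 1e-9

    def test_monotone_under_dilation(self):
        for seed in (0, 3, 7):
            bm = random_blob_mask(seed, shape=(20, 20, 20))
            if not bm.data.any():
                continue
            grown = BinaryMask(ndimage.binary_dilation(bm.data))
            t0 = local_thickness(bm).thickness_um
            t1 = local_thickness(grown).thickness_um
            assert (t1[bm.data] >= t0[bm.data] - 1e-9).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            local_thickness(BinaryMask(np.zeros((5, 5, 5), bool)))

    def test_brute_force_refuses_large_grids(self):
        with pytest.raises(ValueError, match="too large"):
            brute_force_thickness(BinaryMask(np.ones((80, 10, 10), bool)))


class TestSeparation:
    def test_annulus_separation_matches_gap(self, symmetric_phantom):
        spec, vol, truth = symmetric_phantom
        sep = separation(truth.csf_mask)
        gap = spec.dura_radius_um - spec.nerve_radius_um
        vals = sep.foreground_values()
        assert np.median(vals) == pytest.approx(gap, abs=1.5)

    def test_trabeculae_reduce_mean_separation(self, symmetric_phantom, default_phantom):
        _, _, truth0 = symmetric_phantom
        _, _, truth1 = default_phantom
        # same annulus geometry; adding microstructure shrinks the free space
        sep0 = separation(truth0.csf_mask).foreground_values().mean()
        sep1 = separation(truth1.csf_mask).foreground_values().mean()
        assert sep1 < sep0

    def test_empty_csf_rejected(self):
        with pytest.raises(ValueError):
            separation(BinaryMask(np.zeros((5, 5, 5), bool)))


class TestThicknessPdf:
    def test_uniform_slab_single_bin(self):
        slab = np.zeros((13, 20, 20), bool)
        slab[4:9] = True
        tm = local_thickness(BinaryMask(slab))
        centers, density = thickness_pdf(tm, 1.0)
        occupied = density > 0
        assert occupied.sum() == 1
        assert density[occupied][0] == pytest.approx(1.0)

    def test_normalization(self):
        for seed in (2, 6):
            bm = random_blob_mask(seed)
            if not bm.data.any():
                continue
            _, density = thickness_pdf(local_thickness(bm), 0.7)
            assert density.sum() * 0.7 == pytest.approx(1.0, abs=1e-9)

    def test_invalid_bin_width(self):
        bm = random_blob_mask(2)
        with pytest.raises(ValueError):
            thickness_pdf(local_thickness(bm), 0.0)


@pytest.fixture(scope="module")
def chamber_separation():
    mask, truth = phantom.two_chamber_mask()
    return separation(mask), truth


class TestSpaceCensus:
    def test_two_chambers_counted_with_correct_diameters(self, chamber_separation):
        sep, truth = chamber_separation
        census = count_intertrabecular_spaces(sep, 130.0)
        assert len(census) == 2
        diams = sorted(s["diameter_um"] for s in census.spaces)
        assert diams[0] == pytest.approx(150.0, rel=0.05)
        assert diams[1] == pytest.approx(300.0, rel=0.05)
        assert all(s["volume_mm3"] > 0 for s in census.spaces)

    def test_threshold_above_max_gives_empty_census(self, chamber_separation):
        sep, _ = chamber_separation
        census = count_intertrabecular_spaces(sep, sep.max_um() + 1.0)
        assert len(census) == 0

    def test_halving_h_depth_never_decreases_count(self, chamber_separation):
        sep, _ = chamber_separation
        n_coarse = len(count_intertrabecular_spaces(sep, 130.0, h_depth_um=20.0))
        n_fine = len(count_intertrabecular_spaces(sep, 130.0, h_depth_um=10.0))
        assert n_fine >= n_coarse

    def test_invalid_threshold(self, chamber_separation):
        sep, _ = chamber_separation
        with pytest.raises(ValueError):
            count_intertrabecular_spaces(sep, -1.0)
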
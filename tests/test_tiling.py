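"""Registration and stitching: shift recovery, least-squares offsets, seams."""

import numpy as np
import pytest

from sasmorph import phantom, tiling
from sasmorph.grids import VoxelGrid
from sasmorph.tiling import (OffsetGraph, build_offset_graph, max_gradient_jump,
                             register_pair, resolve_offsets, stitch)


def crop(base, origin, size=60):
    oz, oy, ox = origin
    return VoxelGrid(base[10 + oz:10 + oz + size,
                          10 + oy:10 + oy + size,
                          10 + ox:10 + ox + size])


class TestRegisterPair:
    def test_known_shift_recovered_subvoxel(self, broadband_field):
        a = crop(broadband_field, (0, 0, 0))
        b = crop(broadband_field, (5, -3, 2))
        for nominal in [(5, -3, 2), (4, -2, 3), (7, -5, 0)]:
            shift, conf = register_pair(a, b, nominal, search_halfwidth=6)
            assert np.abs(shift - (5, -3, 2)).max() < 0.1
            assert 0.0 < conf <= 1.0

    def test_noise_keeps_integer_part_and_lowers_confidence(self, broadband_field):
        a = crop(broadband_field, (0, 0, 0))
        b = crop(broadband_field, (5, -3, 2))
        _, conf_clean = register_pair(a, b, (5, -3, 2), 6)
        sigma = 0.1 * np.ptp(b.data)
        confs = []
        for seed in range(20):
            noisy = VoxelGrid(b.data + np.random.default_rng(seed).normal(0, sigma, b.shape))
            shift, conf = register_pair(a, noisy, (5, -3, 2), 6)
            assert tuple(np.round(shift).astype(int)) == (5, -3, 2)
            confs.append(conf)
        assert np.mean(confs) < conf_clean

    def test_agrees_with_independent_phase_correlation(self, broadband_field):
        """Cross-check against the reference phase-correlation implementation."""
        from skimage.registration import phase_cross_correlation
        a = crop(broadband_field, (0, 0, 0))
        b = crop(broadband_field, (5, -3, 2))
        shift, _ = register_pair(a, b, (5, -3, 2), 6)
        ref, _, _ = phase_cross_correlation(a.data[5:, :, 2:][:55, :57, :56],
                                            b.data[:, 3:, :][:55, :57, :56],
                                            upsample_factor=10)
        # reference measures the residual from the nominal (5, -3, 2)
        assert np.abs((shift - (5, -3, 2)) - ref).max() <= 0.2

    def test_rejects_small_or_flat_overlap(self, broadband_field):
        a = crop(broadband_field, (0, 0, 0))
        with pytest.raises(ValueError, match="overlap"):
            register_pair(a, a, (55, 0, 0), 4)
        flat = VoxelGrid(np.zeros((60, 60, 60)))
        with pytest.raises(ValueError, match="unregistrable"):
            register_pair(flat, flat, (0, 0, 0), 4)


class TestResolveOffsets:
    def test_single_edge(self):
        g = OffsetGraph(2)
        g.add(0, 1, (10.0, -2.0, 3.0), 1.0)
        off = resolve_offsets(g)
        assert np.allclose(off[0], 0)
        assert np.allclose(off[1], (10, -2, 3))

    def test_consistent_cycle_zero_residual(self):
        g = OffsetGraph(3)
        g.add(0, 1, (10, 0, 0), 1.0)
        g.add(1, 2, (0, 5, 0), 1.0)
        g.add(0, 2, (10, 5, 0), 1.0)
        off = resolve_offsets(g)
        assert np.allclose(off, [[0, 0, 0], [10, 0, 0], [10, 5, 0]], atol=1e-9)

    def test_perturbed_cycle_least_squares(self):
        # shifts 10, 10 and 23 (one edge 3 voxels off): the normal equations
        # give offsets 0, 11, 22 - every tile within 1.5 voxels of truth
        g = OffsetGraph(3)
        g.add(0, 1, (10, 0, 0), 1.0)
        g.add(1, 2, (10, 0, 0), 1.0)
        g.add(0, 2, (23, 0, 0), 1.0)
        off = resolve_offsets(g, weight_by_confidence=False)
        assert np.allclose(off[:, 0], [0, 11, 22], atol=1e-9)
        # up to the free global translation, every tile is within 1.5 voxels
        err = off[:, 0] - [0, 10, 20]
        assert np.abs(err - err.mean()).max() <= 1.5

    def test_disconnected_graph_names_component(self):
        g = OffsetGraph(4)
        g.add(0, 1, (5, 0, 0), 1.0)
        g.add(2, 3, (5, 0, 0), 1.0)
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            resolve_offsets(g)


class TestStitch:
    def test_single_tile_idempotent(self, broadband_field):
        tile = VoxelGrid(broadband_field[:40, :40, :40])
        out = stitch([(tile, (0, 0, 0))], np.zeros((1, 3)))
        assert np.allclose(out.data, tile.data)

    def test_identical_background_tiles_reproduce_naive_mosaic(self, stitch_phantom):
        spec, vol, truth = stitch_phantom
        tiles = phantom.add_tile_backgrounds_and_split(vol, (40, 90, 90), 0.25,
                                                       gradient_amplitude=0.0,
                                                       rng_seed=9)
        naive = phantom.naive_mosaic(tiles, vol.shape)
        out = stitch(tiles)
        assert np.allclose(out.data, naive.data, atol=1e-8)

    def test_gradient_tiles_register_and_stitch_seamlessly(self, stitch_phantom):
        spec, vol, truth = stitch_phantom
        tiles = phantom.add_tile_backgrounds_and_split(vol, (40, 90, 90), 0.25,
                                                       gradient_amplitude=0.3,
                                                       rng_seed=9)
        graph = build_offset_graph(tiles, search_halfwidth=6)
        offsets = resolve_offsets(graph)
        true_off = np.array([o for _, o in tiles], float)
        true_off -= true_off[0]
        assert np.abs(offsets - true_off).max() <= 0.5

        naive = phantom.naive_mosaic(tiles, vol.shape)
        stitched = stitch(tiles, offsets)
        assert stitched.shape == vol.shape
        jump_ratio = max_gradient_jump(stitched, vol) / max_gradient_jump(naive, vol)
        assert jump_ratio <= 0.20

        # up to the unidentifiable volume-wide smooth field, the stitched
        # volume reproduces the gradient-free source
        from sasmorph.enhance import detrend_polynomial
        resid = detrend_polynomial(stitched.data - vol.data)
        rms = float(np.sqrt((resid**2).mean()))
        assert rms <= spec.noise_sigma + 0.1 * 0.3

    def test_gap_in_coverage_raises(self):
        rng = np.random.default_rng(0)
        t0 = VoxelGrid(rng.normal(size=(20, 20, 20)))
        t1 = VoxelGrid(rng.normal(size=(20, 20, 20)))
        with pytest.raises(ValueError, match="uncovered"):
            stitch([(t0, (0, 0, 0)), (t1, (0, 0, 30))],
                   np.array([[0, 0, 0], [0, 0, 30.0]]))

    def test_coarse_tile_resampled_to_fine_grid(self):
        rng = np.random.default_rng(5)
        fine = VoxelGrid(rng.normal(size=(16, 16, 16)), voxel_size_um=1.0)
        coarse = VoxelGrid(fine.data[::2, ::2, ::2].copy(), voxel_size_um=2.0)
        out = stitch([(coarse, (0, 0, 0))], np.zeros((1, 3)),
                     target_voxel_size_um=1.0)
        assert out.voxel_size_um == 1.0
        assert out.shape == (16, 16, 16)
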
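"""Registration engine and mosaic assembly."""

import numpy as np
import pytest

from stagescan import (
    OffsetEstimate,
    compose,
    global_positions,
    pairwise_offset,
    phase_correlate,
)


class TestPhaseCorrelate:
    def test_identical_images_give_zero_shift_high_confidence(self, textured_scene):
        img = textured_scene[:128, :128].astype(float)
        est = phase_correlate(img, img)
        assert est.vector == (0.0, 0.0)
        assert est.confidence > 0.9

    def test_circular_shift_recovered(self, textured_scene):
        a = textured_scene[:128, :128].astype(float)
        b = np.roll(a, (7, -3), axis=(0, 1))
        est = phase_correlate(a, b, window=False)
        # content displaced by (7, -3): delta correlation, exact recovery
        assert est.vector == (7.0, -3.0)

    def test_translation_equivariance(self, textured_scene):
        # shifting both images equally leaves the estimate unchanged
        a = textured_scene[50:178, 50:178].astype(float)
        b = textured_scene[53:181, 55:183].astype(float)
        a2 = textured_scene[60:188, 70:198].astype(float)
        b2 = textured_scene[63:191, 75:203].astype(float)
        e1 = phase_correlate(a, b)
        e2 = phase_correlate(a2, b2)
        assert e1.dy == pytest.approx(e2.dy, abs=0.15)
        assert e1.dx == pytest.approx(e2.dx, abs=0.15)

    def test_agrees_with_skimage_on_subpixel_shift(self):
        # independent cross-check against the upsampled-DFT implementation
        from scipy import ndimage
        from skimage.registration import phase_cross_correlation

        rng = np.random.default_rng(8)
        base = ndimage.gaussian_filter(rng.normal(size=(160, 160)), 2.0)
        shifted = ndimage.shift(base, (2.6, -1.3), order=3, mode="wrap")
        ours = phase_correlate(base, shifted, window=False)
        theirs, _, _ = phase_cross_correlation(base, shifted, upsample_factor=50)
        # skimage reports the shift to apply to the moving image (opposite sign)
        assert ours.dy == pytest.approx(-theirs[0], abs=0.1)
        assert ours.dx == pytest.approx(-theirs[1], abs=0.1)


class TestPairwiseOffset:
    def test_identical_tiles_zero_offset(self, textured_scene):
        tile = textured_scene[:128, :128]
        est = pairwise_offset(tile, tile, (0.0, 0.0))
        assert (est.dy, est.dx) == (0.0, 0.0)
        assert est.confidence > 0.9
        assert not est.fallback

    def test_integer_shift_recovered_exactly(self, textured_scene):
        # tiles cut from one scene: position offset known exactly
        a = textured_scene[30:158, 40:168]
        b = textured_scene[37:165, 133:261]  # offset (7, 93) vs a
        est = pairwise_offset(a, b, (0.0, 96.0), search_radius_px=12)
        assert (est.dy, est.dx) == (7.0, 93.0)

    def test_featureless_overlap_falls_back_to_nominal(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(128, 128))
        b = rng.normal(size=(128, 128))  # unrelated noise
        est = pairwise_offset(a, b, (0.0, 96.0), min_confidence=0.2)
        assert est.fallback
        assert (est.dy, est.dx) == (0.0, 96.0)

    def test_too_narrow_overlap_rejected(self, textured_scene):
        a = textured_scene[:128, :128]
        with pytest.raises(ValueError, match="overlap"):
            pairwise_offset(a, a, (0.0, 120.0))


class TestGlobalPositions:
    def test_consistent_offsets_reproduced_exactly(self):
        ids = [(0, 0), (1, 0), (0, 1), (1, 1)]
        truth = {(0, 0): (0, 0), (1, 0): (3, 94), (0, 1): (92, 5), (1, 1): (95, 99)}
        offsets = []
        for a, b in [((0, 0), (1, 0)), ((0, 0), (0, 1)), ((1, 0), (1, 1)), ((0, 1), (1, 1))]:
            offsets.append(
                OffsetEstimate(a, b, truth[b][0] - truth[a][0],
                               truth[b][1] - truth[a][1], 1.0)
            )
        pos = global_positions(offsets, ids)
        for tid in ids:
            assert pos[tid][0] == pytest.approx(truth[tid][0], abs=1e-9)
            assert pos[tid][1] == pytest.approx(truth[tid][1], abs=1e-9)

    def test_single_corrupted_edge_absorbed_by_redundancy(self):
        # 3x3 grid with exact offsets except one corrupted edge
        ids = [(i, j) for j in range(3) for i in range(3)]
        truth = {(i, j): (100.0 * j, 100.0 * i) for i, j in ids}
        offsets = []
        from stagescan.stitching import grid_edges

        for a, b in grid_edges(3, 3):
            dy = truth[b][0] - truth[a][0]
            dx = truth[b][1] - truth[a][1]
            if (a, b) == ((1, 1), (2, 1)):
                dy += 30.0  # corrupted estimate that still reports confidence
            offsets.append(OffsetEstimate(a, b, dy, dx, 1.0))
        pos = global_positions(offsets, ids)
        err = max(
            np.hypot(pos[t][0] - truth[t][0], pos[t][1] - truth[t][1]) for t in ids
        )
        assert err < 1.0

    def test_single_tile_sits_at_origin(self):
        assert global_positions([], [(0, 0)]) == {(0, 0): (0.0, 0.0)}

    def test_disconnected_graph_lists_components(self):
        ids = [(0, 0), (1, 0), (5, 5)]
        offsets = [OffsetEstimate((0, 0), (1, 0), 0.0, 96.0, 1.0)]
        with pytest.raises(ValueError, match="disconnected"):
            global_positions(offsets, ids)


class TestCompose:
    def test_cut_and_reassemble_identity(self, textured_scene):
        tiles, positions = [], []
        for i in range(3):
            for j in range(2):
                r, c = 20 + j * 96, 20 + i * 96
                tiles.append(textured_scene[r : r + 128, c : c + 128])
                positions.append((r, c))
        comp = compose(tiles, positions, blend_width_px=16)
        orig = textured_scene[20 : 20 + 96 + 128, 20 : 20 + 2 * 96 + 128]
        assert comp.shape == orig.shape
        assert np.abs(comp.astype(int) - orig.astype(int)).max() <= 1

    def test_zero_blend_is_last_writer_wins(self):
        a = np.full((16, 16), 10, dtype=np.uint16)
        b = np.full((16, 16), 99, dtype=np.uint16)
        comp = compose([a, b], [(0, 0), (0, 8)], blend_width_px=0)
        assert comp[0, 12] == 99
        assert comp[0, 4] == 10

    def test_single_tile_identity(self, textured_scene):
        tile = textured_scene[:64, :64]
        np.testing.assert_array_equal(compose([tile], [(0, 0)], 8), tile)

    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            compose([np.zeros((8, 8))], [(np.nan, 0.0)], 4)


class TestEndToEndPiezoScanStitch:
    def test_open_loop_piezo_scan_stitches_to_under_2px_rms(self):
        """25/30 % overlap absorbs ±20 % piezo step error: recovered tile
        positions agree with the simulated ground truth to < 2 px RMS."""
        from stagescan import (
            OpticsModel,
            VirtualCamera,
            make_nervenet_specimen,
            plan_serpentine,
            run_scan,
            stitch_scan,
        )
        from stagescan.hardware import StageState, piezo_model

        optics = OpticsModel(fov_px=128)
        fov = optics.fov_um
        nx, ny = 5, 4
        origin = (200.0, 200.0)
        extent = (
            fov + (nx - 1) * fov * 0.75 + fov,
            fov + (ny - 1) * fov * 0.70 + fov,
            30.0,
        )
        n_cells = int(extent[0] * extent[1] / 900)  # ~30 um mesh spacing
        vol = make_nervenet_specimen(
            extent, n_cells, seed=9, surface_amplitude_um=0.0,
            origin=(origin[0] - fov, origin[1] - fov, 185.0),
        )
        mid = 185.0 + (vol.intensity.shape[0] - 1) * vol.pitch_z / 2.0
        plan = plan_serpentine(nx, ny, fov, 0.25, 0.30, origin, nz=3, dz_um=2.0)
        camera = VirtualCamera(vol, optics, seed=4)
        stage = StageState(
            {ax: piezo_model() for ax in "xyz"},
            position={"x": 200.0, "y": 200.0, "z": 200.0},
        )
        records, _ = run_scan(
            plan, stage, camera, z_start_um=mid - 2.0,
            rng=np.random.default_rng(28),
        )
        px = optics.pixel_um
        mips = {(r.i, r.j): r.mip for r in records}
        nominal = {
            (r.i, r.j): (r.nominal_xy_um[1] / px, r.nominal_xy_um[0] / px)
            for r in records
        }
        truth = {
            (r.i, r.j): (r.achieved_xy_um[1] / px, r.achieved_xy_um[0] / px)
            for r in records
        }
        positions, offsets, composite = stitch_scan(
            mips, nominal, nx, ny, search_radius_px=50
        )
        anchor = (0, 0)
        errors = []
        for key, solved in positions.items():
            expected = (
                truth[key][0] - truth[anchor][0] + positions[anchor][0],
                truth[key][1] - truth[anchor][1] + positions[anchor][1],
            )
            errors.append((solved[0] - expected[0], solved[1] - expected[1]))
        errors = np.asarray(errors)
        rms = float(np.sqrt((errors**2).sum(axis=1).mean()))
        assert rms < 2.0
        assert composite.shape[0] > 128 and composite.shape[1] > 128
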
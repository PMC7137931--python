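"""QC mathematics: USAF formulas, diffraction limits, MTF, drift, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stagescan import (
    abbe_limit,
    calibrate_steps,
    drift_track,
    illumination_uniformity,
    make_slanted_edge,
    measure_displacement,
    rayleigh_limit,
    res_cc,
    res_lp,
    slant_edge_mtf,
)
from stagescan.hardware import actuate, piezo_model


class TestResolutionFormulas:
    def test_group7_element6_rounds_to_228(self):
        assert round(res_lp(7, 6)) == 228
        assert res_lp(7, 6) == pytest.approx(228.07, abs=0.01)

    def test_group0_element1(self):
        assert res_lp(0, 1) == 1.0
        assert res_cc(1.0) == 1000.0

    def test_group2_element4(self):
        assert res_lp(2, 4) == pytest.approx(2 ** 2.5)

    def test_element_out_of_range(self):
        with pytest.raises(ValueError):
            res_lp(3, 0)
        with pytest.raises(ValueError):
            res_lp(3, 7)

    @settings(max_examples=60, deadline=None)
    @given(
        group=st.integers(min_value=-2, max_value=7),
        element=st.integers(min_value=1, max_value=6),
    )
    def test_formulas_match_direct_evaluation(self, group, element):
        assert res_lp(group, element) == 2.0 ** (group + (element - 1) / 6.0)
        assert res_cc(res_lp(group, element)) == 1000.0 / res_lp(group, element)

    def test_spacing_strictly_decreasing_in_index_order(self):
        spacings = [
            res_cc(res_lp(g, e)) for g in range(-2, 8) for e in range(1, 7)
        ]
        assert all(a > b for a, b in zip(spacings, spacings[1:]))


class TestDiffractionLimits:
    def test_abbe_equals_wavelength_at_na_half(self):
        assert abbe_limit(530.0, 0.5) == 530.0

    def test_rayleigh_530nm(self):
        assert rayleigh_limit(530.0, 0.5) == pytest.approx(646.6)
        assert round(rayleigh_limit(530.0, 0.5)) == 647

    def test_abbe_half_wavelength_at_na_one(self):
        assert abbe_limit(500.0, 1.0) == 250.0


class TestSlantEdgeMTF:
    def test_normalized_to_one_at_dc(self):
        curve = slant_edge_mtf(make_slanted_edge(128, 5.0), 4)
        assert curve.contrast[0] == pytest.approx(1.0)
        assert curve.frequency.max() <= 0.5

    def test_ideal_edge_follows_pixel_aperture_sinc(self):
        curve = slant_edge_mtf(make_slanted_edge(128, 5.0), 4)
        f = np.linspace(0.05, 0.4, 15)
        oracle = np.abs(np.sinc(f))
        assert np.max(np.abs(curve.at(f) - oracle) / oracle) < 0.02

    @pytest.mark.parametrize("sigma", [0.8, 1.2])
    def test_gaussian_blur_matches_analytic_mtf(self, sigma):
        curve = slant_edge_mtf(make_slanted_edge(128, 5.0, blur_sigma_px=sigma), 4)
        f = np.linspace(0.05, 0.4, 15)
        oracle = np.exp(-2.0 * np.pi**2 * sigma**2 * f**2) * np.abs(np.sinc(f))
        meas = curve.at(f)
        assert np.max(np.abs(meas - oracle)) < 0.03
        usable = oracle > 0.1
        assert np.max(np.abs(meas[usable] - oracle[usable]) / oracle[usable]) < 0.03

    def test_detects_horizontal_edges_by_transposing(self):
        curve = slant_edge_mtf(make_slanted_edge(128, 5.0).T, 4)
        assert abs(curve.edge_angle_deg) == pytest.approx(5.0, abs=0.3)

    def test_axis_aligned_edge_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            slant_edge_mtf(make_slanted_edge(128, 0.0), 4)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            slant_edge_mtf(np.full((64, 64), 3.0), 4)


class TestDisplacement:
    def test_identical_frames_zero(self, textured_scene):
        frame = textured_scene[:128, :128]
        m = measure_displacement(frame, frame, 0.386)
        assert m.magnitude_um == 0.0
        assert not m.flagged

    def test_constructed_13px_shift(self, textured_scene):
        a = textured_scene[30:158, 30:158]
        b = textured_scene[30:158, 43:171]  # content displaced 13 px in x
        m = measure_displacement(a, b, 0.386)
        assert abs(m.dx_um) == pytest.approx(13 * 0.386, abs=0.05)
        assert 13 * 0.386 == pytest.approx(5.018)

    def test_7px_shift_below_3um_stability_bound(self, textured_scene):
        a = textured_scene[30:158, 30:158]
        b = textured_scene[37:165, 30:158]
        m = measure_displacement(a, b, 0.386)
        assert m.magnitude_um == pytest.approx(7 * 0.386, abs=0.05)
        assert m.magnitude_um < 3.0

    def test_featureless_frames_flagged(self):
        rng = np.random.default_rng(0)
        m = measure_displacement(
            rng.normal(size=(64, 64)), rng.normal(size=(64, 64)), 0.386,
            min_confidence=0.2,
        )
        assert m.flagged


class TestDriftTrack:
    def test_static_series_has_zero_drift(self, textured_scene):
        frames = [textured_scene[:96, :96]] * 5
        table, summary = drift_track(frames, 0.386)
        assert summary["max_abs_dx_px"] == 0.0
        assert summary["max_abs_dy_px"] == 0.0

    def test_linear_drift_half_pixel_per_frame(self, textured_scene):
        from scipy import ndimage

        base = textured_scene[20:148, 20:148].astype(float)
        frames = [
            ndimage.shift(base, (0.0, -0.5 * k), order=3, mode="wrap")
            for k in range(10)
        ]
        table, summary = drift_track(frames, 1.0)
        # drift grows 0.5 px per frame; frame 9 has drifted 4.5 px
        assert summary["max_abs_dx_px"] == pytest.approx(4.5, abs=0.15)
        assert np.all(np.diff(table["dx_px"].abs()) > 0.2)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            drift_track([np.zeros((8, 8))], 1.0)


class TestCalibrateSteps:
    @staticmethod
    def _simulate(seed=0, n=15, sizes=(20, 50, 250, 500, 1000), model=None):
        model = model or piezo_model()
        rng = np.random.default_rng(seed)
        rows = []
        for direction, sign in (("up", 1), ("down", -1)):
            for size in sizes:
                for _ in range(n):
                    rows.append(
                        {
                            "axis": "z",
                            "direction": direction,
                            "step_size": size,
                            "distance_um": abs(actuate(model, sign * size, rng)),
                        }
                    )
        return pd.DataFrame(rows), model

    def test_recovers_simulated_slope_within_two_se(self):
        df, model = self._simulate(seed=1)
        result = calibrate_steps(df)
        fit = result.slopes[("z", "up")]
        assert abs(fit.um_per_unit - model.nominal_um_per_unit) <= 2 * fit.stderr

    def test_up_mean_exceeds_down_mean(self):
        df, _ = self._simulate(seed=2)
        result = calibrate_steps(df)
        by = {(r.direction, r.step_size): r for r in result.records}
        for size in (20, 50, 250, 500, 1000):
            assert by[("up", size)].mean_um > by[("down", size)].mean_um

    def test_single_measurement_has_no_sd(self):
        df = pd.DataFrame(
            [{"axis": "z", "direction": "up", "step_size": 100, "distance_um": 5.0}]
        )
        rec = calibrate_steps(df).records[0]
        assert rec.n == 1
        assert rec.sd_um is None

    def test_unresolvable_repeats_have_no_sd(self):
        df, _ = self._simulate(seed=3, sizes=(20,))
        df["resolvable"] = False
        rec = calibrate_steps(df).records[0]
        assert rec.n == 15
        assert rec.sd_um is None

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            calibrate_steps(pd.DataFrame({"axis": ["z"]}))

    def test_calibration_table_round_trip(self):
        df, model = self._simulate(seed=4)
        cal = calibrate_steps(df).to_calibration()
        up = cal.lookup("z", "up")
        down = cal.lookup("z", "down")
        assert up == pytest.approx(model.nominal_um_per_unit, rel=0.05)
        assert down == pytest.approx(
            model.nominal_um_per_unit / model.asymmetry_ratio, rel=0.05
        )


class TestIlluminationUniformity:
    def test_constant_image(self):
        report = illumination_uniformity(np.full((128, 128), 500.0))
        assert report["corner_centre_ratio"] == pytest.approx(1.0)
        assert report["cv"] == 0.0

    def test_ten_percent_corner_vignette(self):
        from stagescan.specimen import _vignette

        img = 1000.0 * _vignette(256, 0.10)
        report = illumination_uniformity(img)
        assert report["corner_centre_ratio"] == pytest.approx(0.90, abs=0.01)

    def test_invariant_to_global_scaling(self):
        from stagescan.specimen import _vignette

        img = _vignette(128, 0.2)
        r1 = illumination_uniformity(img)
        r2 = illumination_uniformity(1234.5 * img)
        assert r1["corner_centre_ratio"] == pytest.approx(r2["corner_centre_ratio"])
        assert r1["cv"] == pytest.approx(r2["cv"])
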
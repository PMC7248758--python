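"""Temperature-based aquagram: baseline, areas, calibration, full chain."""

import numpy as np
import pandas as pd
import pytest

import aquagram as aq
from aquagram.temperature import (
    ConditioningError,
    RangeError,
    ReferenceCurves,
    loess_smooth,
    local_calibration,
)

WL = np.arange(1300.0, 1600.01, 0.5)


class TestBaselineCorrect:
    def test_linear_spectrum_maps_to_zeros(self):
        spec = 0.05 + 3e-4 * (WL - 1300.0)
        np.testing.assert_allclose(aq.baseline_correct(spec, WL), 0.0, atol=1e-12)

    def test_constant_spectrum_maps_to_zeros(self):
        np.testing.assert_allclose(
            aq.baseline_correct(np.full(WL.size, 0.7), WL), 0.0, atol=1e-12
        )

    def test_gaussian_on_sloped_line_recovers_gaussian(self):
        """Oracle: explicit subtraction of the known line.  The band's tails
        vanish at the edges, so the fitted line is the known line itself."""
        gauss = 0.8 * np.exp(-0.5 * ((WL - 1450.0) / 15.0) ** 2)
        line = 0.1 + 2e-4 * (WL - 1300.0)
        corrected = aq.baseline_correct(gauss + line, WL)
        np.testing.assert_allclose(corrected, gauss, atol=1e-12)

    def test_single_point_anchor_mode(self):
        spec = 0.1 + 1e-3 * (WL - 1300.0)
        out = aq.baseline_correct(spec, WL, edge_halfwidth_nm=0.0)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[-1] == pytest.approx(0.0, abs=1e-12)

    def test_wrong_span_raises(self):
        wl = np.arange(1310.0, 1590.01, 0.5)
        with pytest.raises(RangeError, match="span"):
            aq.baseline_correct(np.zeros(wl.size), wl)


class TestRelativeAreas:
    def test_triangle_closed_form(self):
        """Triangle apex 1.0 at 1450 nm, zeros at the edges: total area is
        150 nm*AU and C05 [1406, 1418] holds ~0.0597 of it."""
        tri = np.where(WL <= 1450.0, (WL - 1300.0) / 150.0, (1600.0 - WL) / 150.0)
        ra = aq.relative_areas(tri, WL)
        assert ra.total_auc == pytest.approx(150.0, rel=1e-9)
        j = ra.coordinate_ids.index("C05")
        expected = ((118.0**2 - 106.0**2) / 2.0 / 150.0) / 150.0
        assert ra.rel_area[j] == pytest.approx(expected, rel=1e-9)
        assert ra.rel_area[j] == pytest.approx(0.0597, abs=2e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        spec = np.exp(-0.5 * ((WL - 1450) / 40.0) ** 2) + 0.01
        for k in (0.1, 3.0, 42.0):
            np.testing.assert_allclose(
                aq.relative_areas(k * spec, WL).rel_area,
                aq.relative_areas(spec, WL).rel_area,
                atol=1e-14,
            )

    def test_zero_region_zero_area(self):
        spec = np.where(WL >= 1400.0, 1.0, 0.0)
        ra = aq.relative_areas(spec, WL)
        assert ra.rel_area[ra.coordinate_ids.index("C01")] == 0.0

    def test_nonpositive_total_raises(self):
        from aquagram.temperature import DegenerateSpectrumError

        with pytest.raises(DegenerateSpectrumError):
            aq.relative_areas(np.zeros(WL.size), WL)


class TestLoessSmoothing:
    def test_linear_data_reproduced(self):
        t = np.arange(20.0, 70.1, 2.0)
        y = 0.02 + 0.001 * t
        grid = np.arange(20.0, 70.01, 0.1)
        np.testing.assert_allclose(
            loess_smooth(t, y, grid), 0.02 + 0.001 * grid, atol=1e-6
        )

    def test_quadratic_data_reproduced_by_degree2(self):
        t = np.arange(20.0, 70.1, 2.0)
        y = 0.1 - 0.002 * t + 4e-5 * t**2
        grid = np.arange(20.0, 70.01, 0.1)
        np.testing.assert_allclose(
            loess_smooth(t, y, grid, degree=2), 0.1 - 0.002 * grid + 4e-5 * grid**2,
            atol=1e-6,
        )

    def test_smoothing_reduces_noise(self):
        rng = np.random.default_rng(1)
        t = np.arange(20.0, 70.1, 2.0)
        truth = 0.05 + 0.0008 * t
        noise_sd = 5e-4
        mae = []
        for _ in range(20):
            y = truth + noise_sd * rng.standard_normal(t.size)
            fit = loess_smooth(t, y, t)
            mae.append(np.abs(fit - truth).mean())
        assert np.mean(mae) < noise_sd

    def test_too_few_points_for_span(self):
        with pytest.raises(RangeError, match="span"):
            loess_smooth(np.arange(3.0), np.arange(3.0), np.array([1.0]), span=2.0)


def linear_curves(alpha, beta, ids=("C01",), lo=20.0, hi=70.0):
    grid = np.arange(lo, hi + 1e-9, 0.1)
    curves = np.vstack([alpha + beta * grid for _ in ids])
    return ReferenceCurves(list(ids), grid, curves, np.array([lo, hi]),
                           np.zeros((2, len(ids))))


class TestLocalCalibration:
    def test_linear_curve_recovered_exactly(self):
        calib = local_calibration(linear_curves(0.04, 5e-4), 28.0)
        assert calib.alpha[0] == pytest.approx(0.04, abs=1e-12)
        assert calib.beta[0] == pytest.approx(5e-4, abs=1e-14)
        assert calib.window == (26.0, 30.0)

    def test_constant_curve_flagged_ill_conditioned(self):
        calib = local_calibration(linear_curves(0.04, 0.0), 28.0)
        assert not calib.conditioned[0]
        with pytest.raises(ConditioningError, match="C01"):
            aq.temperature_equivalent(0.05, calib, "C01")

    def test_window_clipped_at_span_edge(self):
        calib = local_calibration(linear_curves(0.04, 5e-4), 20.0)
        assert calib.window == (20.0, 22.0)

    def test_window_outside_span_raises(self):
        with pytest.raises(RangeError, match="outside"):
            local_calibration(linear_curves(0.04, 5e-4), 80.0)


class TestTemperatureEquivalent:
    def test_fixed_point_returns_experiment_temperature(self):
        calib = local_calibration(linear_curves(0.04, 5e-4), 28.0)
        r_at_28 = 0.04 + 5e-4 * 28.0
        assert aq.temperature_equivalent(r_at_28, calib, "C01") == pytest.approx(28.0)

    def test_linear_inversion_recovers_true_temperature(self):
        calib = local_calibration(linear_curves(0.02, 8e-4), 28.0)
        for t_true in (26.5, 28.0, 29.5):
            r = 0.02 + 8e-4 * t_true
            assert aq.temperature_equivalent(r, calib, "C01") == pytest.approx(
                t_true, abs=1e-9
            )


class TestReferenceCurves:
    def test_needs_temperature_metadata(self):
        ds = aq.SpectralDataset(WL, np.ones((2, WL.size)) * np.exp(-((WL - 1450) / 40) ** 2),
                                pd.DataFrame({"group_label": ["a", "b"]}))
        with pytest.raises(RangeError, match="temperature_C"):
            aq.build_reference_curves(ds)

    def test_curves_pass_through_noiseless_raw_points(self, reference_ramp):
        curves = aq.build_reference_curves(reference_ramp)
        for j in range(12):
            at_raw = np.interp(curves.raw_temps, curves.T_grid, curves.curves[j])
            np.testing.assert_allclose(at_raw, curves.raw_rel_areas[:, j], atol=5e-6)


class TestTempAquagram:
    def test_self_consistency_at_28C(self, clean_rich_model, reference_ramp):
        """The reference's own 28 degC state maps back to ~28 degC."""
        exp = aq.simulate_temperature_series(clean_rich_model, temps_C=[28.0], n_scans=3)
        res = aq.temp_aquagram(exp, reference_ramp, experiment_T=28.0,
                               n_boot=200, seed=0)
        t = res.table[res.table["conditioned"]]
        assert np.abs(t["value"] - 28.0).max() < 0.2

    def test_group_values_independent_of_other_groups(
        self, groups_27_29, reference_ramp
    ):
        res_both = aq.temp_aquagram(groups_27_29, reference_ramp,
                                    experiment_T=28.0, n_boot=100, seed=0)
        only_27 = groups_27_29.take(
            np.flatnonzero((groups_27_29.meta["group_label"] == "T27").to_numpy())
        )
        res_one = aq.temp_aquagram(only_27, reference_ramp,
                                   experiment_T=28.0, n_boot=100, seed=0)
        a = res_both.values_for("T27").to_numpy()
        b = res_one.values_for("T27").to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_scale_invariance_of_values(self, groups_27_29, reference_ramp):
        res = aq.temp_aquagram(groups_27_29, reference_ramp, experiment_T=28.0,
                               n_boot=100, seed=0)
        scaled = groups_27_29.with_absorbance(3.7 * groups_27_29.absorbance)
        res_scaled = aq.temp_aquagram(scaled, reference_ramp, experiment_T=28.0,
                                      n_boot=100, seed=0)
        np.testing.assert_allclose(
            res.table["value"].to_numpy(), res_scaled.table["value"].to_numpy(),
            atol=1e-9,
        )

    def test_intervals_shrink_with_group_size(self, clean_rich_model, reference_ramp):
        import dataclasses

        noisy = dataclasses.replace(clean_rich_model, noise_sd=0.002)
        widths = {}
        for n in (3, 30):
            exp = aq.simulate_temperature_series(noisy, temps_C=[28.0], n_scans=n,
                                                 seed=5)
            res = aq.temp_aquagram(exp, reference_ramp, experiment_T=28.0,
                                   n_boot=300, seed=1)
            t = res.table[res.table["conditioned"]]
            widths[n] = (t["ucl95"] - t["lcl95"]).mean()
            res.validate()
        assert widths[30] < widths[3]

    def test_per_group_windows_cover_full_span(self, reference_ramp):
        """experiment_T=None calibrates each group at its own temperature."""
        res = aq.temp_aquagram(reference_ramp, reference_ramp, experiment_T=None,
                               n_boot=100, seed=0)
        t = res.table[res.table["conditioned"]]
        err = np.abs(
            t["value"] - t["group"].str.removeprefix("T").astype(float)
        )
        assert err.max() < 0.2

    def test_control_deltas_reported(self, clean_rich_model, reference_ramp):
        sol = aq.simulate_solute_series(
            clean_rich_model, concentrations_mM=[100.0], n_reps=2, n_scans=3,
            n_control_scans=6,
        )
        res = aq.temp_aquagram(sol, reference_ramp, experiment_T=28.0,
                               control_group="control", n_boot=100, seed=0)
        deltas = res.table[res.table["mode"] == "delta"]
        assert set(deltas["group"]) == {"c100", "control"}
        ctrl = deltas[deltas["group"] == "control"]
        np.testing.assert_allclose(ctrl["value"].dropna(), 0.0, atol=1e-12)
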
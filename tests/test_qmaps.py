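"""Parameter-map fitting: exact noiseless inversions, solver agreement,
pseudo-diffusion bounds and the B1 correction."""

import numpy as np
import pytest

from qmrep.phantom import B_VALUES, ECHO_TIMES, FLIP_ANGLES, TR_VFA
from qmrep.qmaps import (
    compute_hypoxia_score,
    default_hypoxia_combine,
    fit_adc,
    fit_all,
    fit_ivim_simplified,
    fit_r2star,
    fit_t1_vfa,
    flip_angle_correction,
)
from qmrep.volume import AcquisitionSeries, ImageVolume


def series_from_stack(stack, kind, axis, tr=None):
    vols = [ImageVolume(s, (1, 1, 1)) for s in stack]
    return AcquisitionSeries(vols, kind, axis, tr)


def ivim_signal(b, s0, d, f, dstar):
    return s0 * (f * np.exp(-b * dstar) + (1 - f) * np.exp(-b * d))


def dwi_series(d, f, s0=500.0, dstar_factor=10.0):
    d = np.asarray(d, dtype=float)
    f = np.asarray(f, dtype=float)
    stack = [ivim_signal(b, s0, d, f, dstar_factor * d) for b in B_VALUES]
    return series_from_stack(stack, "b-value", B_VALUES)


class TestAdc:
    def test_equal_signals_give_zero(self):
        stack = [np.full((2, 2, 2), 100.0) for _ in B_VALUES]
        adc = fit_adc(series_from_stack(stack, "b-value", B_VALUES))
        np.testing.assert_array_equal(adc.values, 0.0)

    def test_noiseless_monoexponential_inverts_exactly(self):
        d = np.full((3, 3, 3), 1.0e-3)
        adc = fit_adc(dwi_series(d, np.zeros_like(d)))
        np.testing.assert_allclose(adc.values, 1.0e-3, rtol=1e-12)

    def test_nonpositive_signal_flags_voxel_invalid(self):
        stack = [np.full((2, 2, 2), 100.0 * np.exp(-b * 1e-3)) for b in B_VALUES]
        stack[-1][0, 0, 0] = 0.0
        adc = fit_adc(series_from_stack(stack, "b-value", B_VALUES))
        assert not adc.valid[0, 0, 0]
        assert adc.valid.sum() == 7

    def test_identical_b_values_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            fit_adc(dwi_series(np.full((2, 2, 2), 1e-3), np.zeros((2, 2, 2))), b_pair=(50, 50))

    def test_missing_b_value_named_in_error(self):
        with pytest.raises(ValueError, match="123"):
            fit_adc(dwi_series(np.full((2, 2, 2), 1e-3), np.zeros((2, 2, 2))), b_pair=(123, 800))

    def test_adc_at_least_d_when_perfused(self):
        d = np.full((3, 3, 3), 1.2e-3)
        f = np.full((3, 3, 3), 0.10)
        series = dwi_series(d, f)
        adc = fit_adc(series)
        dfit, _ = fit_ivim_simplified(series)
        assert np.all(adc.values >= dfit.values)


class TestIvim:
    def test_zero_perfusion_recovers_exactly(self):
        d = np.full((3, 3, 3), 1.3e-3)
        dfit, ffit = fit_ivim_simplified(dwi_series(d, np.zeros_like(d)))
        np.testing.assert_allclose(dfit.values, 1.3e-3, rtol=1e-12)
        np.testing.assert_allclose(ffit.values, 0.0, atol=1e-12)

    def test_perfused_voxels_within_pseudodiffusion_bound(self):
        from .oracles import ivim_contamination_bounds

        d0, f0 = 1.2e-3, 0.10
        d = np.full((3, 3, 3), d0)
        f = np.full((3, 3, 3), f0)
        dfit, ffit = fit_ivim_simplified(dwi_series(d, f))
        d_bound, f_bound = ivim_contamination_bounds(f0, d0, 10 * d0, B_VALUES)
        assert np.all(np.abs(ffit.values - f0) < f_bound)
        assert np.all(np.abs(dfit.values - d0) < d_bound)
        # the bound is tight to within an order of magnitude
        assert np.abs(ffit.values - f0).max() > 0.2 * f_bound

    def test_matches_independent_polyfit_oracle(self, rng):
        stack = rng.uniform(50.0, 500.0, size=(len(B_VALUES), 2, 2, 2))
        stack[0] = 500.0
        series = series_from_stack(stack, "b-value", B_VALUES)
        dfit, ffit = fit_ivim_simplified(series)
        hi = B_VALUES >= 200
        for idx in np.ndindex(2, 2, 2):
            sig = stack[(slice(None),) + idx]
            slope, intercept = np.polyfit(B_VALUES[hi], np.log(sig[hi]), 1)
            assert dfit.values[idx] == pytest.approx(-slope, rel=1e-9)
            f_expect = np.clip(1.0 - np.exp(intercept) / sig[0], 0.0, 1.0)
            assert ffit.values[idx] == pytest.approx(f_expect, abs=1e-9)

    def test_negative_f_clamped_and_counted(self):
        # high-b intercept above S(0) => raw f < 0
        d = np.full((2, 2, 2), 1.0e-3)
        stack = [np.where(b == 0, 90.0, ivim_signal(b, 100.0, d, 0.0, 1e-2)) for b in B_VALUES]
        report = {}
        _, ffit = fit_ivim_simplified(
            series_from_stack(stack, "b-value", B_VALUES), report=report
        )
        np.testing.assert_array_equal(ffit.values, 0.0)
        assert report["f_clamped"] == 8

    def test_missing_b0_rejected(self):
        stack = [np.full((2, 2, 2), 100.0) for _ in B_VALUES[1:]]
        series = series_from_stack(stack, "b-value", B_VALUES[1:])
        with pytest.raises(ValueError, match="b = 0"):
            fit_ivim_simplified(series)


class TestHypoxiaScore:
    def _pmaps(self, d_vals, f_vals):
        from qmrep.volume import ParametricMap

        vol = ImageVolume(np.asarray(d_vals, dtype=float), (1, 1, 1))
        return (
            ParametricMap(vol, "D"),
            ParametricMap(vol.with_values(np.asarray(f_vals, dtype=float)), "f"),
        )

    def test_projection_combine_returns_d(self):
        d, f = self._pmaps(np.full((2, 2, 2), 1.1e-3), np.full((2, 2, 2), 0.1))
        hs = compute_hypoxia_score(d, f, combine=lambda dd, ff: dd)
        np.testing.assert_array_equal(hs.values, d.values)

    def test_constant_inputs_give_constant_score(self):
        d, f = self._pmaps(np.full((2, 2, 2), 1.1e-3), np.full((2, 2, 2), 0.1))
        hs = compute_hypoxia_score(d, f)
        assert np.unique(hs.values).size == 1

    def test_invalid_input_voxel_propagates(self):
        d_vals = np.full((2, 2, 2), 1.1e-3)
        d_vals[0, 0, 0] = np.nan
        d, f = self._pmaps(d_vals, np.full((2, 2, 2), 0.1))
        hs = compute_hypoxia_score(d, f)
        assert not hs.valid[0, 0, 0]

    def test_default_combine_monotone_decreasing_in_both(self):
        assert default_hypoxia_combine(1e-3, 0.05) > default_hypoxia_combine(2e-3, 0.05)
        assert default_hypoxia_combine(1e-3, 0.05) > default_hypoxia_combine(1e-3, 0.2)
        assert 0 < default_hypoxia_combine(2e-3, 0.1) < 1

    def test_phantom_noiseless_hs_matches_truth_pointwise(self, clean_study):
        truth = clean_study.truth
        maps = fit_all(clean_study.sessions[0], mask=truth.regions.wg)
        wg = truth.regions.wg
        expected = default_hypoxia_combine(
            maps["D"].values[wg], maps["f"].values[wg]
        )
        np.testing.assert_allclose(maps["HS"].values[wg], expected, rtol=1e-12)


class TestR2Star:
    def _series(self, r2s, s0=400.0):
        stack = [s0 * np.exp(-te * 1e-3 * r2s) for te in ECHO_TIMES]
        return series_from_stack(stack, "echo-time", ECHO_TIMES)

    def test_noiseless_inversion_to_1e6(self):
        r2s = np.full((3, 3, 3), 30.0)
        fit = fit_r2star(self._series(r2s))
        np.testing.assert_allclose(fit.values, 30.0, rtol=1e-6)

    def test_constant_signal_gives_zero_decay(self):
        fit = fit_r2star(self._series(np.zeros((2, 2, 2))))
        np.testing.assert_allclose(fit.values, 0.0, atol=1e-10)

    def test_fewer_than_three_echoes_rejected(self):
        stack = [np.ones((2, 2, 2)), np.ones((2, 2, 2)) * 0.5]
        with pytest.raises(ValueError, match="3 echo"):
            fit_r2star(series_from_stack(stack, "echo-time", ECHO_TIMES[:2]))

    def test_loglinear_initializer_agrees_with_nls_noiseless(self):
        r2s = np.full((2, 2, 2), 22.0)
        series = self._series(r2s)
        stack = series.stack().reshape(len(ECHO_TIMES), -1)
        slope = np.polyfit(ECHO_TIMES * 1e-3, np.log(stack), 1)[0]
        fit = fit_r2star(series)
        np.testing.assert_allclose(fit.values.ravel(), -slope, rtol=1e-9)


class TestFlipAngleCorrection:
    def test_perfect_field_gives_unity(self):
        b1 = ImageVolume(np.full((3, 3, 3), 90.0), (1, 1, 1))
        np.testing.assert_array_equal(flip_angle_correction(b1).values, 1.0)

    def test_81_degrees_gives_0_9(self):
        b1 = ImageVolume(np.full((2, 2, 2), 81.0), (1, 1, 1))
        np.testing.assert_allclose(flip_angle_correction(b1).values, 0.9)

    def test_nonpositive_actual_angle_invalid(self):
        vals = np.full((2, 2, 2), 90.0)
        vals[0, 0, 0] = 0.0
        kappa = flip_angle_correction(ImageVolume(vals, (1, 1, 1)))
        assert np.isnan(kappa.values[0, 0, 0])

    def test_coarse_map_resampled_to_reference(self):
        # affine field: trilinear resampling reproduces it exactly (interior)
        coarse = np.fromfunction(lambda i, j, k: 80.0 + 2.0 * i, (4, 4, 4))
        b1 = ImageVolume(coarse, (2.0, 2.0, 2.0))
        ref = ImageVolume(np.zeros((7, 7, 7)), (1.0, 1.0, 1.0))
        kappa = flip_angle_correction(b1, reference=ref)
        expected = (80.0 + np.arange(7)[:, None, None] * 1.0) / 90.0
        np.testing.assert_allclose(kappa.values[:, :4, :4], np.broadcast_to(expected[:, :1, :1], (7, 4, 4)), rtol=1e-12)


class TestT1Vfa:
    def _series(self, t1, m0=1000.0, kappa=1.0, angles=FLIP_ANGLES):
        e1 = np.exp(-TR_VFA / t1)
        stack = []
        for alpha in angles:
            a = np.deg2rad(alpha) * kappa
            stack.append(m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a)))
        return series_from_stack(stack, "flip-angle", angles, TR_VFA)

    def test_noiseless_inversion_to_1e6(self):
        t1 = np.full((3, 3, 3), 1400.0)
        fit = fit_t1_vfa(self._series(t1))
        np.testing.assert_allclose(fit.values, 1400.0, rtol=1e-6)

    def test_identity_correction_changes_nothing(self):
        t1 = np.full((2, 2, 2), 1100.0)
        series = self._series(t1)
        ones = ImageVolume(np.ones((2, 2, 2)), (1, 1, 1))
        a = fit_t1_vfa(series, kappa=None)
        b = fit_t1_vfa(series, kappa=ones)
        np.testing.assert_array_equal(a.values, b.values)

    def test_transmit_error_biases_t1_and_correction_recovers(self):
        t1 = np.full((2, 2, 2), 1400.0)
        series = self._series(t1, kappa=0.9)
        biased = fit_t1_vfa(series, kappa=None)
        assert np.all(np.abs(biased.values - 1400.0) / 1400.0 > 0.01)
        kappa = ImageVolume(np.full((2, 2, 2), 0.9), (1, 1, 1))
        corrected = fit_t1_vfa(series, kappa=kappa)
        np.testing.assert_allclose(corrected.values, 1400.0, rtol=1e-6)

    def test_two_angle_despot1_closed_form_equals_nls(self):
        t1_true = 1234.0
        angles = np.array([5.0, 20.0])
        series = self._series(np.full((2, 2, 2), t1_true), angles=angles)
        fit = fit_t1_vfa(series)
        s = series.stack().reshape(2, -1)
        a = np.deg2rad(angles)[:, None]
        y = s / np.sin(a)
        x = s / np.tan(a)
        e1 = (y[1] - y[0]) / (x[1] - x[0])
        t1_closed = -TR_VFA / np.log(e1)
        np.testing.assert_allclose(fit.values.ravel(), t1_closed, rtol=1e-9)
        np.testing.assert_allclose(fit.values, t1_true, rtol=1e-9)

    def test_fewer_than_two_angles_rejected(self):
        series = self._series(np.full((2, 2, 2), 1000.0), angles=np.array([15.0]))
        with pytest.raises(ValueError, match="2 flip"):
            fit_t1_vfa(series)


class TestFitDeterminismAndBias:
    def test_fits_are_deterministic(self, noisy_study):
        mask = noisy_study.truth.regions.wg
        a = fit_all(noisy_study.sessions[0], mask=mask)
        b = fit_all(noisy_study.sessions[0], mask=mask)
        for q in a:
            np.testing.assert_array_equal(a[q].values, b[q].values)

    def test_median_bias_below_2pct_at_snr_20(self):
        # constant-parameter grids, >= 1e4 voxels, noise at SNR 20 for the
        # weakest signal of each series
        rng = np.random.default_rng(2024)
        shape = (25, 25, 17)  # 10625 voxels
        from qmrep.phantom import rician

        d0, f0, r2s0, t10 = 1.3e-3, 0.08, 30.0, 1400.0
        d = np.full(shape, d0)
        f = np.full(shape, f0)
        dwi_clean = [ivim_signal(b, 500.0, d, f, 10 * d) for b in B_VALUES]
        sigma_dwi = min(s.min() for s in dwi_clean) / 20.0
        dwi = series_from_stack(
            [rician(s, sigma_dwi, rng) for s in dwi_clean], "b-value", B_VALUES
        )
        adc = fit_adc(dwi)
        dfit, ffit = fit_ivim_simplified(dwi)
        adc_true = np.log(
            ivim_signal(50, 500, d0, f0, 10 * d0) / ivim_signal(800, 500, d0, f0, 10 * d0)
        ) / 750.0
        assert abs(np.nanmedian(adc.values) - adc_true) / adc_true < 0.02
        assert abs(np.nanmedian(dfit.values) - d0) / d0 < 0.02
        assert abs(np.nanmedian(ffit.values) - f0) / f0 < 0.25  # f is noise-dominated

        megre_clean = [400.0 * np.exp(-te * 1e-3 * r2s0) for te in ECHO_TIMES]
        sigma_me = min(s for s in (m.min() for m in megre_clean)) / 20.0
        megre = series_from_stack(
            [rician(np.full(shape, s), sigma_me, rng) for s in megre_clean],
            "echo-time", ECHO_TIMES,
        )
        r2s = fit_r2star(megre)
        assert abs(np.nanmedian(r2s.values) - r2s0) / r2s0 < 0.02

        e1 = np.exp(-TR_VFA / t10)
        vfa_clean = [
            1000.0 * np.sin(np.deg2rad(al)) * (1 - e1) / (1 - e1 * np.cos(np.deg2rad(al)))
            for al in FLIP_ANGLES
        ]
        sigma_vfa = min(vfa_clean) / 20.0
        vfa = series_from_stack(
            [rician(np.full(shape, s), sigma_vfa, rng) for s in vfa_clean],
            "flip-angle", FLIP_ANGLES, TR_VFA,
        )
        t1 = fit_t1_vfa(vfa)
        assert abs(np.nanmedian(t1.values) - t10) / t10 < 0.02
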
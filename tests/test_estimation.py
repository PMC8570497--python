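"""Estimation pipeline: derivatives, peaks, regressions, tau_cl recovery."""

import numpy as np
import pytest
from scipy import stats

import prespike as pk
from prespike.estimation import (PrespikeNotFoundError, SubtractionProtocol,
                                 analyze_recording, compare_derivative_models,
                                 differentiate, epoch_average_series,
                                 estimate_tau_cl_peak_ratio,
                                 estimate_tau_cl_slope,
                                 extract_derivative_extrema,
                                 extract_prespike_features,
                                 derive_cleft_parameters,
                                 fit_train_derivatives,
                                 isolate_calcium_prespike,
                                 regress_prespike_vs_derivative)
from prespike.timeseries import TimeSeries


class TestDifferentiate:
    def test_linear_ramp_constant_slope(self):
        s = TimeSeries(3.0 * np.arange(100) * 1e-4, 1e-4, 0.0, "V")
        d = differentiate(s, 1)
        assert np.allclose(d.values, 3.0, rtol=1e-9)

    def test_sine_second_derivative(self):
        # 50 samples per period
        f = 200.0
        dt = 1.0 / (50 * f)
        t = dt * np.arange(500)
        s = TimeSeries(np.sin(2 * np.pi * f * t), dt, 0.0, "V")
        d2 = differentiate(s, 2)
        w = 2 * np.pi * f
        expected = -(w**2) * np.sin(w * t)
        assert np.allclose(d2.values[10:-10], expected[10:-10], atol=0.01 * w**2)

    def test_wider_window_smooths_noise(self):
        rng = np.random.default_rng(0)
        s = TimeSeries(rng.normal(0, 1, 2000), 1e-4, 0.0, "V")
        v_small = differentiate(s, 1, smooth_window=5).values.var()
        v_large = differentiate(s, 1, smooth_window=21).values.var()
        assert v_large < v_small

    def test_window_too_small_rejected(self):
        s = TimeSeries(np.arange(50, dtype=float), 1e-4, 0.0, "V")
        with pytest.raises(ValueError, match="too small"):
            differentiate(s, 2, smooth_window=3)


def resistive_epoch(params, noise_sd=0.0, seed=0, dt=20e-6,
                    fwhm=0.4e-3, amplitude=0.110):
    shape = pk.APShape(fwhm=fwhm, amplitude=amplitude, t_peak=2e-3)
    ap = pk.make_action_potential(shape, dt=dt, duration=6e-3)
    clean = pk.predict_vc_prespike(ap, params, "resistive")
    rng = np.random.default_rng(seed)
    noisy = clean.with_values(clean.values + rng.normal(0, noise_sd, len(clean)))
    return ap, noisy


class TestPrespikeFeatures:
    def test_noiseless_resistive_peaks_match_second_derivative(self, calyx_params):
        ap, pre = resistive_epoch(calyx_params)
        feats = extract_prespike_features(pre)
        assert feats.t_neg < feats.t_pos
        d2 = differentiate(ap, 2)
        t_d2_max = d2.times[int(np.argmax(d2.values))]
        t_d2_min = d2.times[int(np.argmin(d2.values))]
        # prespike = -g*tau^2*AP'': its neg/pos peaks sit at AP'' max/min
        assert feats.t_neg == pytest.approx(t_d2_max, abs=2 * ap.dt)
        assert feats.t_pos == pytest.approx(t_d2_min, abs=2 * ap.dt)
        assert feats.peak_delay == pytest.approx(t_d2_min - t_d2_max, abs=2 * ap.dt)

    def test_flat_trace_raises(self):
        flat = TimeSeries(np.zeros(100), 1e-4, 0.0, "A")
        with pytest.raises(PrespikeNotFoundError, match="no prespike"):
            extract_prespike_features(flat)

    def test_peak_amplitudes_stable_at_snr_10(self, calyx_params):
        ap, clean = resistive_epoch(calyx_params)
        ref = extract_prespike_features(clean)
        sd = abs(ref.neg_peak) / 10.0
        negs, poss = [], []
        for seed in range(100):
            _, noisy = resistive_epoch(calyx_params, noise_sd=sd, seed=seed)
            f = extract_prespike_features(noisy)
            negs.append(f.neg_peak)
            poss.append(f.pos_peak)
        assert np.mean(negs) == pytest.approx(ref.neg_peak, rel=0.05)
        assert np.mean(poss) == pytest.approx(ref.pos_peak, rel=0.05)


class TestRegression:
    def make_train_fits(self, params, scenario, seed=None, noise=15e-12):
        shape = pk.APShape(fwhm=0.4e-3, amplitude=0.110, t_peak=2e-3)
        proto = pk.TrainProtocol(n_stimuli=8, interval=10e-3,
                                 amplitude_decay=0.96, broadening=1.05)
        v = pk.make_ap_train(shape, proto, dt=20e-6)
        clean = pk.predict_vc_prespike(v, params, scenario).values
        if seed is None:
            vals = clean
        else:
            rng = np.random.default_rng(seed)
            vals = clean + rng.normal(0, noise, clean.size)
        return fit_train_derivatives(v, v.with_values(vals, unit="A"),
                                     epoch=10e-3)

    def test_noiseless_resistive_fit_is_exact(self, calyx_params):
        fit1, fit2 = self.make_train_fits(calyx_params, "resistive")
        truth = calyx_params.g_cl * calyx_params.tau_cl**2
        assert fit2.pearson_r == pytest.approx(-1.0, abs=1e-4)
        assert fit2.slope == pytest.approx(-truth, rel=0.02)
        assert fit2.deviation_at_origin < 0.02 * truth * 1e7  # essentially zero
        assert abs(fit2.pearson_r) > abs(fit1.pearson_r)

    def test_capacitive_data_favor_first_derivative(self, calyx_params):
        fit1, fit2 = self.make_train_fits(calyx_params, "capacitive")
        assert abs(fit1.pearson_r) > abs(fit2.pearson_r)
        assert fit1.deviation_at_origin < fit2.deviation_at_origin

    def test_single_ap_flagged_underdetermined(self, calyx_params):
        ap, pre = resistive_epoch(calyx_params)
        f = extract_prespike_features(pre)
        d = extract_derivative_extrema(differentiate(ap, 2))
        fit = regress_prespike_vs_derivative([f], [d])
        assert fit.underdetermined
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_regressor_rejected(self, calyx_params):
        ap, pre = resistive_epoch(calyx_params)
        f = extract_prespike_features(pre)
        with pytest.raises(ValueError, match="degenerate"):
            regress_prespike_vs_derivative([f, f], [(1.0, 1.0), (1.0, 1.0)])


class TestModelComparison:
    def test_identical_lists_give_null_result(self, calyx_params):
        fit1, fit2 = TestRegression().make_train_fits(calyx_params, "resistive",
                                                      seed=1)
        c = compare_derivative_models([fit1, fit1, fit1], [fit1, fit1, fit1])
        assert c.t_r == 0.0 and c.p_r == 1.0
        assert c.t_deviation == 0.0 and c.p_deviation == 1.0

    def test_three_pair_textbook_oracle(self):
        """Paired t on three hand-made fit pairs vs the closed formula
        t = mean(d) / (sd(d)/sqrt(n))."""
        def fit(r, dev):
            return pk.DerivativeFit(slope=-1.0, intercept=dev, pearson_r=r,
                                    deviation_at_origin=dev, n_points=10)
        r1, r2 = [-0.90, -0.95, -0.93], [-0.97, -0.99, -0.96]
        d1, d2 = [3.0, 2.0, 4.0], [1.0, 0.5, 0.8]
        c = compare_derivative_models(
            [fit(r, d) for r, d in zip(r1, d1)],
            [fit(r, d) for r, d in zip(r2, d2)])
        diff = np.array(r1) - np.array(r2)
        t_expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(3))
        assert c.t_r == pytest.approx(t_expected, rel=1e-9)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=2)
        assert c.p_r == pytest.approx(p_expected, rel=1e-9)

    def test_unequal_counts_rejected(self, calyx_params):
        f1, f2 = TestRegression().make_train_fits(calyx_params, "resistive", seed=1)
        with pytest.raises(ValueError, match="equal"):
            compare_derivative_models([f1], [f2, f2])


def p5_recording(params, tau_ca=0.217e-3, noise_sd=0.0, seed=0, n=10,
                 skip=2, use=8, amplitude=-1.9e-9):
    shape = pk.APShape(fwhm=0.5e-3, amplitude=0.120, t_peak=2e-3)
    proto = pk.TrainProtocol(n_stimuli=n, interval=10e-3)
    v = pk.make_ap_train(shape, proto, dt=20e-6)
    ica = pk.make_calcium_train(amplitude, tau_ca, shape, proto, dt=20e-6)
    rs = pk.synthesize_paired_recording(v, ica, params, noise_sd=noise_sd,
                                        seed=seed)
    sp = SubtractionProtocol(skip=skip, use=use, epoch=10e-3)
    return rs, sp, ica


class TestIsolation:
    def test_no_calcium_gives_zero(self, calyx_params):
        shape = pk.APShape(fwhm=0.5e-3, amplitude=0.120, t_peak=2e-3)
        proto = pk.TrainProtocol(n_stimuli=10, interval=10e-3)
        v = pk.make_ap_train(shape, proto, dt=20e-6)
        zero_ica = v.with_values(np.zeros(len(v)), unit="A")
        rs = pk.synthesize_paired_recording(v, zero_ica, calyx_params)
        sp = SubtractionProtocol(skip=2, use=8, epoch=10e-3)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        ap_scale = np.abs(pk.predict_vc_prespike(v, calyx_params,
                                                 "resistive").values).max()
        assert np.abs(delta.values).max() < 1e-9 * ap_scale

    def test_resistive_identity(self, calyx_params):
        rs, sp, ica = p5_recording(calyx_params)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        ica_ep = epoch_average_series(ica, sp)
        expected = -calyx_params.tau_cl * np.gradient(ica_ep.values, ica_ep.dt,
                                                      edge_order=2)
        assert np.allclose(delta.values[2:-2], expected[2:-2],
                           atol=5e-3 * np.abs(expected).max())

    def test_epoch_averaging_reduces_noise_sqrt_n(self, calyx_params):
        sd = 50e-12
        rs, sp, _ = p5_recording(calyx_params, noise_sd=sd, seed=3, n=27,
                                 skip=2, use=25)
        rs0, sp0, _ = p5_recording(calyx_params, noise_sd=sd, seed=3, n=27,
                                   skip=2, use=25)
        # noise-only region: compare single-epoch vs 25-epoch average noise
        delta25 = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        sp1 = SubtractionProtocol(skip=2, use=1, epoch=10e-3)
        delta1 = isolate_calcium_prespike(rs0.active_sweeps, rs0.passive_sweeps, sp1)
        quiet = slice(int(7e-3 / delta1.dt), None)  # tail of the epoch, no signal
        ratio = delta1.values[quiet].std() / delta25.values[quiet].std()
        assert ratio == pytest.approx(5.0, rel=0.35)

    def test_misaligned_sweeps_rejected(self, calyx_params):
        rs, sp, _ = p5_recording(calyx_params)
        bad = TimeSeries(rs.passive_sweeps[0].values[:-7], rs.v_pre.dt, 0.0, "A")
        with pytest.raises(ValueError, match="aligned"):
            isolate_calcium_prespike(rs.active_sweeps, [bad], sp)


class TestTauEstimators:
    def test_peak_ratio_round_trip(self, calyx_params):
        rs, sp, ica = p5_recording(calyx_params, tau_ca=0.25e-3, amplitude=-2e-9)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        ica_ep = epoch_average_series(ica, sp)
        tau_cl, tau_ca = estimate_tau_cl_peak_ratio(delta, ica_ep)
        assert tau_cl == pytest.approx(calyx_params.tau_cl, rel=0.02)
        assert tau_ca == pytest.approx(0.25e-3, rel=0.02)

    def test_cleft_fraction_scales_estimate(self, calyx_params):
        rs, sp, ica = p5_recording(calyx_params)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        ica_ep = epoch_average_series(ica, sp)
        t_full, _ = estimate_tau_cl_peak_ratio(delta, ica_ep, cleft_fraction=1.0)
        t_frac, _ = estimate_tau_cl_peak_ratio(delta, ica_ep, cleft_fraction=2 / 3)
        assert t_frac == pytest.approx(1.5 * t_full, rel=1e-9)

    def test_flat_delta_raises(self, calyx_params):
        flat = TimeSeries(np.zeros(500), 2e-5, 0.0, "A")
        ica = TimeSeries(np.ones(500), 2e-5, 0.0, "A")
        with pytest.raises(PrespikeNotFoundError):
            estimate_tau_cl_peak_ratio(flat, ica)

    def test_slope_round_trip_noiseless(self, calyx_params):
        rs, sp, ica = p5_recording(calyx_params)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        ica_ep = epoch_average_series(ica, sp)
        tau, lag, r = estimate_tau_cl_slope(delta, ica_ep)
        assert tau == pytest.approx(calyx_params.tau_cl, rel=0.01)
        assert abs(lag) < ica_ep.dt
        assert r > 0.999

    def test_slope_recovers_imposed_shift(self, calyx_params):
        rs, sp, ica = p5_recording(calyx_params)
        delta = isolate_calcium_prespike(rs.active_sweeps, rs.passive_sweeps, sp)
        shift = 3  # samples = 60 us at dt 20 us
        shifted = TimeSeries(np.roll(delta.values, shift), delta.dt, 0.0, "A")
        ica_ep = epoch_average_series(ica, sp)
        tau, lag, r = estimate_tau_cl_slope(shifted, ica_ep, max_lag=200e-6)
        assert lag == pytest.approx(shift * delta.dt, abs=delta.dt)
        assert tau == pytest.approx(calyx_params.tau_cl, rel=0.05)

    def test_noise_only_flagged(self):
        rng = np.random.default_rng(0)
        delta = TimeSeries(rng.normal(0, 1e-12, 500), 2e-5, 0.0, "A")
        ica = pk.make_calcium_current(-2e-9, 5e-3, 0.25e-3, dt=2e-5,
                                      duration=500 * 2e-5 - 2e-5)
        tau, lag, r = estimate_tau_cl_slope(delta, ica)
        assert abs(r) < 0.5  # reported correlation exposes the non-detection


class TestDeriveParameters:
    def test_algebraic_example(self):
        g, c, r_ex = derive_cleft_parameters(0.1e-15, 10e-6, h=30e-9)
        assert g == pytest.approx(1.0e-6, rel=1e-12)
        assert c == pytest.approx(10e-12, rel=1e-12)
        assert r_ex * 1e2 == pytest.approx(75.4, rel=0.01)

    def test_tau_scaling(self):
        g1, c1, _ = derive_cleft_parameters(0.1e-15, 10e-6)
        g2, c2, _ = derive_cleft_parameters(0.1e-15, 20e-6)
        assert g2 == pytest.approx(g1 / 4)
        assert c2 == pytest.approx(c1 / 2)

    def test_zero_tau_rejected(self):
        with pytest.raises(ValueError, match="tau_cl"):
            derive_cleft_parameters(0.1e-15, 0.0)


class TestFullPipeline:
    def test_noiseless_chain_recovers_circuit(self, calyx_params):
        rs, sp, _ = p5_recording(calyx_params)
        res = analyze_recording(rs, sp)
        assert res.tau_cl_slope == pytest.approx(calyx_params.tau_cl, rel=0.05)
        assert res.g_cl == pytest.approx(calyx_params.g_cl, rel=0.15)
        assert res.c_cl == pytest.approx(calyx_params.c_cl, rel=0.15)
        assert res.R_ex_given_h == pytest.approx(
            8 * np.pi * 30e-9 / calyx_params.g_cl, rel=0.15)
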
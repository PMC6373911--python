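"""Feature extraction: energy, log-linear fits, baselines, slopes, exclusions."""

import copy

import numpy as np
import pytest

from cpetcf.features import (
    PREDICTOR_FIELDS,
    LogLinearFit,
    VE_REF_LMIN,
    baseline_ventilation,
    build_feature_vector,
    fit_loglinear_ve_vo2,
    total_energy,
    ventilatory_slopes,
    vo2_at_fixed_ve,
    vo2_ve_ratio_series,
)
from cpetcf.trace import CPETTrace


def _trace_from(t, work, vo2, ve=None, bf=None, vt=None, ramp_start=180.0, exh=None):
    n = t.size
    exh = t[-1] if exh is None else exh
    if vt is None:
        vt = np.full(n, 0.8)
    if ve is None and bf is None:
        bf = np.full(n, 20.0)
        ve = bf * vt
    elif bf is None:
        bf = ve / vt
    return CPETTrace(
        time=t,
        work_rate=work,
        vo2=vo2,
        vco2=0.85 * vo2,
        ve=ve,
        bf=bf,
        vt=vt,
        warmup_start_s=t[0],
        ramp_start_s=ramp_start,
        exhaustion_s=exh,
        recovery_end_s=t[-1],
    )


class TestTotalEnergy:
    def test_constant_power(self):
        t = np.arange(0.0, 61.0)
        tr = _trace_from(t, np.full(t.size, 100.0), np.full(t.size, 1.0), ramp_start=5, exh=60.0)
        assert total_energy(tr) == pytest.approx(6.0, rel=1e-12)  # 100 W * 60 s

    def test_zero_work(self):
        t = np.arange(0.0, 61.0)
        tr = _trace_from(t, np.zeros(t.size), np.full(t.size, 1.0), ramp_start=5, exh=60.0)
        assert total_energy(tr) == 0.0

    def test_linear_ramp_closed_form(self):
        t = np.arange(0.0, 601.0)
        tr = _trace_from(t, t / 3.0, np.full(t.size, 1.0), ramp_start=5, exh=600.0)
        # ramp 0 -> 200 W over 600 s: 0.5 * 200 * 600 W*s = 60 kJ
        assert total_energy(tr) == pytest.approx(60.0, rel=1e-12)

    def test_additive_over_partition_and_resampling_invariant(self, zero_noise_record):
        from cpetcf.trace import resample_uniform

        tr = zero_noise_record.trace
        full = total_energy(tr)
        # piecewise-linear work profile: halving the grid must not change the integral
        fine = resample_uniform(tr, 0.5)
        assert total_energy(fine) == pytest.approx(full, rel=1e-9)


class TestLogLinearFit:
    @staticmethod
    def _exp_trace(alpha=2.0, beta=0.5, n=700):
        t = np.arange(float(n))
        vo2 = np.linspace(0.4, 2.0, n)
        ve = np.exp(alpha + beta * vo2)
        return _trace_from(t, np.linspace(15, 180, n), vo2, ve=ve, exh=t[-1] - 1)

    def test_exact_model_recovered_to_machine_precision(self):
        fit = fit_loglinear_ve_vo2(self._exp_trace())
        assert fit.alpha == pytest.approx(2.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_warmup_corruption_ignored(self):
        clean = self._exp_trace()
        corrupted = copy.deepcopy(clean)
        corrupted.ve = np.where(corrupted.time < 180.0, corrupted.ve * 10, corrupted.ve)
        corrupted.bf = corrupted.ve / corrupted.vt
        f1, f2 = fit_loglinear_ve_vo2(clean), fit_loglinear_ve_vo2(corrupted)
        assert f1.alpha == f2.alpha and f1.beta == f2.beta

    def test_exclusion_window_perturbation_invariance(self, noisy_record):
        """Perturbing samples outside [start+180, exh-60] never changes the fits."""
        rec = copy.deepcopy(noisy_record)
        tr = rec.trace
        outside = (tr.time < tr.ramp_start_s) | (tr.time > tr.exhaustion_s - 60.0)
        for ch in ("ve", "bf", "vt", "vo2"):
            arr = getattr(tr, ch).copy()
            arr[outside] *= 3.0
            setattr(tr, ch, arr)
        f0 = fit_loglinear_ve_vo2(noisy_record.trace)
        f1 = fit_loglinear_ve_vo2(tr)
        assert (f0.alpha, f0.beta) == (f1.alpha, f1.beta)
        assert ventilatory_slopes(noisy_record.trace) == ventilatory_slopes(tr)

    def test_matches_normal_equations_oracle(self, noisy_record):
        tr = noisy_record.trace
        fit = fit_loglinear_ve_vo2(tr)
        m = (tr.time >= tr.ramp_start_s) & (tr.time <= tr.exhaustion_s - 60.0)
        X = np.column_stack([np.ones(m.sum()), tr.vo2[m]])
        # brute-force normal equations: (X'X)^-1 X'y
        ab = np.linalg.solve(X.T @ X, X.T @ np.log(tr.ve[m]))
        assert fit.alpha == pytest.approx(ab[0], abs=1e-10)
        assert fit.beta == pytest.approx(ab[1], abs=1e-10)

    def test_window_too_short_errors(self):
        tr = self._exp_trace(n=700)
        tr.exhaustion_s = 185.0  # window [180, 125] is empty
        with pytest.raises(ValueError, match="window"):
            fit_loglinear_ve_vo2(tr)


class TestVo2AtFixedVe:
    def test_reference_hit_at_intercept(self):
        fit = LogLinearFit(alpha=float(np.log(VE_REF_LMIN)), beta=0.5, r2=1.0, window=(0, 1))
        assert vo2_at_fixed_ve(fit) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        fit = LogLinearFit(alpha=float(np.log(10.0)), beta=0.5, r2=1.0, window=(0, 1))
        expected = (np.log(49.32) - np.log(10.0)) / 0.5
        assert vo2_at_fixed_ve(fit, 49.32) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.191, abs=5e-4)

    def test_forward_model_inverse_consistency(self):
        fit = LogLinearFit(alpha=1.3, beta=0.9, r2=1.0, window=(0, 1))
        v = vo2_at_fixed_ve(fit, 40.0)
        assert np.exp(fit.alpha + fit.beta * v) == pytest.approx(40.0, abs=1e-10)

    def test_degenerate_beta_errors(self):
        fit = LogLinearFit(alpha=1.0, beta=0.0, r2=0.0, window=(0, 1))
        with pytest.raises(ZeroDivisionError):
            vo2_at_fixed_ve(fit)


class TestBaselinesAndSlopes:
    def test_constant_warmup_means(self):
        t = np.arange(0.0, 400.0)
        tr = _trace_from(t, np.full(t.size, 15.0), np.full(t.size, 0.5), exh=390.0)
        bf0, vt0 = baseline_ventilation(tr)
        assert bf0 == pytest.approx(20.0, rel=1e-12)
        assert vt0 == pytest.approx(0.8, rel=1e-12)

    def test_linear_bf_mean_is_midpoint(self):
        t = np.arange(0.0, 400.0)
        n = t.size
        bf = np.where(t < 180, 15 + 10 * t / 179.0, 25.0)  # 15 -> 25 over warm-up
        vt = np.full(n, 0.8)
        tr = _trace_from(t, np.full(n, 15.0), np.full(n, 0.5), bf=bf, vt=vt, exh=390.0)
        tr.ve = tr.bf * tr.vt
        assert baseline_ventilation(tr)[0] == pytest.approx(20.0, rel=1e-12)

    def test_slopes_of_constructed_channels(self):
        t = np.arange(0.0, 700.0)
        vo2 = np.linspace(0.4, 2.0, t.size)
        bf = 10 + 5 * vo2
        vt = np.full(t.size, 0.8)
        tr = _trace_from(t, np.linspace(15, 180, t.size), vo2, bf=bf, vt=vt, exh=t[-1] - 1)
        tr.ve = tr.bf * tr.vt
        bfs, vts = ventilatory_slopes(tr)
        assert bfs == pytest.approx(5.0, rel=1e-10)
        assert vts == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_patient_recovers_generator_baselines(self, zero_noise_record):
        rec = zero_noise_record
        bf0, vt0 = baseline_ventilation(rec.trace)
        assert bf0 == pytest.approx(rec.truth.params["baseline_bf"], rel=1e-8)
        assert vt0 == pytest.approx(rec.truth.params["baseline_vt"], rel=1e-8)

    def test_slopes_match_ols_oracle(self, noisy_record):
        tr = noisy_record.trace
        m = (tr.time >= tr.ramp_start_s) & (tr.time <= tr.exhaustion_s - 60.0)
        X = np.column_stack([np.ones(m.sum()), tr.vo2[m]])
        bfs, vts = ventilatory_slopes(tr)
        assert bfs == pytest.approx(np.linalg.solve(X.T @ X, X.T @ tr.bf[m])[1], abs=1e-10)
        assert vts == pytest.approx(np.linalg.solve(X.T @ X, X.T @ tr.vt[m])[1], abs=1e-10)


class TestFeatureVector:
    def test_seven_predictors(self, noisy_record):
        fv = build_feature_vector(noisy_record)
        assert len(PREDICTOR_FIELDS) == 7
        assert fv.predictors().shape == (7,)

    def test_deterministic(self, noisy_record):
        a = build_feature_vector(noisy_record).predictors()
        b = build_feature_vector(noisy_record).predictors()
        np.testing.assert_array_equal(a, b)

    def test_noiseless_closed_loop_with_generator(self, zero_noise_record):
        rec = zero_noise_record
        fv = build_feature_vector(rec)
        p = rec.truth.params
        assert fv.baseline_bf == pytest.approx(p["baseline_bf"], rel=1e-8)
        assert fv.baseline_vt == pytest.approx(p["baseline_vt"], rel=1e-8)
        # VO2 at the reference ventilation from the generator's own (alpha, beta)
        expected = (np.log(VE_REF_LMIN) - p["alpha"]) / p["beta"]
        assert fv.vo2_at_fixed_ve == pytest.approx(expected, rel=1e-8)
        assert fv.fvc == rec.fvc and fv.fev1 == rec.fev1


class TestRatioSeries:
    def test_proportional_channels_give_constant_ratio(self):
        t = np.arange(0.0, 300.0)
        ve = np.linspace(10, 60, t.size)
        tr = _trace_from(t, np.full(t.size, 15.0), 0.04 * ve, ve=ve, exh=290.0)
        s = vo2_ve_ratio_series(tr)
        np.testing.assert_allclose(s.to_numpy(), 0.04, rtol=1e-12)

    def test_unit_rescaling_invariance(self, noisy_record):
        tr = copy.deepcopy(noisy_record.trace)
        base = vo2_ve_ratio_series(tr).to_numpy()
        tr.vo2 = tr.vo2 / 60.0  # L/min -> L/s on both channels
        tr.ve = tr.ve / 60.0
        tr.bf = tr.bf / 60.0  # keep identity VE = BF*VT
        np.testing.assert_allclose(vo2_ve_ratio_series(tr).to_numpy(), base, rtol=1e-12)

    def test_matches_elementwise_division(self, noisy_record):
        tr = noisy_record.trace
        np.testing.assert_array_equal(vo2_ve_ratio_series(tr).to_numpy(), tr.vo2 / tr.ve)
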
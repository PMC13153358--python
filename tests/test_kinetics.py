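"""Exponential-decay, recovery and steady-state fitting."""

import numpy as np
import pytest

from amparcore import (
    CurrentTrace,
    KineticsError,
    build_recovery_envelope,
    fit_exponential_decay,
    fit_recovery,
    hh_recovery_model,
    make_current_trace,
    read_trace,
    steady_state_ratio,
    two_sample_ttest,
    write_trace,
)


class TestCurrentTrace:
    def test_grid_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            CurrentTrace(np.array([0.0, 0.1, 0.5]), np.zeros(3))
        with pytest.raises(ValueError, match="increasing"):
            CurrentTrace(np.array([0.0, -0.1, -0.2]), np.zeros(3))

    def test_io_roundtrip(self, tmp_path):
        fx = make_current_trace("desensitization", {"tau": 5.0}, noise_sd=0.01, seed=1)
        path = write_trace(fx.trace, tmp_path / "trace.tsv")
        back = read_trace(path)
        np.testing.assert_allclose(back.time, fx.trace.time)
        np.testing.assert_allclose(back.current, fx.trace.current)
        assert back.annotations == {
            k: tuple(v) for k, v in fx.trace.annotations.items()
        }


class TestExponentialDecay:
    def test_noiseless_exact_recovery(self):
        fx = make_current_trace("desensitization", {"tau": 5.0}, dt=0.05)
        fit = fit_exponential_decay(fx.trace)
        assert fit.tau == pytest.approx(5.0, abs=1e-3)
        assert fit.converged

    def test_glua1a2_desensitization_under_noise(self):
        fx = make_current_trace(
            "desensitization", {"tau": 7.64}, noise_sd=0.02, dt=0.05, seed=4
        )
        fit = fit_exponential_decay(fx.trace)
        assert fit.tau == pytest.approx(7.64, rel=0.05)

    def test_deactivation_window(self):
        fx = make_current_trace("deactivation", {"tau": 3.45}, dt=0.02)
        t_off = fx.trace.annotations["application"][1]
        fit = fit_exponential_decay(fx.trace, window=(t_off, fx.trace.time[-1]))
        assert fit.tau == pytest.approx(3.45, rel=1e-4)

    def test_constant_trace_rejected(self):
        t = np.arange(0.0, 50.0, 0.1)
        trace = CurrentTrace(t, np.full_like(t, -3.0), {"application": (5.0, 45.0)})
        with pytest.raises(KineticsError, match="decaying"):
            fit_exponential_decay(trace)

    def test_too_few_samples_rejected(self):
        t = np.arange(0.0, 0.5, 0.1)
        trace = CurrentTrace(t, -np.exp(-t), {"application": (0.0, 0.4)})
        with pytest.raises(KineticsError, match="samples"):
            fit_exponential_decay(trace)

    def test_scaling_invariance(self):
        fx = make_current_trace("desensitization", {"tau": 7.64}, noise_sd=0.02, seed=9)
        fit1 = fit_exponential_decay(fx.trace)
        scaled = CurrentTrace(
            fx.trace.time, 37.0 * fx.trace.current, fx.trace.annotations
        )
        fit2 = fit_exponential_decay(scaled)
        # identical up to optimizer stopping tolerance
        assert fit2.tau == pytest.approx(fit1.tau, rel=1e-5)


class TestHHModel:
    def test_t_zero_is_one(self):
        assert hh_recovery_model(0.0, 20.0, 75.0, 1.02) == pytest.approx(1.0)

    def test_long_time_limit_is_imax(self):
        assert hh_recovery_model(1e9, 20.0, 75.0, 1.02) == pytest.approx(20.0)

    def test_m_one_reduces_to_single_exponential(self):
        t = np.linspace(0.0, 500.0, 300)
        hh = hh_recovery_model(t, 20.0, 75.0, 1.0)
        single = 20.0 - (20.0 - 1.0) * np.exp(-t / 75.0)
        np.testing.assert_allclose(hh, single, rtol=1e-12, atol=1e-12)

    def test_monotone_nondecreasing_in_t(self):
        t = np.linspace(0.0, 2000.0, 500)
        for m in (0.5, 1.0, 2.0, 4.0):
            y = hh_recovery_model(t, 30.0, 75.0, m)
            assert np.all(np.diff(y) >= -1e-12)

    def test_domain_violations(self):
        with pytest.raises(KineticsError):
            hh_recovery_model(1.0, 20.0, -5.0, 1.0)
        with pytest.raises(KineticsError):
            hh_recovery_model(1.0, 0.5, 75.0, 1.0)


class TestRecoveryFit:
    def test_noiseless_roundtrip_four_significant_digits(self):
        fx = make_current_trace(
            "recovery_envelope",
            {"tau_recdes": 75.0, "m": 1.02, "i_max": 30.0,
             "intervals": [5, 10, 20, 50, 100, 200, 400, 800]},
        )
        fit = fit_recovery(fx.envelope_t, fx.envelope_residual)
        assert fit.tau_recdes == pytest.approx(75.0, rel=1e-4)
        assert fit.m == pytest.approx(1.02, rel=1e-4)
        assert fit.i_max == pytest.approx(30.0, rel=1e-4)

    def test_conditioning_normalization_roundtrip(self):
        fx = make_current_trace(
            "recovery_envelope", {"tau_recdes": 105.0, "m": 1.3, "i_max": 25.0}
        )
        fit = fit_recovery(
            fx.envelope_t, fx.envelope_conditioning, normalized_to="conditioning"
        )
        assert fit.tau_recdes == pytest.approx(105.0, rel=1e-4)
        assert fit.m == pytest.approx(1.3, rel=1e-3)

    def test_envelope_built_from_two_pulse_traces(self):
        fx = make_current_trace(
            "recovery_envelope", {"tau_recdes": 75.0, "m": 1.02, "i_max": 30.0}
        )
        t, i = build_recovery_envelope(fx.traces)
        np.testing.assert_allclose(t, np.sort(fx.params["intervals"]))
        np.testing.assert_allclose(i, fx.envelope_conditioning, rtol=1e-10)

    def test_m_one_data_recovers_m_near_one(self):
        fx = make_current_trace(
            "recovery_envelope", {"tau_recdes": 60.0, "m": 1.0, "i_max": 15.0,
                                  "intervals": [10, 25, 60, 120, 300, 700]},
        )
        fit = fit_recovery(fx.envelope_t, fx.envelope_residual)
        assert fit.m == pytest.approx(1.0, abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(KineticsError, match=">= 4"):
            fit_recovery([10.0, 20.0, 50.0], [1.0, 2.0, 3.0])

    def test_stochastic_recovery_study(self):
        """2% noise, 8 points: median tau error < 10%, m error < 25%."""
        tau_errs, m_errs = [], []
        for seed in range(100):
            fx = make_current_trace(
                "recovery_envelope",
                {"tau_recdes": 75.0, "m": 1.02, "i_max": 30.0,
                 "intervals": [10, 20, 40, 75, 150, 300, 600, 1200]},
                noise_sd=0.02,
                seed=seed,
            )
            fit = fit_recovery(fx.envelope_t, fx.envelope_residual)
            tau_errs.append(abs(fit.tau_recdes - 75.0) / 75.0)
            m_errs.append(abs(fit.m - 1.02) / 1.02)
        assert np.median(tau_errs) < 0.10
        assert np.median(m_errs) < 0.25

    def test_zero_conditioning_peak_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        flat = CurrentTrace(
            t, np.zeros_like(t), {"pulse1": (10.0, 30.0), "pulse2": (50.0, 70.0)}
        )
        with pytest.raises(KineticsError, match="conditioning"):
            build_recovery_envelope([flat])


class TestSteadyState:
    def test_identical_steady_and_peak(self):
        t = np.arange(0.0, 100.0, 0.1)
        y = np.where(t >= 10.0, -5.0, 0.0)
        ann = {"application": (10.0, 100.0)}
        ratio = steady_state_ratio(
            CurrentTrace(t, y, ann), CurrentTrace(t, y, ann)
        )
        assert ratio.ratio == pytest.approx(1.0)

    def test_small_fraction_roundtrip_under_noise(self):
        fx = make_current_trace(
            "steady_state_pair", {"ratio": 0.032}, noise_sd=0.01, seed=6
        )
        result = steady_state_ratio(fx.traces[0], fx.traces[1])
        assert result.ratio == pytest.approx(0.032, rel=0.10)

    def test_scaling_invariance(self):
        fx = make_current_trace("steady_state_pair", {"ratio": 0.05}, seed=2)
        r1 = steady_state_ratio(fx.traces[0], fx.traces[1]).ratio
        scaled = [
            CurrentTrace(tr.time, 11.0 * tr.current, tr.annotations)
            for tr in fx.traces
        ]
        r2 = steady_state_ratio(scaled[0], scaled[1]).ratio
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_flat_ctz_trace_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        glu = CurrentTrace(
            t, np.where(t >= 10.0, -1.0, 0.0), {"application": (10.0, 100.0)}
        )
        ctz = CurrentTrace(t, np.zeros_like(t), {"application": (10.0, 100.0)})
        with pytest.raises(KineticsError, match="zero maximal"):
            steady_state_ratio(glu, ctz)


def test_two_sample_ttest_wrapper():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, 40)
    b = rng.normal(2.0, 1.0, 40)
    res = two_sample_ttest(a, b)
    assert res.pvalue < 1e-6
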
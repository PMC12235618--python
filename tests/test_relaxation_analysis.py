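import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import spearmanr

from endortools import (
    Trace,
    fit_nse_biexp,
    fit_nse_mono,
    fit_recovery,
    mean_T1e,
    regress_rates,
)


def make_recovery(T1e=120e-6, beta=0.8, A=1.0, I0=1.0, kind="saturation", n=48):
    t = np.geomspace(T1e / 100.0, 6.0 * T1e, n)
    I = I0 * (1.0 - A * np.exp(-((t / T1e) ** beta)))
    return Trace(t=t, I=I, meta={"kind": kind})


def make_nse(T2n=500e-6, I0=1.0, n=40, t_max=400e-6):
    t = np.linspace(0.0, t_max, n)
    return Trace(t=t, I=I0 * np.exp(-2.0 * t / T2n), meta={"kind": "nse"})


class TestMeanT1e:
    def test_beta_one_identity(self):
        assert mean_T1e(120e-6, 1.0) == pytest.approx(120e-6, rel=1e-12)

    def test_beta_half_doubles(self):
        assert mean_T1e(100e-6, 0.5) == pytest.approx(200e-6, rel=1e-12)

    def test_two_thirds_frozen_value(self):
        # frozen from the numeric-integration oracle below
        assert mean_T1e(100e-6, 2.0 / 3.0) == pytest.approx(132.934e-6, rel=1e-4)

    @pytest.mark.parametrize("beta", [0.4, 0.6, 0.8, 1.0, 1.2, 1.5])
    def test_matches_numeric_integral(self, beta):
        T = 80e-6
        u_max = 40.0 ** (1.0 / beta)  # exp(-40) truncation error
        oracle, _ = quad(lambda u: np.exp(-(u**beta)), 0.0, u_max, limit=200)
        assert mean_T1e(T, beta) == pytest.approx(T * oracle, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mean_T1e(-1.0, 0.8)
        with pytest.raises(ValueError):
            mean_T1e(1e-4, 0.0)


class TestFitRecovery:
    def test_noiseless_round_trip(self):
        trace = make_recovery(T1e=120e-6, beta=0.8, A=1.0)
        fit = fit_recovery(trace)
        assert fit.T1e == pytest.approx(120e-6, rel=1e-6)
        assert fit.beta == pytest.approx(0.8, rel=1e-6)
        assert fit.A == pytest.approx(1.0, rel=1e-6)
        assert fit.T1e_bar == pytest.approx(mean_T1e(120e-6, 0.8), rel=1e-6)

    def test_fixed_beta_reduces_to_exponential(self):
        trace = make_recovery(T1e=90e-6, beta=1.0)
        fit = fit_recovery(trace, fix_beta=1.0)
        assert fit.T1e == pytest.approx(90e-6, rel=1e-8)
        assert fit.beta == 1.0

    def test_inversion_recovery_A_above_one(self):
        trace = make_recovery(T1e=100e-6, beta=0.85, A=1.9, kind="inversion")
        fit = fit_recovery(trace)
        assert fit.A == pytest.approx(1.9, rel=1e-5)
        assert fit.A > 1.0

    def test_intensity_rescaling_invariance(self):
        t1 = make_recovery(T1e=110e-6, beta=0.75)
        t2 = Trace(t=t1.t, I=37.5 * t1.I, meta=dict(t1.meta))
        f1, f2 = fit_recovery(t1), fit_recovery(t2)
        assert f2.T1e == pytest.approx(f1.T1e, rel=1e-9)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-9)

    def test_weighted_round_trip(self):
        trace = make_recovery(T1e=120e-6, beta=0.8)
        fit = fit_recovery(trace, weighting="relative")
        assert fit.T1e == pytest.approx(120e-6, rel=1e-6)

    def test_rejects_nse_trace(self):
        with pytest.raises(ValueError, match="recovery"):
            fit_recovery(make_nse())

    def test_short_trace_warns(self):
        trace = make_recovery(n=48)
        short = Trace(
            t=trace.t[:12], I=trace.I[:12], meta=dict(trace.meta)
        )  # spans < 2 T1e
        with pytest.warns(UserWarning, match="2\\*T1e"):
            fit_recovery(short)

    def test_sigmas_present(self):
        rng = np.random.default_rng(0)
        trace = make_recovery()
        noisy = Trace(
            t=trace.t,
            I=trace.I * (1 + 0.02 * rng.standard_normal(len(trace.t))),
            meta=dict(trace.meta),
        )
        fit = fit_recovery(noisy)
        for key in ("I0", "A", "T1e", "beta", "T1e_bar"):
            assert fit.sigmas[key] >= 0.0


class TestFitNseMono:
    def test_noiseless_round_trip(self):
        fit = fit_nse_mono(make_nse(T2n=500e-6), window_max=400e-6)
        assert fit.T2n == pytest.approx(500e-6, rel=1e-9)
        assert fit.fractions == [1.0]

    def test_log_linear_algebra(self):
        trace = make_nse(T2n=300e-6, t_max=200e-6)
        fit = fit_nse_mono(trace, window_max=200e-6)
        slope = np.polyfit(trace.t, np.log(trace.I), 1)[0]
        assert fit.rates[0] == pytest.approx(-0.5 * slope, rel=1e-9)

    def test_window_restricts_points(self):
        trace = make_nse(T2n=300e-6, t_max=400e-6, n=40)
        fit = fit_nse_mono(trace, window_max=200e-6)
        assert fit.window[1] == 200e-6

    def test_unbiased_on_any_window(self):
        trace = make_nse(T2n=300e-6, t_max=400e-6, n=40)
        for wmax in (50e-6, 120e-6, 400e-6):
            fit = fit_nse_mono(trace, window_max=wmax)
            assert fit.T2n == pytest.approx(300e-6, rel=1e-8)

    def test_truncated_noisy_monte_carlo(self):
        # 2% noise, window 200 us, T2n = 300 us: mean recovery within 5%
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.linspace(0.0, 200e-6, 40)
            I = np.exp(-2.0 * t / 300e-6) + 0.02 * rng.standard_normal(len(t))
            fit = fit_nse_mono(Trace(t=t, I=I, meta={"kind": "nse"}))
            recovered.append(fit.T2n)
        assert np.mean(recovered) == pytest.approx(300e-6, rel=0.05)

    def test_too_few_points_in_window(self):
        with pytest.raises(ValueError, match="window"):
            fit_nse_mono(make_nse(t_max=400e-6, n=40), window_max=15e-6)

    def test_non_decaying_rejected(self):
        t = np.linspace(0, 100e-6, 20)
        trace = Trace(t=t, I=np.exp(+2 * t / 100e-6), meta={"kind": "nse"})
        with pytest.raises(ValueError, match="decay"):
            fit_nse_mono(trace)


class TestFitNseBiexp:
    @staticmethod
    def biexp_trace(f=0.5, r_fast=65e3, r_slow=600.0, n=40, t_max=200e-6, noise=0.0, seed=0):
        t = np.linspace(0.0, t_max, n)
        I = f * np.exp(-2 * t * r_fast) + (1 - f) * np.exp(-2 * t * r_slow)
        if noise:
            I = I + noise * np.random.default_rng(seed).standard_normal(n)
        return Trace(t=t, I=I, meta={"kind": "nse"})

    def test_noiseless_round_trip(self):
        fit = fit_nse_biexp(self.biexp_trace(f=0.5, r_fast=65e3, r_slow=600.0))
        (rf, ff), (rs, fs) = fit.components
        assert rf == pytest.approx(65e3, rel=1e-4)
        assert rs == pytest.approx(600.0, rel=1e-4)
        assert ff == pytest.approx(0.5, abs=1e-4)
        assert ff + fs == pytest.approx(1.0)

    def test_fast_rate_listed_first(self):
        fit = fit_nse_biexp(self.biexp_trace(f=0.3))
        assert fit.rates[0] > fit.rates[1]

    def test_degenerate_single_population_matches_mono(self):
        trace = self.biexp_trace(f=0.0, r_slow=4e3)
        mono = fit_nse_mono(trace, window_max=200e-6)
        bi = fit_nse_biexp(trace)
        slow_rate = bi.components[1][0] if bi.components[0][1] < 0.5 else bi.components[0][0]
        assert slow_rate == pytest.approx(mono.rates[0], rel=1e-3)

    def test_shared_rate_refit_recovers_fractions(self):
        rates = (65e3, 600.0)
        for f_true in (0.3, 0.7):
            trace = self.biexp_trace(f=f_true, noise=0.01, seed=7)
            fit = fit_nse_biexp(trace, shared_rates=rates)
            assert fit.components[0][1] == pytest.approx(f_true, abs=0.02)

    def test_close_rates_flagged(self):
        trace = self.biexp_trace(f=0.5, r_fast=2e3, r_slow=1e3)
        with pytest.warns(UserWarning, match="poorly separated"):
            fit = fit_nse_biexp(trace, shared_rates=(2e3, 1e3))
        assert fit.flagged

    def test_needs_eight_points(self):
        trace = self.biexp_trace(n=40)
        short = Trace(t=trace.t[:6], I=trace.I[:6], meta={"kind": "nse"})
        with pytest.raises(ValueError, match="8 points"):
            fit_nse_biexp(short)

    def test_fraction_monotone_in_generating_fraction(self):
        # Spearman rho = 1 across 0.1-0.9, 20 seeds each
        gen_f = np.linspace(0.1, 0.9, 9)
        mean_fitted = []
        for f in gen_f:
            fitted = [
                fit_nse_biexp(
                    self.biexp_trace(f=f, noise=0.01, seed=s),
                    shared_rates=(65e3, 600.0),
                ).components[0][1]
                for s in range(20)
            ]
            mean_fitted.append(np.mean(fitted))
        rho, _ = spearmanr(gen_f, mean_fitted)
        assert rho == 1.0


class TestRegressRates:
    def test_exact_half_slope_line(self):
        x = np.array([7e3, 12e3, 18e3, 22e3])
        reg = regress_rates(list(zip(x, 0.5 * x)))
        assert reg.slope == pytest.approx(0.5, rel=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-9)
        assert reg.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        reg = regress_rates([(1e3, 2e3), (2e3, 5e3)])
        assert reg.slope == pytest.approx(3.0)
        assert reg.intercept == pytest.approx(-1e3)
        assert reg.n == 2

    def test_through_origin(self):
        x = np.array([1e3, 2e3, 4e3])
        reg = regress_rates(list(zip(x, 0.5 * x)), through_origin=True)
        assert reg.slope == pytest.approx(0.5, rel=1e-12)
        assert reg.intercept == 0.0

    def test_degenerate_abscissa(self):
        with pytest.raises(ValueError, match="degenerate"):
            regress_rates([(1e3, 1.0), (1e3, 2.0)])

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            regress_rates([(1e3, 0.5e3)])

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError, match="positive"):
            regress_rates([(1e3, -1.0), (2e3, 1.0)])


@settings(max_examples=25, deadline=None)
@given(
    T1e=st.floats(20e-6, 500e-6),
    beta=st.floats(0.5, 1.2),
)
def test_recovery_round_trip_property(T1e, beta):
    trace = make_recovery(T1e=T1e, beta=beta)
    fit = fit_recovery(trace)
    assert fit.T1e == pytest.approx(T1e, rel=1e-4)
    assert fit.beta == pytest.approx(beta, rel=1e-4)
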
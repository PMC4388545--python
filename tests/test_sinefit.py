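"""Sine-model fitting: exactness, normalization, invariances, noise behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from disctilt import FitOptions, SineFit, SineWaveRegressor, fit_sine, goodness, tilt_direction
from disctilt.sinefit import _linear_solve, _normalize
from disctilt.trace import CenteredTrace

from _oracles import sine_grid_oracle

B0 = 2 * np.pi / 1024


def make_trace(a, c, n=1024, noise=0.0, rng=None, width=1024):
    u = np.linspace(0, width - 1, n) - (width - 1) / 2
    v = a * np.sin(2 * np.pi * u / width - c)
    if noise:
        v = v + rng.normal(0, noise, n)
    return CenteredTrace(u=u, v=v, scan_width=width)


class TestExactRecovery:
    @pytest.mark.parametrize("a", [5.0, 20.0, 40.0, 80.0])
    def test_noiseless_parameters_recovered(self, a):
        fit = fit_sine(make_trace(a, 1.0))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(B0, rel=1e-6)
        assert fit.c == pytest.approx(1.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.quality_pass and fit.converged

    def test_flat_trace_short_circuits(self):
        ct = CenteredTrace(u=np.arange(16.0) - 7.5, v=np.zeros(16), scan_width=16)
        fit = fit_sine(ct)
        assert fit.a == 0.0
        assert fit.r_squared == 1.0
        assert fit.quality_pass

    def test_too_few_points_rejected(self):
        ct = CenteredTrace(u=np.arange(7.0), v=np.arange(7.0), scan_width=8)
        with pytest.raises(ValueError, match="at least 8"):
            fit_sine(ct)

    def test_fixed_period_mode_equals_linear_solve(self, rng):
        tr = make_trace(25.0, 2.0, n=256, noise=4.0, rng=rng)
        fit = fit_sine(tr, FitOptions(b_mode="fixed_period"))
        a_lin, c_lin = _linear_solve(tr.u, tr.v, B0)
        assert fit.b == B0
        assert fit.a == pytest.approx(a_lin, abs=1e-12)
        assert fit.c == pytest.approx(c_lin, abs=1e-12)

    def test_grid_init_reaches_same_optimum(self, rng):
        tr = make_trace(30.0, 4.0, n=512, noise=3.0, rng=rng)
        f1 = fit_sine(tr, FitOptions(init="linear"))
        f2 = fit_sine(tr, FitOptions(init="grid"))
        assert f1.a == pytest.approx(f2.a, rel=1e-6)
        assert f1.c == pytest.approx(f2.c, rel=1e-5)


class TestNormalization:
    def test_negative_amplitude_absorbed_into_phase(self):
        a, c = _normalize(-15.0, 0.5)
        assert a == 15.0
        assert c == pytest.approx(0.5 + np.pi)

    def test_phase_wrapped_into_base_interval(self):
        a, c = _normalize(3.0, -0.25)
        assert a == 3.0 and 0 <= c < 2 * np.pi
        assert c == pytest.approx(2 * np.pi - 0.25)

    @given(a=st.floats(1.0, 80.0), c=st.floats(0.1, 6.0), k=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, a, c, k):
        tr = make_trace(a, c, n=128)
        scaled = CenteredTrace(u=tr.u, v=k * tr.v, scan_width=tr.scan_width)
        f1, f2 = fit_sine(tr), fit_sine(scaled)
        assert f2.a == pytest.approx(k * f1.a, rel=1e-5)
        assert f2.b == pytest.approx(f1.b, rel=1e-6)
        assert f2.c == pytest.approx(f1.c, rel=1e-4, abs=1e-4)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-9)

    @given(a=st.floats(1.0, 80.0), c=st.floats(0.1, 3.0))
    def test_reflection_shifts_phase_by_pi(self, a, c):
        tr = make_trace(a, c, n=128)
        neg = CenteredTrace(u=tr.u, v=-tr.v, scan_width=tr.scan_width)
        f1, f2 = fit_sine(tr), fit_sine(neg)
        assert f2.a == pytest.approx(f1.a, rel=1e-5)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-9)
        assert np.mod(f2.c - f1.c, 2 * np.pi) == pytest.approx(np.pi, abs=1e-4)


class TestOracleEquivalence:
    def test_fixed_b_fit_matches_grid_search(self, rng):
        for _ in range(10):
            a, c = rng.uniform(5, 60), rng.uniform(0, 2 * np.pi)
            tr = make_trace(a, c, n=128, noise=3.0, rng=rng)
            fit = fit_sine(tr, FitOptions(b_mode="fixed_period"))
            a_g, c_g, _ = sine_grid_oracle(tr.u, tr.v, B0, a_max=1.5 * fit.a + 1)
            da = (1.5 * fit.a + 1) / 399
            assert fit.a == pytest.approx(a_g, abs=da)
            dc = np.mod(fit.c - c_g, 2 * np.pi)
            assert min(dc, 2 * np.pi - dc) < 2 * np.pi / 720 + 1e-9


class TestNoise:
    def test_amplitude_recovery_grid(self):
        # median error over seeds, across amplitudes and noise levels
        n = 1024
        for a in (5.0, 20.0, 40.0, 80.0):
            for sigma in (0.0, 2.0, 5.0):
                errs = []
                for seed in range(100):
                    r = np.random.default_rng(1000 * seed + int(a))
                    fit = fit_sine(make_trace(a, 1.0, n=n, noise=sigma, rng=r))
                    errs.append(abs(fit.a - a))
                bound = max(0.01, 0.5 * sigma * np.sqrt(2 / n) * 3)
                assert np.median(errs) < bound, (a, sigma)

    def test_r_squared_degrades_monotonically_with_noise(self):
        r = np.random.default_rng(7)
        z = r.normal(0, 1, 512)
        u = np.arange(512.0) - 255.5
        base = 30 * np.sin(2 * np.pi * u / 512 - 1.0)
        last = np.inf
        for sigma in (0.0, 1.0, 2.0, 5.0, 10.0):
            tr = CenteredTrace(u=u, v=base + sigma * z, scan_width=512)
            r2 = fit_sine(tr).r_squared
            assert r2 <= last + 1e-12
            last = r2


class TestDerivedMetrics:
    def test_tilt_direction_closed_form(self):
        fit = SineFit(a=20, b=B0, c=0.0, r_squared=1, rss=0, n_points=1024,
                      converged=True, quality_pass=True, scan_width=1024)
        assert tilt_direction(fit) == pytest.approx(3 * np.pi / 2)

    def test_tilt_direction_periodic_in_phase(self):
        kw = dict(a=20, b=B0, r_squared=1, rss=0, n_points=1024,
                  converged=True, quality_pass=True, scan_width=1024)
        t1 = tilt_direction(SineFit(c=1.2, **kw))
        t2 = tilt_direction(SineFit(c=1.2 + 2 * np.pi, **kw))
        d = np.mod(t1 - t2, 2 * np.pi)
        assert min(d, 2 * np.pi - d) == pytest.approx(0.0, abs=1e-9)

    def test_tilt_direction_undefined_for_flat_fit(self):
        fit = SineFit(a=0, b=B0, c=0, r_squared=1, rss=0, n_points=16,
                      converged=True, quality_pass=True, scan_width=1024)
        with pytest.raises(ValueError, match="undefined"):
            tilt_direction(fit)

    def test_quality_gate_is_strict(self):
        kw = dict(a=1, b=B0, c=0, rss=1, n_points=16, converged=True,
                  scan_width=1024)
        assert not goodness(SineFit(r_squared=0.90, quality_pass=False, **kw))["quality_pass"]
        assert goodness(SineFit(r_squared=0.901, quality_pass=True, **kw))["quality_pass"]

    def test_r_squared_matches_residual_recomputation_with_outlier(self):
        tr = make_trace(30.0, 1.0, n=256)
        v = tr.v.copy()
        v[100] += 100.0
        tr2 = CenteredTrace(u=tr.u, v=v, scan_width=tr.scan_width)
        fit = fit_sine(tr2)
        resid = v - fit.a * np.sin(fit.b * tr.u - fit.c)
        tss = np.sum((v - v.mean()) ** 2)
        assert fit.r_squared < 1
        assert fit.r_squared == pytest.approx(1 - np.sum(resid**2) / tss, abs=1e-12)


class TestEstimatorAPI:
    def test_clone_and_params_round_trip(self):
        reg = SineWaveRegressor(scan_width=512, b_mode="fixed_period", tol=1e-8)
        c = clone(reg)
        assert c.get_params() == reg.get_params()

    def test_predict_reproduces_signal_and_score_is_r2(self):
        u = (np.arange(1024.0) - 511.5)[:, None]
        v = 12 * np.sin(2 * np.pi * u[:, 0] / 1024 - 0.7)
        reg = SineWaveRegressor(scan_width=1024).fit(u, v)
        assert np.allclose(reg.predict(u), v, atol=1e-6)
        assert reg.score(u, v) == pytest.approx(1.0, abs=1e-9)

    def test_scan_width_inferred_from_span_when_omitted(self):
        u = (np.arange(512.0) - 255.5)[:, None]
        v = 15 * np.sin(2 * np.pi * u[:, 0] / 512 - 1.3)
        reg = SineWaveRegressor().fit(u, v)
        assert reg.amplitude_ == pytest.approx(15.0, rel=1e-6)
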
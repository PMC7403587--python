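"""Temperature artifact filtering, normalization, binning and cosinor fits."""

import numpy as np
import pytest

from shiftwork.exceptions import DegenerateInputError, ParameterError
from shiftwork.temperature import (
    TemperatureSeries,
    amplitude_change,
    bin_5min,
    cosinor_fit,
    normalize_baseline,
    remove_temp_artifacts,
)


def ts(temp, dt_s=10.0, t0=0.0, **kw):
    temp = np.asarray(temp, float)
    t = t0 + np.arange(temp.size) * dt_s / 3600.0
    return TemperatureSeries(t_hours=t, temp_c=temp, **kw)


def cosine_series(hours=96.0, mesor=37.2, amp=0.64, phi=18.0, dt_s=10.0):
    n = int(hours * 3600 / dt_s)
    t = np.arange(n) * dt_s / 3600.0
    return TemperatureSeries(
        t_hours=t, temp_c=mesor + amp * np.cos(2 * np.pi * (t - phi) / 24.0)
    )


class TestRemoveArtifacts:
    def test_constant_series_untouched(self):
        out = remove_temp_artifacts(ts(np.full(500, 37.0)))
        assert not out.artifact.any()

    def test_large_spike_flagged(self, rng):
        temp = rng.normal(37.0, 0.1, 500)
        temp[250] = 42.0
        out = remove_temp_artifacts(ts(temp))
        assert out.artifact[250]
        assert out.artifact.sum() <= 3

    def test_slow_cosine_mostly_retained(self):
        out = remove_temp_artifacts(cosine_series(hours=72.0, amp=0.6))
        assert (~out.artifact).mean() >= 0.99

    def test_short_series_falls_back_with_warning(self, rng):
        with pytest.warns(UserWarning):
            out = remove_temp_artifacts(ts(rng.normal(37, 0.1, 50)))
        assert len(out) == 50

    def test_masked_not_deleted(self, rng):
        temp = rng.normal(37.0, 0.1, 300)
        temp[10] = 45.0
        out = remove_temp_artifacts(ts(temp))
        assert len(out) == 300 and out.temp_c[10] == 45.0


class TestNormalizeBaseline:
    def test_constant_becomes_zero(self):
        out = normalize_baseline(ts(np.full(400, 37.0)), (0.0, 1.0))
        assert np.allclose(out.temp_c, 0.0)
        assert out.baseline_delta

    def test_idempotent(self):
        once = normalize_baseline(ts(np.arange(400.0)), (0.0, 1.0))
        twice = normalize_baseline(once, (0.0, 1.0))
        np.testing.assert_allclose(twice.temp_c, once.temp_c)

    def test_full_cycle_cosine_mesor_removed(self):
        out = normalize_baseline(cosine_series(hours=96.0), (0.0, 96.0))
        fit = cosinor_fit(bin_5min(out), 24.0)
        assert fit.mesor == pytest.approx(0.0, abs=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_baseline(ts(np.full(10, 37.0)), (5.0, 6.0))


class TestBin5Min:
    def test_constant_bin(self):
        out = bin_5min(ts(np.full(30, 37.0)))
        assert len(out) == 1 and out.temp_c[0] == pytest.approx(37.0)

    def test_all_artifact_bin_missing(self):
        s = ts(np.full(60, 37.0))
        s.artifact[:30] = True
        out = bin_5min(s)
        assert np.isnan(out.temp_c[0]) and out.artifact[0]
        assert out.temp_c[1] == pytest.approx(37.0)

    def test_linear_ramp_bins_to_midpoint_mean(self):
        out = bin_5min(ts(np.arange(60.0)))
        assert out.temp_c[0] == pytest.approx(np.mean(np.arange(30.0)))
        assert out.temp_c[1] == pytest.approx(np.mean(np.arange(30.0, 60.0)))


class TestCosinor:
    def test_exact_recovery_on_noiseless_cosine(self):
        fit = cosinor_fit(cosine_series(mesor=0.0, amp=1.0, phi=18.0), 24.0)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.mesor == pytest.approx(0.0, abs=1e-6)
        assert fit.acrophase_zt == pytest.approx(18.0, abs=1e-6)

    def test_recovery_through_5min_binning(self):
        # bin averaging attenuates a 24-h cosine by sinc(pi*5/1440) ~ 2e-5
        fit = cosinor_fit(bin_5min(cosine_series(mesor=0.0, amp=1.0, phi=18.0)), 24.0)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-4)

    def test_constant_series_degenerates_to_zero_amplitude(self):
        fit = cosinor_fit(ts(np.full(8640 * 2, 36.9)), 24.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.mesor == pytest.approx(36.9)

    def test_amplitude_invariant_under_mesor_and_time_shift(self):
        base = cosine_series(mesor=37.0, amp=0.5, phi=6.0)
        shifted = TemperatureSeries(
            t_hours=base.t_hours + 5.0, temp_c=base.temp_c + 2.0
        )
        f0 = cosinor_fit(base, 24.0)
        f1 = cosinor_fit(shifted, 24.0)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-9)
        assert f1.mesor == pytest.approx(f0.mesor + 2.0, abs=1e-9)
        assert f1.acrophase_zt == pytest.approx((f0.acrophase_zt + 5.0) % 24, abs=1e-6)

    def test_agrees_with_acrophase_grid_search_oracle(self, rng):
        for _ in range(10):
            amp = rng.uniform(0.1, 1.0)
            phi = rng.uniform(0.0, 24.0)
            n = 864
            t = np.arange(n) * 5.0 / 60.0
            y = 37 + amp * np.cos(2 * np.pi * (t - phi) / 24.0) + rng.normal(0, 0.2, n)
            series = TemperatureSeries(t_hours=t, temp_c=y)
            fit = cosinor_fit(series, 24.0)
            # independent oracle: profile the acrophase on a 0.01-h grid
            best = (np.inf, None, None)
            for g in np.arange(0.0, 24.0, 0.01):
                X = np.column_stack([np.ones(n), np.cos(2 * np.pi * (t - g) / 24.0)])
                beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(res[0]) if res.size else np.sum((y - X @ beta) ** 2)
                if rss < best[0]:
                    best = (rss, abs(beta[1]), g)
            assert fit.amplitude == pytest.approx(best[1], abs=2e-3)

    def test_noisy_amplitude_recovery_within_monte_carlo_error(self, rng):
        amp = 0.64
        n = 864  # 72 h of 5-min bins
        t = np.arange(n) * 5.0 / 60.0
        y = amp * np.cos(2 * np.pi * (t - 18.0) / 24.0) + rng.normal(0, 0.2, n)
        fit = cosinor_fit(TemperatureSeries(t_hours=t, temp_c=y), 24.0)
        # amplitude standard error is sd * sqrt(2/n) ~ 0.0096
        assert abs(fit.amplitude - amp) < 0.05

    def test_missing_bins_simply_omitted(self):
        s = bin_5min(cosine_series(mesor=0.0, amp=0.8))
        s.artifact[::7] = True
        fit = cosinor_fit(s, 24.0)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-4)

    def test_span_shorter_than_period_rejected(self):
        with pytest.raises(ParameterError):
            cosinor_fit(cosine_series(), 24.0, span=(0.0, 12.0))

    def test_all_missing_rejected(self):
        s = ts(np.full(1000, np.nan))
        with pytest.raises(DegenerateInputError):
            cosinor_fit(s, 24.0)


class TestAmplitudeChange:
    def test_equal_amplitudes_zero_delta(self):
        f = cosinor_fit(cosine_series(amp=0.5), 24.0)
        assert amplitude_change(f, f).delta == 0.0

    def test_damping_by_subtraction(self):
        b = cosinor_fit(cosine_series(amp=0.63), 24.0)
        w = cosinor_fit(cosine_series(amp=0.23), 24.0)
        assert amplitude_change(b, w).delta == pytest.approx(-0.40, abs=1e-6)

    def test_period_mismatch_rejected(self):
        b = cosinor_fit(cosine_series(amp=0.5), 24.0)
        w = cosinor_fit(cosine_series(amp=0.5), 12.0)
        with pytest.raises(ParameterError):
            amplitude_change(b, w)
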
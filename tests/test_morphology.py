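import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dentspike as ds
from dentspike.exceptions import ConfigError, DegenerateInputError
from conftest import gaussian_waveform

SQRT3 = np.sqrt(3.0)
FWHM = 2 * np.sqrt(2 * np.log(2))


class TestMeanAndScale:
    def test_single_event_identity(self):
        wm = ds.WaveformMatrix(values=np.arange(31.0)[None, :], window=(-15, 15),
                               fs=1000.0, event_ids=[0])
        np.testing.assert_array_equal(ds.mean_waveform(wm), np.arange(31.0))

    def test_antisymmetric_pair_cancels(self):
        v = np.random.default_rng(0).normal(size=31)
        wm = ds.WaveformMatrix(values=np.vstack([v, -v]), window=(-15, 15),
                               fs=1000.0, event_ids=[0, 1])
        np.testing.assert_allclose(ds.mean_waveform(wm), 0, atol=1e-15)

    def test_mean_concentrates_on_template(self):
        rng = np.random.default_rng(1)
        tpl = gaussian_waveform(6, (-15, 15))
        noisy = tpl + rng.normal(0, 0.5, size=(1000, tpl.size))
        wm = ds.WaveformMatrix(values=noisy, window=(-15, 15), fs=1000.0,
                               event_ids=np.arange(1000))
        err = np.abs(ds.mean_waveform(wm) - tpl)
        assert np.all(err < 3 * 0.5 / np.sqrt(1000) + 1e-9)

    def test_zscore_properties(self):
        wf = gaussian_waveform(6)
        z = ds.scale_waveform(wf)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std() == pytest.approx(1, abs=1e-12)

    def test_affine_invariance(self):
        wf = gaussian_waveform(6)
        np.testing.assert_allclose(ds.scale_waveform(3 * wf + 2),
                                   ds.scale_waveform(wf), atol=1e-12)

    def test_constant_waveform_errors(self):
        with pytest.raises(DegenerateInputError):
            ds.scale_waveform(np.ones(401))


class TestResample:
    def test_knots_reproduced(self):
        wf = gaussian_waveform(6, (-20, 20))
        rs, t = ds.resample_mean(wf, 1000.0, (-20, 20))
        np.testing.assert_allclose(rs[::4], wf, atol=1e-12)

    def test_linear_reproduced_exactly(self):
        wf = np.linspace(-1, 1, 41)
        rs, t = ds.resample_mean(wf, 1000.0, (-20, 20))
        np.testing.assert_allclose(rs, np.interp(t, [-20, 20], [-1, 1]), atol=1e-12)

    def test_gaussian_interpolation_error_small(self):
        wf = gaussian_waveform(6, (-50, 50))
        rs, t = ds.resample_mean(wf, 1000.0, (-50, 50))
        assert np.max(np.abs(rs - np.exp(-0.5 * (t / 6) ** 2))) < 1e-4


class TestSecondDerivative:
    def test_quadratic_exact(self):
        t = np.arange(-10, 11, 1.0)
        d2 = ds.second_derivative(3.0 * t**2, dt_ms=1.0)
        np.testing.assert_allclose(d2, 6.0, atol=1e-10)

    def test_linear_is_zero(self):
        d2 = ds.second_derivative(np.linspace(0, 5, 21), dt_ms=1.0)
        np.testing.assert_allclose(d2, 0, atol=1e-12)

    def test_gaussian_concavity_maxima(self):
        wf = gaussian_waveform(6)
        w = ds.measure_width(wf, 1000.0, (-200, 200))
        assert w.start_ms == pytest.approx(-SQRT3 * 6, abs=0.25)
        assert w.end_ms == pytest.approx(SQRT3 * 6, abs=0.25)


class TestWidth:
    @pytest.mark.parametrize("sigma", [4.0, 5.0, 6.0, 7.0])
    def test_gaussian_width_analytic(self, sigma):
        w = ds.measure_width(gaussian_waveform(sigma), 1000.0, (-200, 200))
        assert w.width_ms == pytest.approx(2 * SQRT3 * sigma, abs=0.5)
        assert -15 <= w.start_ms <= -5 and 5 <= w.end_ms <= 15

    def test_width_scale_and_baseline_invariant(self):
        wf = gaussian_waveform(5.5)
        w0 = ds.measure_width(wf, 1000.0, (-200, 200))
        w1 = ds.measure_width(4.2 * wf + 0.7, 1000.0, (-200, 200))
        assert w0.width_ms == w1.width_ms
        assert w0.start_ms == w1.start_ms

    def test_time_reversal_swaps_limits(self):
        # an asymmetric waveform: Gaussian plus undershoot
        shape = ds.make_ds_template(2).shape
        w = ds.measure_width(shape, 1000.0, (-100, 100))
        wr = ds.measure_width(shape[::-1], 1000.0, (-100, 100))
        assert wr.width_ms == pytest.approx(w.width_ms, abs=1e-9)
        assert wr.start_ms == pytest.approx(-w.end_ms, abs=1e-9)

    @given(st.floats(3.5, 8.0))
    @settings(max_examples=25, deadline=None)
    def test_gaussian_family_property(self, sigma):
        w = ds.measure_width(gaussian_waveform(sigma), 1000.0, (-200, 200))
        assert w.width_ms == pytest.approx(2 * SQRT3 * sigma, abs=0.5)


class TestHalfHeight:
    @pytest.mark.parametrize("sigma", [4.0, 5.0, 6.0, 7.0])
    def test_gaussian_fwhm(self, sigma):
        w = ds.half_height_width(gaussian_waveform(sigma), 1000.0, (-200, 200))
        assert w.width_ms == pytest.approx(FWHM * sigma, abs=0.5)

    def test_rectangular_pulse(self):
        wf = np.zeros(401)
        wf[190:211] = 1.0  # 21 samples high: half-crossings at the edges
        w = ds.half_height_width(wf, 1000.0, (-200, 200))
        assert w.width_ms == pytest.approx(21.0, abs=0.5)

    def test_monotone_ramp_flagged(self):
        w = ds.half_height_width(np.linspace(0, 1, 401), 1000.0, (-200, 200))
        assert w.flagged and np.isnan(w.width_ms)

    def test_baseline_sensitivity_vs_width(self):
        # slow activity far from the peak biases the baseline estimate and
        # hence the half-height width; the second-derivative width, which
        # only sees peri-peak curvature, is untouched
        t = np.arange(-200, 201)
        wf = gaussian_waveform(6, (-200, 200))
        drifted = wf + 0.3 * (np.abs(t) > 50)
        w_sd = ds.measure_width(wf, 1000.0, (-200, 200))
        w_sd_drift = ds.measure_width(drifted, 1000.0, (-200, 200))
        assert w_sd.width_ms == w_sd_drift.width_ms
        h = ds.half_height_width(wf, 1000.0, (-200, 200))
        h_drift = ds.half_height_width(drifted, 1000.0, (-200, 200))
        assert abs(h.width_ms - h_drift.width_ms) > 0.5


class TestCV:
    def test_constant_zero(self):
        assert ds.cv([2, 2, 2]) == 0

    def test_two_point_hand_value(self):
        assert ds.cv([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    @given(st.floats(0.1, 100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        vals = np.array([1.0, 2.0, 4.0])
        assert ds.cv(k * vals) == pytest.approx(ds.cv(vals), rel=1e-9)

    def test_summary_groups(self):
        s = ds.cv_summary("M4", {"a": [10, 12], "b": [11, 13]})
        assert s.per_group_cv["a"] == pytest.approx(ds.cv([10, 12]))
        assert s.cv_of_means == pytest.approx(ds.cv([11, 12]))

    def test_width_more_stable_than_amplitude_across_channels(self):
        # same template seen at "channels" with different laminar gains plus
        # small noise: width CV << amplitude CV
        rng = np.random.default_rng(4)
        tpl = ds.make_ds_template(1).shape
        gains = np.linspace(0.2, 1.0, 8)
        widths, amps = [], []
        for g in gains:
            wf = g * 2.0 * tpl + rng.normal(0, 0.002, tpl.size)
            widths.append(ds.measure_width(wf, 1000.0, (-100, 100)).width_ms)
            amps.append(wf[100])
        assert ds.cv(widths) < ds.cv(amps)
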
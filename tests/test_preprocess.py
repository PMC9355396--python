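"""Preprocessing-chain contracts: decimation, Bessel highpass, Gaussian
smoothing, derivative/event alignment, and the per-trap N=1 rule."""
import numpy as np
import pytest
from scipy import signal as sps

from phytoephys import (
    AlignmentError,
    InvalidArgumentError,
    NoiseModel,
    Trace,
    add_noise,
    align_by_event,
    align_by_steepest_deflection,
    average_per_trap,
    downsample,
    gaussian_smooth,
    highpass_bessel,
)


def _sine_trace(f, fs, duration, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return Trace(values=amp * np.sin(2 * np.pi * f * t), fs=fs)


def _fit_amplitude(y, f, fs):
    """Least-squares amplitude of a sinusoid at frequency f."""
    t = np.arange(y.size) / fs
    basis = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return float(np.hypot(*coef))


class TestDownsample:
    def test_sample_count(self):
        tr = Trace(values=np.zeros(30_000), fs=1000.0)
        out = downsample(tr, 100.0)
        assert out.n == 3000
        assert out.fs == 100.0

    def test_identity_when_rate_unchanged(self):
        tr = _sine_trace(5, 200, 10)
        out = downsample(tr, 200.0)
        np.testing.assert_array_equal(out.values, tr.values)

    def test_band_limited_amplitude_preserved(self):
        tr = _sine_trace(10, 1000, 30)
        out = downsample(tr, 100.0)
        mid = out.values[out.n // 4 : -out.n // 4]
        assert _fit_amplitude(mid, 10, 100.0) == pytest.approx(1.0, rel=0.01)

    def test_event_times_preserved(self):
        tr = Trace(values=np.zeros(10_000), fs=1000.0, events=[("stimulus", 5.0)])
        out = downsample(tr, 100.0)
        assert out.event_time("stimulus") == 5.0

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidArgumentError):
            downsample(_sine_trace(1, 100, 10), 200.0)


class TestBesselHighpass:
    def test_dc_removed(self):
        # steady-state initialization: a constant held since before the
        # record maps to (near) zero everywhere, and stays zero
        fs = 10.0
        tr = Trace(values=np.full(int(3000 * fs), 5.0), fs=fs)
        out = highpass_bessel(tr, fc=0.01, order=2)
        assert np.max(np.abs(out.values)) < 5e-3

    def test_dc_step_transient_decays(self):
        # a step *within* the record does excite the filter, then decays
        fs = 10.0
        y = np.concatenate([np.zeros(int(10 * fs)), np.full(int(3000 * fs), 5.0)])
        out = highpass_bessel(Trace(values=y, fs=fs), fc=0.01, order=2)
        assert abs(out.values[int(11 * fs)]) > 1.0
        assert abs(out.values[-1]) < 5e-3

    def test_passband_gain_unity(self):
        fs, f = 50.0, 1.0
        tr = _sine_trace(f, fs, 600)
        out = highpass_bessel(tr, fc=0.01, order=2)
        tail = out.values[out.n // 2 :]
        assert _fit_amplitude(tail, f, fs) == pytest.approx(1.0, rel=0.01)

    def test_corner_gain_matches_analog_prototype(self):
        """Steady-state gain at fc equals the analytic magnitude of the
        analog 2nd-order Bessel highpass prototype."""
        fs, fc = 5.0, 0.01
        tr = _sine_trace(fc, fs, 3000)
        out = highpass_bessel(tr, fc=fc, order=2)
        measured = _fit_amplitude(out.values[out.n // 2 :], fc, fs)
        b, a = sps.bessel(2, 2 * np.pi * fc, btype="highpass", analog=True, norm="mag")
        _, h = sps.freqs(b, a, worN=[2 * np.pi * fc])
        assert measured == pytest.approx(abs(h[0]), rel=0.05)

    def test_fc_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            highpass_bessel(_sine_trace(1, 10, 10), fc=6.0)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        tr = Trace(values=np.full(1000, 2.5), fs=100.0)
        out = gaussian_smooth(tr, 0.2)
        np.testing.assert_allclose(out.values, 2.5, rtol=1e-12)

    def test_matches_direct_convolution_oracle(self):
        """Noise s.d. reduction equals a direct convolution with the same
        unit-area kernel (within 2%)."""
        rng = np.random.default_rng(0)
        fs, window = 100.0, 0.5
        y = rng.standard_normal(20_000)
        out = gaussian_smooth(Trace(values=y, fs=fs), window)

        sigma = window / 6.0 * fs
        half = int(3.0 * sigma + 0.5)
        k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
        k /= k.sum()
        direct = np.convolve(y, k, mode="same")
        core = slice(half, -half)
        assert out.values[core].std() == pytest.approx(direct[core].std(), rel=0.02)
        np.testing.assert_allclose(out.values[core], direct[core], atol=5e-3)

    def test_window_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gaussian_smooth(Trace(values=np.zeros(100), fs=100.0), 0.005)


def _shifted_ap(ap_clean, lag_samples):
    return Trace(
        values=np.roll(ap_clean.values, lag_samples),
        fs=ap_clean.fs,
        events=[("stimulus", 20.0 + lag_samples / ap_clean.fs)],
        meta={"trap": f"t{lag_samples}"},
    )


class TestDerivativeAlignment:
    def test_known_integer_lags_recovered(self, ap_clean):
        lags = [0, 150, 600, 1200]
        traces = [_shifted_ap(ap_clean, l) for l in lags]
        wset = align_by_steepest_deflection(traces)
        ref = wset.aligned[0]
        for row in wset.aligned[1:]:
            # residual misalignment <= 1 sample: best correlation lag ~0
            xc = [np.dot(ref, np.roll(row, k)) for k in (-1, 0, 1)]
            assert np.argmax(xc) in (0, 1, 2)
            np.testing.assert_allclose(row, ref, atol=1e-3 * np.abs(ref).max() + 1e-12)

    def test_single_trace_mean_is_trace_ci_zero(self, ap_clean):
        tr = ap_clean.replace(meta={"trap": "a"})
        wset = align_by_steepest_deflection([tr])
        np.testing.assert_array_equal(wset.mean, wset.aligned[0])
        assert np.all(wset.ci95 == 0)

    def test_flat_trace_raises(self):
        flat = Trace(values=np.zeros(5000), fs=100.0)
        with pytest.raises(AlignmentError):
            align_by_steepest_deflection([flat])

    def test_monotone_ramp_raises(self):
        ramp = Trace(values=np.linspace(0, 1, 5000), fs=100.0)
        with pytest.raises(AlignmentError):
            align_by_steepest_deflection([ramp])

    def test_translation_equivariance_with_noise(self, ap_clean):
        nm = NoiseModel(baseline_sd=1e-3, drift_amp=0, mains_amp_50hz=0, laser_amp_40hz=0)
        noisy = add_noise(ap_clean, nm, seed=3)
        shifted = Trace(
            values=np.roll(noisy.values, 500), fs=noisy.fs,
            events=[("stimulus", 20.5)], meta={"trap": "b"},
        )
        wset = align_by_steepest_deflection([noisy.replace(meta={"trap": "a"}), shifted])
        np.testing.assert_allclose(wset.aligned[0], wset.aligned[1], atol=1e-9)


class TestEventAlignment:
    def test_rezeroed_on_event(self):
        a = Trace(values=np.arange(100.0), fs=10.0, events=[("laser_on", 2.0)])
        b = Trace(values=np.arange(100.0), fs=10.0, events=[("laser_on", 5.0)])
        wset = align_by_event([a, b], "laser_on")
        i0 = np.argmin(np.abs(wset.t))
        assert wset.t[i0] == 0.0
        assert wset.aligned[0][i0] == 20.0
        assert wset.aligned[1][i0] == 50.0

    def test_missing_event_names_trace(self):
        a = Trace(values=np.zeros(100), fs=10.0, events=[("laser_on", 2.0)])
        b = Trace(values=np.zeros(100), fs=10.0)
        with pytest.raises(InvalidArgumentError, match="trace 1"):
            align_by_event([a, b], "laser_on")

    def test_single_trace_passthrough(self):
        a = Trace(values=np.arange(50.0), fs=10.0, events=[("laser_on", 1.0)])
        wset = align_by_event([a], "laser_on")
        np.testing.assert_array_equal(wset.aligned[0], a.values)


class TestPerTrapAveraging:
    def _wset(self, traps):
        from phytoephys.preprocess import WaveformSet
        rng = np.random.default_rng(1)
        rows = rng.standard_normal((len(traps), 20))
        return WaveformSet(
            aligned=rows, fs=10.0, t=np.arange(20) / 10.0,
            per_trial_meta=[{"trap": t} for t in traps],
        )

    def test_n_equals_unique_traps(self):
        wset = self._wset(["a", "a", "a", "b", "b"])
        out = average_per_trap(wset)
        assert out.n == 2
        np.testing.assert_allclose(out.aligned[0], wset.aligned[:3].mean(axis=0))
        assert out.per_trial_meta[0]["n_averaged"] == 3

    def test_distinct_traps_identity(self):
        wset = self._wset(["a", "b", "c"])
        out = average_per_trap(wset)
        np.testing.assert_array_equal(out.aligned, wset.aligned)

    def test_duplicate_waveforms_average_to_themselves(self):
        wset = self._wset(["a", "a"])
        wset.aligned[1] = wset.aligned[0]
        out = average_per_trap(wset)
        np.testing.assert_array_equal(out.aligned[0], wset.aligned[0])

    def test_missing_trap_ids_rejected(self):
        from phytoephys.preprocess import WaveformSet
        wset = WaveformSet(aligned=np.zeros((2, 5)), fs=1.0, t=np.arange(5.0),
                           per_trial_meta=[{"trap": "a"}, {}])
        with pytest.raises(InvalidArgumentError):
            average_per_trap(wset)


def test_waveform_set_mean_converges_with_n(ap_clean):
    """RMSE of the set mean against the template decreases with membership."""
    nm = NoiseModel(baseline_sd=2e-3, drift_amp=0, mains_amp_50hz=0, laser_amp_40hz=0)

    def rmse(n):
        traces = [
            add_noise(ap_clean, nm, seed=s).replace(meta={"trap": f"t{s}"})
            for s in range(n)
        ]
        wset = align_by_event(traces, "stimulus")
        template = ap_clean.values[: wset.aligned.shape[1]]
        return np.sqrt(np.mean((wset.mean - template) ** 2))

    assert rmse(40) < rmse(5)
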
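"""Waveform statistics: AP features, WASP features, and SNR.

All amplitude measurements are taken relative to the mean of a stated
baseline segment, and crossing times are refined by linear interpolation
between the bracketing samples (sub-sample resolution).  Ties at equal
extrema resolve to the earliest sample.

SNR follows the benchmark definition: peak amplitude of the waveform
(current or voltage) divided by the sample standard deviation of the
unstimulated baseline segment.  It is dimensionless, so recordings in volts
and in amperes are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FeatureUndefinedError, InvalidArgumentError, UndefinedSNRError
from .trace import Trace

__all__ = [
    "APFeatures",
    "WASPFeatures",
    "SNRResult",
    "ap_features",
    "wasp_features",
    "snr",
    "snr_of_trace",
    "snr_db",
]

#: Guard between the end of the baseline window and the stimulus (s).
BASELINE_GUARD_S = 1.0


@dataclass
class APFeatures:
    """Operational statistics of a fast (action-potential) waveform.

    ``min_amplitude`` is the most negative deflection relative to the
    baseline mean; ``half_width_s`` the time between the two crossings of
    half that amplitude; ``max_down_slope``/``max_up_slope`` the extremes of
    the first temporal derivative (the up slope restricted to the segment
    between the minimum and its subsequent maximum).
    """

    min_amplitude: float
    peak_to_peak: float
    max_down_slope: float
    max_up_slope: float
    half_width_s: float


@dataclass
class WASPFeatures:
    """Operational statistics of a slow (wound-response) waveform.

    ``latency_s``: time from laser-on to the first crossing of half the
    maximal deflection.  ``duration_s``: time from laser-on to recovery,
    the first zero of the first temporal derivative after the extremum.
    When the derivative never returns to zero within the record,
    ``recovered`` is False and ``duration_s`` is the record end time.
    """

    latency_s: float
    duration_s: float
    amplitude: float
    recovered: bool = True


@dataclass
class SNRResult:
    """Signal-to-noise ratio of one recording.

    ``snr = peak_amplitude / baseline_sd`` with the sample (n-1) standard
    deviation of the baseline segment.
    """

    snr: float
    peak_amplitude: float = float("nan")
    baseline_sd: float = float("nan")
    baseline_window: tuple = (float("nan"), float("nan"))


# ---------------------------------------------------------------------------
# crossing helpers


def _cross_time(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    """Linear-interpolated time at which the segment crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _half_crossings(x: np.ndarray, fs: float, imin: int, level: float) -> tuple[float, float]:
    """Times of the half-amplitude crossings either side of the minimum."""
    left = None
    for i in range(imin, 0, -1):
        if x[i - 1] >= level:
            left = _cross_time((i - 1) / fs, i / fs, x[i - 1], x[i], level)
            break
    right = None
    for i in range(imin, x.size - 1):
        if x[i + 1] >= level:
            right = _cross_time(i / fs, (i + 1) / fs, x[i], x[i + 1], level)
            break
    if left is None or right is None:
        raise FeatureUndefinedError(
            "half_width undefined: waveform does not recross half amplitude "
            "on both sides of its minimum (truncated record?)"
        )
    return left, right


# ---------------------------------------------------------------------------
# AP features


def ap_features(waveform: np.ndarray, fs: float, baseline: np.ndarray) -> APFeatures:
    """Fast-signal statistics of a smoothed, aligned waveform.

    ``baseline`` is a pre-event segment used only for its mean.  The
    waveform must contain a genuine negative deflection; a flat input
    raises :class:`FeatureUndefinedError`.
    """
    y = np.asarray(waveform, float)
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    b = float(np.mean(baseline))
    x = y - b
    if np.ptp(x) == 0:
        raise FeatureUndefinedError("flat waveform: AP features undefined")
    imin = int(np.argmin(x))
    min_amp = float(x[imin])
    if min_amp >= 0:
        raise FeatureUndefinedError("no negative deflection: AP features undefined")
    ptp = float(x.max() - x.min())
    d = np.gradient(x) * fs
    max_down = float(d.min())
    imax_after = imin + int(np.argmax(x[imin:]))
    seg = d[imin : imax_after + 1] if imax_after > imin else d[imin : imin + 1]
    max_up = float(seg.max())
    left, right = _half_crossings(x, fs, imin, min_amp / 2.0)
    return APFeatures(
        min_amplitude=min_amp,
        peak_to_peak=ptp,
        max_down_slope=max_down,
        max_up_slope=max_up,
        half_width_s=right - left,
    )


# ---------------------------------------------------------------------------
# WASP features


def wasp_features(
    waveform: np.ndarray,
    fs: float,
    t: np.ndarray,
    baseline: np.ndarray,
    derivative_smooth_s: float = 2.0,
    min_persist: int = 3,
) -> WASPFeatures:
    """Slow-signal statistics on a time axis with laser-on at t = 0.

    The recovery point is the first zero crossing of the first temporal
    derivative after the extremum.  Because the derivative of a
    tens-of-seconds tail sampled at 100 Hz is dominated by sample-scale
    noise, the derivative is trend-smoothed with a Gaussian window
    (``derivative_smooth_s``, same +/-3 sigma convention as waveform
    smoothing) before the crossing search, and the crossing must persist for
    ``min_persist`` samples.  If the derivative never recrosses zero, the
    record end is reported with ``recovered=False``.
    """
    y = np.asarray(waveform, float)
    t = np.asarray(t, float)
    if y.shape != t.shape:
        raise InvalidArgumentError("waveform and time axis must match")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    b = float(np.mean(baseline))
    x = y - b
    post = t >= 0
    if not post.any():
        raise InvalidArgumentError("time axis contains no post-laser samples")
    xp = np.where(post, x, 0.0)
    iext = int(np.argmax(np.abs(xp)))
    amplitude = float(x[iext])
    if amplitude == 0:
        raise FeatureUndefinedError("flat waveform: WASP features undefined")
    sign = np.sign(amplitude)

    # latency: first crossing of half the extremal deflection after t = 0
    half = amplitude / 2.0
    start = int(np.argmax(post))
    latency = None
    for i in range(start, iext):
        if sign * x[i + 1] >= sign * half and sign * x[i] < sign * half:
            latency = _cross_time(t[i], t[i + 1], sign * x[i], sign * x[i + 1], sign * half)
            break
    if latency is None:
        latency = float(t[iext])

    # duration: first derivative zero after the extremum
    d = np.gradient(x) * fs
    if derivative_smooth_s > 0:
        d = ndimage.gaussian_filter1d(d, derivative_smooth_s / 6.0 * fs, mode="reflect", truncate=3.0)
    rec_sign = -sign  # derivative sign while recovering toward baseline
    duration = float(t[-1])
    recovered = False
    for i in range(iext + 1, x.size - 1):
        if rec_sign * d[i] > 0 and rec_sign * d[i + 1] <= 0:
            stop = min(x.size, i + 1 + min_persist)
            if np.all(rec_sign * d[i + 1 : stop] <= 0):
                duration = _cross_time(t[i], t[i + 1], d[i], d[i + 1], 0.0)
                recovered = True
                break
    return WASPFeatures(
        latency_s=float(latency),
        duration_s=float(duration),
        amplitude=amplitude,
        recovered=recovered,
    )


# ---------------------------------------------------------------------------
# SNR


def snr(waveform: np.ndarray, baseline: np.ndarray, baseline_window=(float("nan"), float("nan"))) -> SNRResult:
    """Peak amplitude over baseline standard deviation.

    ``baseline`` must hold at least 100 samples of unstimulated recording
    and exclude the response; zero baseline variance raises
    :class:`UndefinedSNRError` rather than returning infinity.
    """
    y = np.asarray(waveform, float)
    b = np.asarray(baseline, float)
    if b.size < 100:
        raise InvalidArgumentError("baseline segment must hold at least 100 samples")
    sd = float(b.std(ddof=1))
    if sd == 0:
        raise UndefinedSNRError("baseline variance is zero; SNR undefined")
    peak = float(np.max(np.abs(y - b.mean())))
    return SNRResult(snr=peak / sd, peak_amplitude=peak, baseline_sd=sd,
                     baseline_window=tuple(baseline_window))


def snr_of_trace(
    trace: Trace,
    stimulus_label: str | None = None,
    guard_s: float = BASELINE_GUARD_S,
) -> SNRResult:
    """SNR of a session trace using its pre-stimulus segment as baseline.

    The baseline spans from the record start to ``guard_s`` before the
    stimulus event (``stimulus`` or ``laser_on``, whichever is present); the
    peak is searched after the stimulus.
    """
    if stimulus_label is None:
        stimulus_label = "stimulus" if trace.has_event("stimulus") else "laser_on"
    t_stim = trace.event_time(stimulus_label)
    i_stim = trace.index_of(t_stim)
    i_guard = max(0, i_stim - int(round(guard_s * trace.fs)))
    baseline = trace.values[:i_guard]
    response = trace.values[i_stim:]
    return snr(response, baseline, baseline_window=(trace.t0, trace.t0 + i_guard / trace.fs))


def snr_db(a: SNRResult, b: SNRResult) -> float:
    """Difference between two SNRs in decibels: 20 log10(a/b)."""
    if a.snr <= 0 or b.snr <= 0:
        raise InvalidArgumentError("snr values must be positive")
    return 20.0 * float(np.log10(a.snr / b.snr))
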
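"""Preprocessing chain: downsample, highpass, smooth, align, average.

The fixed stage order for fast signals (VFT action potentials) is
downsample -> 2nd-order Bessel highpass (0.01 Hz) -> align on the steepest
deflection -> per-trap averaging -> Gaussian smoothing (200 ms window).
Slow signals (WASPs) skip the highpass and are aligned on the laser-on
event instead, with a 500 ms smoothing window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from .errors import AlignmentError, InvalidArgumentError
from .trace import Trace

__all__ = [
    "WaveformSet",
    "downsample",
    "highpass_bessel",
    "gaussian_smooth",
    "align_by_steepest_deflection",
    "align_by_event",
    "average_per_trap",
]

#: Guard stripped from each end of the default alignment search window (s).
ALIGN_GUARD_S = 1.0


@dataclass
class WaveformSet:
    """Aligned equal-length waveforms on a common relative time axis.

    ``t`` is time in seconds relative to the alignment point (derivative
    minimum or stimulus event).  ``per_trial_meta`` carries device, cage
    flag, plant and trap/leaf identifiers for each row.  The pointwise mean
    and 95% confidence band (mean +/- 1.96 SEM) are recomputed on demand, so
    they always reflect current membership.
    """

    aligned: np.ndarray  # (n_waveforms, n_samples)
    fs: float
    t: np.ndarray
    per_trial_meta: list = field(default_factory=list)

    def __post_init__(self):
        self.aligned = np.atleast_2d(np.asarray(self.aligned, float))
        self.t = np.asarray(self.t, float)
        if self.aligned.shape[1] != self.t.size:
            raise InvalidArgumentError("time axis does not match waveform length")
        if self.per_trial_meta and len(self.per_trial_meta) != self.aligned.shape[0]:
            raise InvalidArgumentError("per_trial_meta length mismatch")

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.aligned.mean(axis=0)

    @property
    def ci95(self) -> np.ndarray:
        """Pointwise half-width of the 95% confidence band (1.96 x SEM)."""
        if self.n < 2:
            return np.zeros(self.aligned.shape[1])
        sem = self.aligned.std(axis=0, ddof=1) / np.sqrt(self.n)
        return 1.96 * sem


# ---------------------------------------------------------------------------
# samplewise stages


def downsample(trace: Trace, target_fs: float) -> Trace:
    """Anti-alias filter and decimate to ``target_fs``.

    Event times are in seconds and therefore unchanged.  Polyphase
    resampling handles any rational rate ratio; ``target_fs == fs`` is an
    exact pass-through.
    """
    if target_fs <= 0:
        raise InvalidArgumentError("target_fs must be positive")
    if target_fs > trace.fs:
        raise InvalidArgumentError(
            f"target_fs {target_fs} Hz exceeds trace rate {trace.fs} Hz"
        )
    if target_fs == trace.fs:
        return trace.replace()
    ratio = Fraction(target_fs / trace.fs).limit_denominator(10**6)
    # line-extension padding keeps large DC operating points (OECT bias
    # current) from ringing at the record edges
    out = signal.resample_poly(
        trace.values, ratio.numerator, ratio.denominator, padtype="line"
    )
    res = trace.replace(values=out, fs=target_fs)
    res.log_stage("downsample", target_fs=target_fs)
    return res


def highpass_bessel(trace: Trace, fc: float = 0.01, order: int = 2) -> Trace:
    """Causal digital realization of an analog Bessel highpass.

    The analog prototype (magnitude-normalized, so |H| = 1/sqrt(2) at fc) is
    discretized by the bilinear transform with prewarping at fc and applied
    in a single forward pass, matching the causal behavior of an instrument
    filter.  Removes DC and baseline wander below fc.

    Initial conditions assume the first sample's level has been applied
    forever (the instrument was connected long before the record starts), so
    a large DC operating point — e.g. the OECT bias current — does not
    excite a multi-hundred-second start-up transient.
    """
    if fc <= 0:
        raise InvalidArgumentError("fc must be positive")
    if fc >= trace.fs / 2:
        raise InvalidArgumentError("fc must be below the Nyquist frequency")
    sos = signal.bessel(order, fc, btype="highpass", norm="mag", fs=trace.fs, output="sos")
    zi = signal.sosfilt_zi(sos) * trace.values[0]
    out, _ = signal.sosfilt(sos, trace.values, zi=zi)
    res = trace.replace(values=np.asarray(out))
    res.log_stage("highpass_bessel", fc=fc, order=order)
    return res


def gaussian_smooth(trace: Trace, window_s: float) -> Trace:
    """Convolve with a unit-area Gaussian kernel.

    ``window_s`` is the total +/-3 sigma support of the kernel, i.e.
    sigma = window_s / 6 (the common "window size" convention for Gaussian
    averaging filters).  Edges are handled by reflection, preserving the
    mean of interior-supported signals.
    """
    if window_s < 2.0 / trace.fs:
        raise InvalidArgumentError("window must span at least 2 samples")
    sigma = window_s / 6.0 * trace.fs
    out = ndimage.gaussian_filter1d(trace.values, sigma, mode="reflect", truncate=3.0)
    res = trace.replace(values=out)
    res.log_stage("gaussian_smooth", window_s=window_s)
    return res


def smooth_array(y: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Array version of :func:`gaussian_smooth` for aligned waveforms."""
    sigma = window_s / 6.0 * fs
    return ndimage.gaussian_filter1d(np.asarray(y, float), sigma, mode="reflect", truncate=3.0)


# ---------------------------------------------------------------------------
# alignment


def _search_bounds(trace: Trace, window: tuple[float, float] | None) -> tuple[int, int]:
    """Sample bounds of the alignment search window.

    Default: from the stimulus event (or the record start) to the record
    end, minus 1 s guard bands at each extreme.
    """
    if window is not None:
        lo = max(0, int(np.ceil((window[0] - trace.t0) * trace.fs)))
        hi = min(trace.n, int(np.floor((window[1] - trace.t0) * trace.fs)) + 1)
    else:
        guard = int(round(ALIGN_GUARD_S * trace.fs))
        lo = guard
        if trace.has_event("stimulus"):
            # start slightly before the stimulus: the steepest deflection of a
            # stimulus-locked AP can coincide with the event sample itself
            i_stim = trace.index_of(trace.event_time("stimulus"))
            lo = max(guard, i_stim - int(round(0.5 * trace.fs)))
        hi = trace.n - guard
    if hi - lo < 3:
        raise InvalidArgumentError("alignment search window is too short")
    return lo, hi


def align_by_steepest_deflection(
    traces: list[Trace],
    window: tuple[float, float] | None = None,
) -> WaveformSet:
    """Align traces on the minimum of their first temporal derivative.

    For each trace the global minimum of the central-difference derivative
    inside the search window is the alignment point (ties broken by the
    earliest index); all traces are cropped to the largest common window
    around it.  Flat traces (derivative indistinguishable from constant)
    raise :class:`AlignmentError`.
    """
    if not traces:
        raise InvalidArgumentError("no traces to align")
    fs = traces[0].fs
    if any(tr.fs != fs for tr in traces):
        raise InvalidArgumentError("traces must share a sampling rate")
    idx = []
    for k, tr in enumerate(traces):
        lo, hi = _search_bounds(tr, window)
        d = np.gradient(tr.values) * fs
        dw = d[lo:hi]
        scale = max(np.abs(tr.values).max(), 1e-30)
        if np.ptp(dw) <= 1e-9 * scale * fs:
            raise AlignmentError(
                f"trace {k}: derivative is flat in the search window; "
                "steepest-deflection alignment undefined"
            )
        i = lo + int(np.argmin(dw))
        if i <= lo or i >= hi - 1:
            raise AlignmentError(
                f"trace {k}: derivative minimum sits on the window boundary "
                "(monotone segment?); alignment undefined"
            )
        idx.append(i)
    pre = min(idx)
    post = min(tr.n - i for tr, i in zip(traces, idx))
    aligned = np.stack([tr.values[i - pre : i + post] for tr, i in zip(traces, idx)])
    t = (np.arange(pre + post) - pre) / fs
    meta = [dict(tr.meta) for tr in traces]
    return WaveformSet(aligned=aligned, fs=fs, t=t, per_trial_meta=meta)


def align_by_event(traces: list[Trace], label: str = "laser_on") -> WaveformSet:
    """Align traces so that the named event is at t = 0.

    Crops all traces to the intersection of their spans around the event.
    A trace missing the event (or whose event lies outside the recorded
    span) raises :class:`InvalidArgumentError` naming the trace.
    """
    if not traces:
        raise InvalidArgumentError("no traces to align")
    fs = traces[0].fs
    if any(tr.fs != fs for tr in traces):
        raise InvalidArgumentError("traces must share a sampling rate")
    idx = []
    for k, tr in enumerate(traces):
        if not tr.has_event(label):
            raise InvalidArgumentError(f"trace {k} has no event {label!r}")
        idx.append(tr.index_of(tr.event_time(label)))
    pre = min(idx)
    post = min(tr.n - i for tr, i in zip(traces, idx))
    aligned = np.stack([tr.values[i - pre : i + post] for tr, i in zip(traces, idx)])
    t = (np.arange(pre + post) - pre) / fs
    meta = [dict(tr.meta) for tr in traces]
    return WaveformSet(aligned=aligned, fs=fs, t=t, per_trial_meta=meta)


# ---------------------------------------------------------------------------
# replication structure


def average_per_trap(wset: WaveformSet, key: str = "trap") -> WaveformSet:
    """Average waveforms recorded from the same trap/leaf (N = 1 rule).

    Waveforms sharing a trap identifier are replaced by their pointwise
    mean, so the effective N equals the number of unique traps.  Order of
    first appearance is preserved.
    """
    if not wset.per_trial_meta or any(key not in m for m in wset.per_trial_meta):
        raise InvalidArgumentError(f"per_trial_meta must carry a {key!r} id for every waveform")
    order: dict[str, list[int]] = {}
    for i, m in enumerate(wset.per_trial_meta):
        order.setdefault(str(m[key]), []).append(i)
    rows, metas = [], []
    for trap, members in order.items():
        rows.append(wset.aligned[members].mean(axis=0))
        m = dict(wset.per_trial_meta[members[0]])
        m["n_averaged"] = len(members)
        metas.append(m)
    return WaveformSet(aligned=np.stack(rows), fs=wset.fs, t=wset.t.copy(), per_trial_meta=metas)
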
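"""Time-frequency scalograms and narrowband-interference quantification.

The scalogram is the magnitude of a continuous wavelet transform with an
analytic (complex) Morlet wavelet on a log-spaced frequency grid, normalized
to a global maximum of 1 — the standard way to visualize where a biosignal's
energy lives in time and frequency, and to spot 50 Hz mains or 40 Hz laser
interference bands.

Because 100 Hz data place the 50 Hz mains exactly at Nyquist, narrowband
analyses are meant to run on a 200 Hz (or native-rate) copy of the trace.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from .errors import InvalidArgumentError
from .trace import Trace

__all__ = ["Scalogram", "scalogram", "narrowband_power", "waveform_correlation"]

#: Analytic Morlet with bandwidth 1.5 and center frequency 1.0 (in pywt's
#: normalized units); a smooth single-lobe wavelet, adequate for sub-50 Hz
#: plant-signal content.
DEFAULT_WAVELET = "cmor1.5-1.0"


@dataclass
class Scalogram:
    """|CWT| magnitude matrix, normalized to max 1, on (freqs x times)."""

    freqs: np.ndarray
    times: np.ndarray
    magnitude: np.ndarray
    wavelet: str

    def __post_init__(self):
        if self.magnitude.shape != (self.freqs.size, self.times.size):
            raise InvalidArgumentError("magnitude dims must be freqs x times")


def scalogram(
    trace: Trace,
    f_min: float = 0.1,
    f_max: float = 50.0,
    n_freqs: int = 64,
    wavelet: str = DEFAULT_WAVELET,
) -> Scalogram:
    """Continuous-wavelet scalogram on a log-spaced frequency grid.

    ``f_max`` must stay below Nyquist and ``f_min`` above the reciprocal
    record length.  An all-zero trace yields an all-zero magnitude (the
    normalization guard never divides by zero).
    """
    nyq = trace.fs / 2.0
    if not (0 < f_min < f_max):
        raise InvalidArgumentError("need 0 < f_min < f_max")
    if f_max >= nyq:
        raise InvalidArgumentError(f"f_max must be below Nyquist ({nyq} Hz)")
    if f_min <= 1.0 / trace.duration:
        raise InvalidArgumentError("f_min must exceed 1 / record length")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_freqs)
    scales = pywt.frequency2scale(wavelet, freqs / trace.fs)
    coef, _ = pywt.cwt(trace.values, scales, wavelet, sampling_period=1.0 / trace.fs)
    mag = np.abs(coef)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return Scalogram(freqs=freqs, times=trace.times, magnitude=mag, wavelet=wavelet)


def narrowband_power(trace: Trace, f0: float, bandwidth: float) -> float:
    """Fraction of total spectral power within f0 +/- bandwidth/2.

    Periodogram integration; quantifies how much of a recording is 50 Hz
    mains pickup (cage off vs on) or 40 Hz laser artifact.
    """
    if bandwidth <= 0 or f0 <= 0:
        raise InvalidArgumentError("f0 and bandwidth must be positive")
    if f0 + bandwidth / 2.0 >= trace.fs / 2.0:
        raise InvalidArgumentError("band extends beyond Nyquist")
    f, pxx = sps.periodogram(trace.values, fs=trace.fs, detrend=False)
    total = pxx.sum()
    if total == 0:
        return 0.0
    mask = np.abs(f - f0) <= bandwidth / 2.0
    return float(pxx[mask].sum() / total)


def waveform_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two mean waveforms on a common axis."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise InvalidArgumentError("waveforms must share length and time axis")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidArgumentError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, b).statistic)
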
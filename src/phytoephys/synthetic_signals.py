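"""Synthetic plant surface-potential waveforms and recording sessions.

Two signal classes are emulated:

* Venus-flytrap action potentials (APs): fast, stereotyped, all-or-nothing
  spikes, treated as downward (negative-first) surface deflections so that
  minimum amplitude and maximal down slope are the primary statistics.
* Arabidopsis wound-activated surface potential changes (WASPs): a laser
  burn triggers, after a latency, a rapid depolarization followed by a slow
  and variable recovery tail lasting tens of seconds.

Noise sources mirror a bench recording: Gaussian sensor noise, slow baseline
wander, 50 Hz mains pickup attenuated by a Faraday cage, and a 40 Hz
artifact present only while the wounding laser is active.

All generation is seeded and bit-reproducible; sessions derive per-trial
seeds from a master seed by a counter scheme so that adding trials never
perturbs earlier ones.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import expit

from .errors import InvalidArgumentError
from .trace import Trace

__all__ = [
    "APShapeParams",
    "WASPShapeParams",
    "NoiseModel",
    "SessionProtocol",
    "generate_vft_ap",
    "generate_wasp",
    "add_noise",
    "generate_session",
    "noise_free_template",
    "child_rng",
]

#: Laser exposure used for wounding when no explicit laser_off event exists.
DEFAULT_LASER_WINDOW_S = 1.0

MAINS_HZ = 50.0
LASER_HZ = 40.0


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class APShapeParams:
    """Shape of a Venus-flytrap surface action potential.

    The template is a product of two sigmoids: a fast sigmoidal drop
    (``rise_tau_s``) into the depolarized state and a slower sigmoidal
    recovery (``fall_tau_s``).  The leading edge is the steepest part of the
    trace, which is what derivative-minimum alignment relies on.
    ``jitter`` is the relative s.d. applied multiplicatively to amplitude
    and both time constants across trials.
    """

    amplitude_mV: float = 40.0
    rise_tau_s: float = 0.08
    fall_tau_s: float = 0.5
    polarity: str = "negative_first"
    jitter: float = 0.1

    def __post_init__(self):
        if self.amplitude_mV <= 0:
            raise InvalidArgumentError("amplitude_mV must be positive")
        if self.rise_tau_s <= 0 or self.fall_tau_s <= 0:
            raise InvalidArgumentError("time constants must be positive")
        if self.jitter < 0:
            raise InvalidArgumentError("jitter must be non-negative")
        if self.polarity != "negative_first":
            raise InvalidArgumentError("only negative_first polarity is modeled")


@dataclass
class WASPShapeParams:
    """Shape of an Arabidopsis wound-activated surface potential change.

    Zero baseline until ``latency_s`` after the laser, then a
    ``(1 - exp(-t/depol_tau_s))`` rise multiplied by an
    ``exp(-t/recovery_tau_s)`` decay.  A small Gaussian "rebound" bump
    (``rebound_frac`` of the peak, centred at 2.5 x recovery_tau) terminates
    the recovery at a finite time, so the recovery point — the first zero of
    the first temporal derivative after the extremum — is well defined
    instead of being pushed to infinity by a pure exponential tail.

    ``tail_variability`` is the relative s.d. of ``recovery_tau_s`` across
    trials and also scales a low-pass-filtered roughness added to the tail
    only, reproducing the irregular shape and duration of real WASPs while
    the rising phase stays stereotyped.
    """

    amplitude_mV: float = 30.0
    depol_tau_s: float = 2.0
    recovery_tau_s: float = 8.0
    tail_variability: float = 0.25
    latency_s: float = 1.0
    rebound_frac: float = 0.06

    def __post_init__(self):
        for name in ("amplitude_mV", "depol_tau_s", "recovery_tau_s", "latency_s"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.tail_variability < 0 or self.rebound_frac < 0:
            raise InvalidArgumentError(
                "tail_variability and rebound_frac must be non-negative"
            )
        if self.recovery_tau_s <= self.depol_tau_s:
            raise InvalidArgumentError("recovery_tau_s must exceed depol_tau_s")


@dataclass
class NoiseModel:
    """Additive disturbances of a recording session.

    Amplitudes are in the signal units of the trace the noise is added to
    (volts for surface recordings).  ``drift_amp`` is the r.m.s. of the
    low-frequency baseline wander (white noise low-passed at
    ``drift_fc_hz``).  ``mains_amp_50hz`` is the 50 Hz sinusoid amplitude;
    inside a Faraday cage (``cage=True``) it is multiplied by
    ``cage_attenuation``.  ``laser_amp_40hz`` is only applied while a
    laser_on event window is active.
    """

    baseline_sd: float = 1.5e-3
    drift_amp: float = 0.5e-3
    drift_fc_hz: float = 0.005
    mains_amp_50hz: float = 4.5e-3
    laser_amp_40hz: float = 2.0e-3
    cage: bool = False
    cage_attenuation: float = 0.01

    def __post_init__(self):
        for name in ("baseline_sd", "drift_amp", "mains_amp_50hz", "laser_amp_40hz"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if self.drift_fc_hz <= 0:
            raise InvalidArgumentError("drift_fc_hz must be positive")
        if not (0 <= self.cage_attenuation < 1):
            raise InvalidArgumentError("cage_attenuation must be in [0, 1)")

    @property
    def effective_mains_amp(self) -> float:
        return self.mains_amp_50hz * (self.cage_attenuation if self.cage else 1.0)

    def highest_frequency(self) -> float:
        """Highest deterministic frequency this model injects."""
        f = 0.0
        if self.mains_amp_50hz > 0:
            f = max(f, MAINS_HZ)
        if self.laser_amp_40hz > 0:
            f = max(f, LASER_HZ)
        return f


@dataclass
class SessionProtocol:
    """Timing and replication of a stimulation session.

    20 s of quiet baseline precede the stimulus (trigger-hair touch or
    laser-on); the native acquisition rate defaults to 1 kHz so the
    downsample-to-100-Hz stage of the analysis chain is exercised.
    """

    baseline_s: float = 20.0
    post_s: float = 20.0
    fs_acquire: float = 1000.0
    n_trials: int = 10
    seed: int = 0
    laser_s: float = DEFAULT_LASER_WINDOW_S
    trials_per_plant: int = 3

    def __post_init__(self):
        if self.baseline_s < 0:
            raise InvalidArgumentError("baseline_s must be non-negative")
        if self.post_s <= 0 or self.fs_acquire <= 0:
            raise InvalidArgumentError("post_s and fs_acquire must be positive")
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be at least 1")

    @property
    def stimulus_time_s(self) -> float:
        return self.baseline_s

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.post_s


# ---------------------------------------------------------------------------
# seeding


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Per-trial random generator derived from a master seed.

    The child stream is ``SeedSequence(master_seed, spawn_key=key)``; the
    key is a counter tuple (e.g. condition index, trial index, stream
    index), so adding trials or conditions never perturbs earlier streams.
    """
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    )


# ---------------------------------------------------------------------------
# noise-free templates


def _ap_shape(t: np.ndarray, onset: float, rise_tau: float, fall_tau: float) -> np.ndarray:
    """Unit-height AP shape: fast sigmoidal drop x slower sigmoidal recovery."""
    plateau = 2.0 * fall_tau
    return expit((t - onset) / rise_tau) * expit((onset + plateau - t) / fall_tau)


def _wasp_shape(
    t: np.ndarray,
    onset: float,
    latency: float,
    depol_tau: float,
    recovery_tau: float,
    rebound_frac: float,
) -> np.ndarray:
    """Unit-scale WASP shape (positive-going; caller flips sign)."""
    u = t - onset - latency
    pos = u > 0
    up = np.where(pos, u, 0.0)
    core = -np.expm1(-up / depol_tau) * np.exp(-up / recovery_tau)
    t_reb = 2.5 * recovery_tau
    w_reb = 0.5 * recovery_tau
    rebound = rebound_frac * np.exp(-0.5 * ((up - t_reb) / w_reb) ** 2)
    return np.where(pos, core - rebound, 0.0)


def _jittered(value: float, jitter: float, rng: np.random.Generator) -> float:
    """Multiplicative Gaussian jitter, clipped to stay positive."""
    if jitter == 0:
        return value
    return value * float(np.clip(1.0 + jitter * rng.standard_normal(), 0.2, None))


def generate_vft_ap(
    params: APShapeParams,
    fs: float,
    duration_s: float,
    seed=None,
    onset_s: float | None = None,
) -> Trace:
    """Noise-free Venus-flytrap action potential template.

    Returns a surface-potential trace in volts with zero baseline and a
    single negative-first deflection whose sampled minimum equals
    ``-amplitude_mV`` exactly (within jitter).  A ``stimulus`` event marks
    the onset.
    """
    if fs <= 0 or duration_s <= 0:
        raise InvalidArgumentError("fs and duration_s must be positive")
    if onset_s is None:
        onset_s = duration_s / 3.0
    rng = np.random.default_rng(seed)
    amp = _jittered(params.amplitude_mV, params.jitter, rng)
    rise = _jittered(params.rise_tau_s, params.jitter, rng)
    fall = _jittered(params.fall_tau_s, params.jitter, rng)
    if duration_s < onset_s + 5.0 * fall:
        raise InvalidArgumentError(
            "duration_s too short: need at least onset_s + 5 x fall_tau_s"
        )
    t = np.arange(int(round(duration_s * fs))) / fs
    shape = _ap_shape(t, onset_s, rise, fall)
    values = -(amp * 1e-3) * shape / shape.max()
    return Trace(
        values=values,
        fs=fs,
        units="V",
        device="surface",
        events=[("stimulus", onset_s)],
        meta={
            "kind": "vft",
            "realized": {
                "amplitude_mV": amp,
                "rise_tau_s": rise,
                "fall_tau_s": fall,
                "onset_s": onset_s,
            },
        },
    )


def generate_wasp(
    params: WASPShapeParams,
    fs: float,
    duration_s: float,
    seed=None,
    onset_s: float | None = None,
) -> Trace:
    """Noise-free wound-activated surface potential change template.

    The trace is zero until ``latency_s`` after the laser-on time
    (``onset_s``), then depolarizes (negative-going) and recovers with an
    exponential tail terminated by a small rebound.  ``laser_on`` and
    ``laser_off`` events are attached.
    """
    if fs <= 0 or duration_s <= 0:
        raise InvalidArgumentError("fs and duration_s must be positive")
    if onset_s is None:
        onset_s = duration_s / 6.0
    rng = np.random.default_rng(seed)
    recovery = _jittered(params.recovery_tau_s, params.tail_variability, rng)
    recovery = max(recovery, 1.5 * params.depol_tau_s)
    if duration_s <= onset_s + params.latency_s:
        raise InvalidArgumentError("record ends before the response begins")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    shape = _wasp_shape(
        t, onset_s, params.latency_s, params.depol_tau_s, recovery, params.rebound_frac
    )
    peak = shape.max()
    values = -(params.amplitude_mV * 1e-3) * shape / peak

    if params.tail_variability > 0:
        # low-pass-filtered roughness confined to the tail; the rising phase
        # stays stereotyped
        rough = _lowpassed_noise(n, fs, fc=0.2, rng=rng)
        u = t - onset_s - params.latency_s
        t_peak = t[int(np.argmax(shape))] - onset_s - params.latency_s
        gate = np.clip((u - t_peak) / (2.0 * params.depol_tau_s), 0.0, 1.0)
        gate *= np.exp(-np.clip(u - t_peak, 0.0, None) / (4.0 * recovery))
        sd = params.tail_variability * 0.03 * params.amplitude_mV * 1e-3
        values = values + sd * rough * gate

    laser_off = min(onset_s + DEFAULT_LASER_WINDOW_S, duration_s / 1.0)
    return Trace(
        values=values,
        fs=fs,
        units="V",
        device="surface",
        events=[("laser_on", onset_s), ("laser_off", laser_off)],
        meta={
            "kind": "wasp",
            "realized": {
                "amplitude_mV": params.amplitude_mV,
                "depol_tau_s": params.depol_tau_s,
                "recovery_tau_s": recovery,
                "latency_s": params.latency_s,
                "rebound_frac": params.rebound_frac,
                "onset_s": onset_s,
            },
        },
    )


def noise_free_template(
    kind: str,
    shape,
    fs: float,
    duration_s: float,
    onset_s: float | None = None,
) -> Trace:
    """Template with all trial-to-trial variability switched off.

    This is the ground-truth waveform that the ensemble mean of noisy trials
    converges to, and the reference against which parameter recovery is
    judged.
    """
    if kind == "vft":
        clean = dataclasses.replace(shape, jitter=0.0)
        return generate_vft_ap(clean, fs, duration_s, seed=0, onset_s=onset_s)
    if kind == "wasp":
        clean = dataclasses.replace(shape, tail_variability=0.0)
        return generate_wasp(clean, fs, duration_s, seed=0, onset_s=onset_s)
    raise InvalidArgumentError(f"unknown signal kind {kind!r}")


# ---------------------------------------------------------------------------
# noise


def _lowpassed_noise(n: int, fs: float, fc: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-r.m.s. Gaussian noise low-passed at fc.

    Generated on a coarse grid (a few samples per correlation time) and
    interpolated, so ultra-low corner frequencies stay numerically benign at
    kHz sampling rates.
    """
    fs_coarse = min(fs, max(1.0, 50.0 * fc))
    n_coarse = max(64, int(np.ceil(n * fs_coarse / fs)) + 8)
    white = rng.standard_normal(n_coarse)
    sos = signal.butter(2, fc, btype="lowpass", fs=fs_coarse, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    t_coarse = np.arange(n_coarse) / fs_coarse
    t = np.arange(n) / fs
    return np.interp(t, t_coarse, slow)


def _laser_mask(trace: Trace) -> np.ndarray:
    """Boolean mask of samples during which the wounding laser is active."""
    mask = np.zeros(trace.n, dtype=bool)
    offs = sorted(t for lbl, t in trace.events if lbl == "laser_off")
    for lbl, t_on in trace.events:
        if lbl != "laser_on":
            continue
        later = [t for t in offs if t > t_on]
        t_off = later[0] if later else t_on + DEFAULT_LASER_WINDOW_S
        times = trace.times
        mask |= (times >= t_on) & (times < t_off)
    return mask


def ambient_interference(trace: Trace, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Deterministic-frequency disturbances: drift + mains + laser artifact.

    Returned in the noise model's units (volts at the plant surface); the
    Gaussian sensor-noise floor is *not* included — it is device-specific
    and added by the recording models or by :func:`add_noise`.
    """
    nyq = trace.fs / 2.0
    f_max = noise.highest_frequency()
    if f_max >= nyq:
        raise InvalidArgumentError(
            f"sampling rate {trace.fs} Hz cannot represent {f_max} Hz interference"
        )
    t = trace.times
    out = np.zeros(trace.n)
    if noise.drift_amp > 0:
        out += noise.drift_amp * _lowpassed_noise(trace.n, trace.fs, noise.drift_fc_hz, rng)
    amp50 = noise.effective_mains_amp
    if amp50 > 0:
        out += amp50 * np.sin(2 * np.pi * MAINS_HZ * t + rng.uniform(0, 2 * np.pi))
    if noise.laser_amp_40hz > 0:
        mask = _laser_mask(trace)
        if mask.any():
            out += (
                noise.laser_amp_40hz
                * np.sin(2 * np.pi * LASER_HZ * t + rng.uniform(0, 2 * np.pi))
                * mask
            )
    return out


def add_noise(trace: Trace, noise: NoiseModel, seed=None) -> Trace:
    """Trace + Gaussian sensor noise + drift + mains + laser artifact.

    The input trace is left unmodified.  The 50 Hz component is scaled by
    the cage attenuation when ``noise.cage`` is true; the 40 Hz component
    only appears inside laser_on windows.
    """
    rng = np.random.default_rng(seed)
    out = trace.values + ambient_interference(trace, noise, rng)
    if noise.baseline_sd > 0:
        out = out + rng.normal(0.0, noise.baseline_sd, trace.n)
    noisy = trace.replace(values=out)
    noisy.meta["noise"] = dataclasses.asdict(noise)
    return noisy


# ---------------------------------------------------------------------------
# sessions


def generate_session(
    kind: str,
    shape,
    noise: NoiseModel,
    protocol: SessionProtocol,
) -> list[Trace]:
    """Repeated stimulation trials of one recording session.

    Each trial has its stimulus (``stimulus`` for VFT, ``laser_on`` /
    ``laser_off`` for WASP) at ``protocol.baseline_s`` and is independently
    seeded from ``protocol.seed``.  Trial metadata assigns plant and
    trap/leaf identifiers for later per-trap averaging.
    """
    if kind not in ("vft", "wasp"):
        raise InvalidArgumentError(f"unknown signal kind {kind!r}")
    if protocol.fs_acquire < 2.0 * noise.highest_frequency():
        raise InvalidArgumentError(
            "fs_acquire must be at least twice the highest injected frequency"
        )
    traces = []
    for trial in range(protocol.n_trials):
        shape_rng = child_rng(protocol.seed, trial, 0)
        noise_rng = child_rng(protocol.seed, trial, 1)
        if kind == "vft":
            clean = generate_vft_ap(
                shape, protocol.fs_acquire, protocol.duration_s,
                seed=shape_rng, onset_s=protocol.baseline_s,
            )
        else:
            clean = generate_wasp(
                shape, protocol.fs_acquire, protocol.duration_s,
                seed=shape_rng, onset_s=protocol.baseline_s,
            )
            clean.events = [
                ("laser_on", protocol.baseline_s),
                ("laser_off", protocol.baseline_s + protocol.laser_s),
            ]
        noisy = add_noise(clean, noise, seed=noise_rng)
        noisy.meta.update(
            plant=f"plant{trial // protocol.trials_per_plant + 1}",
            trap=f"trap{trial + 1:02d}",
            trial=trial,
            cage=noise.cage,
            master_seed=protocol.seed,
        )
        traces.append(noisy)
    return traces
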
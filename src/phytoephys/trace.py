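"""Uniformly sampled recording traces with units, provenance and events.

A :class:`Trace` holds one recording channel: surface potential in volts for
passive electrodes (or the bare plant surface potential itself), or drain
current in amperes for an organic electrochemical transistor (OECT).  Event
annotations (stimulus touch, laser on/off) are kept in seconds on the same
clock as the samples.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Recognized recording devices.  ``surface`` denotes a bare, noise-free
#: surface-potential template that has not yet passed through a device model.
DEVICES = ("electrode_agagcl", "electrode_pedotpss", "oect", "surface")

UNITS = ("V", "A")


@dataclass
class Trace:
    """One uniformly sampled signal with metadata.

    Parameters
    ----------
    values : ndarray
        Samples in ``units`` (volts or amperes).
    fs : float
        Sampling rate in Hz, must be positive.
    t0 : float
        Time of the first sample in seconds.
    units : {"V", "A"}
        Amperes if and only if the device is an OECT.
    device : str
        One of :data:`DEVICES`.
    events : list of (str, float)
        Labelled time points (seconds) within the recorded span.
    meta : dict
        Free-form provenance: plant id, trap/leaf id, cage flag, seed,
        realized generator parameters, pipeline stage log.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "V"
    device: str = "surface"
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InvalidArgumentError("values must be a non-empty 1-D array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("values must be finite")
        if self.units not in UNITS:
            raise InvalidArgumentError(f"units must be one of {UNITS}")
        if self.device not in DEVICES:
            raise InvalidArgumentError(f"device must be one of {DEVICES}")
        if (self.units == "A") != (self.device == "oect"):
            raise InvalidArgumentError(
                "units 'A' if and only if device is 'oect' "
                f"(got units={self.units!r}, device={self.device!r})"
            )
        self.events = [(str(lbl), float(t)) for lbl, t in self.events]
        end = self.t0 + self.n / self.fs
        for lbl, t in self.events:
            if not (self.t0 <= t <= end):
                raise InvalidArgumentError(
                    f"event {lbl!r} at t={t} s outside recorded span "
                    f"[{self.t0}, {end}] s"
                )

    # -- conveniences -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def event_time(self, label: str) -> float:
        """Time of the first event with the given label."""
        for lbl, t in self.events:
            if lbl == label:
                return t
        raise InvalidArgumentError(f"trace has no event {label!r}")

    def has_event(self, label: str) -> bool:
        return any(lbl == label for lbl, _ in self.events)

    def index_of(self, t: float) -> int:
        """Sample index nearest to time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.fs))
        if not (0 <= i < self.n):
            raise InvalidArgumentError(f"time {t} s outside recorded span")
        return i

    def replace(self, **kw) -> "Trace":
        """Copy of the trace with selected fields replaced.

        ``values``/``events``/``meta`` default to copies of the originals, so
        mutating the result never touches the source trace.
        """
        kw.setdefault("values", self.values.copy())
        kw.setdefault("events", list(self.events))
        kw.setdefault("meta", dict(self.meta))
        return dataclasses.replace(self, **kw)

    def log_stage(self, stage: str, **params) -> None:
        """Append a pipeline stage record to the provenance log."""
        self.meta.setdefault("pipeline", []).append(
            {"stage": stage, **params}
        )
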
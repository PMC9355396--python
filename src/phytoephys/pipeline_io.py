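"""File formats, configuration and end-to-end experiment orchestration.

Trace files are two-column delimited text (time_s, value) with a
structured-text sidecar (same basename, ``.meta`` suffix, YAML) carrying
sampling rate, units, device, events and free-form metadata; the round trip
is bit-exact for double-precision values.

:func:`run_experiment` drives the full benchmark: simulate surface
potentials, record them through each device model under each cage
condition, run the preprocessing chain, extract features and SNR, compare
groups statistically, and write a manifest from which the run can be
reconstructed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .device_models import (
    ElectrodeParams,
    GateConfig,
    OECTParams,
    record_with_electrode,
    record_with_oect,
)
from .errors import FormatError, InvalidArgumentError
from .features import (
    BASELINE_GUARD_S,
    ap_features,
    snr_of_trace,
    wasp_features,
)
from .preprocess import downsample, gaussian_smooth, highpass_bessel
from .stats_compare import two_way_anova_tukey
from .synthetic_signals import (
    APShapeParams,
    NoiseModel,
    SessionProtocol,
    WASPShapeParams,
    child_rng,
    generate_session,
    noise_free_template,
)
from .trace import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "DeviceSpec",
    "ExperimentConfig",
    "preprocess_trace",
    "trace_features",
    "ground_truth_features",
    "run_experiment",
]

#: Analysis-chain constants of the benchmark.
TARGET_FS = 100.0
HIGHPASS_FC = 0.01
HIGHPASS_ORDER = 2
SMOOTH_WINDOW_S = {"vft": 0.2, "wasp": 0.5}


# ---------------------------------------------------------------------------
# trace serialization


def _plain(obj):
    """Recursively convert numpy/dataclass content to YAML-safe builtins."""
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def write_trace(trace: Trace, path) -> None:
    """Write a trace as delimited text plus its ``.meta`` sidecar.

    Values are printed with 17 significant digits, which round-trips IEEE
    doubles exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for i, v in enumerate(trace.values):
            fh.write(f"{trace.t0 + i / trace.fs:.17g},{v:.17g}\n")
    sidecar = {
        "fs": float(trace.fs),
        "t0": float(trace.t0),
        "units": trace.units,
        "device": trace.device,
        "events": [[lbl, float(t)] for lbl, t in trace.events],
        "meta": _plain(trace.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_trace(path) -> Trace:
    """Read a trace file and its sidecar, validating format and timing.

    Malformed rows raise :class:`FormatError` with the offending line
    number; a missing sidecar, unit mismatch or non-monotone time column is
    also a format error.  Event validity (within the recorded span) is
    enforced by the :class:`Trace` constructor.
    """
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing sidecar {sc_path}")
    try:
        with open(sc_path) as fh:
            sidecar = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable sidecar {sc_path}: {exc}") from exc
    if not isinstance(sidecar, dict) or "fs" not in sidecar:
        raise FormatError(f"sidecar {sc_path} lacks required fields")

    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if lineno == 1 or not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError("expected two comma-separated columns", line=lineno)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"unparseable number in {parts}", line=lineno)
    if not values:
        raise FormatError("trace file holds no samples")
    times = np.asarray(times)
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 3  # +header +1-based +next row
        raise FormatError("time column is not strictly increasing", line=bad)
    fs = float(sidecar["fs"])
    t0 = float(sidecar.get("t0", times[0]))
    expected = t0 + np.arange(len(values)) / fs
    if np.max(np.abs(times - expected)) > 1e-6 / fs:
        raise FormatError("time column inconsistent with sidecar fs/t0")
    return Trace(
        values=np.asarray(values),
        fs=fs,
        t0=t0,
        units=sidecar.get("units", "V"),
        device=sidecar.get("device", "surface"),
        events=[(lbl, t) for lbl, t in sidecar.get("events", [])],
        meta=sidecar.get("meta", {}) or {},
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DeviceSpec:
    """One recording pathway of the benchmark."""

    name: str  # electrode_agagcl | electrode_pedotpss | oect
    electrode: ElectrodeParams | None = None
    oect: OECTParams | None = None
    gate: GateConfig | None = None

    def __post_init__(self):
        if self.name == "oect":
            self.oect = self.oect or OECTParams()
            self.gate = self.gate or GateConfig(mode="soil")
        elif self.name in ("electrode_agagcl", "electrode_pedotpss"):
            self.electrode = self.electrode or ElectrodeParams(name=self.name)
        else:
            raise InvalidArgumentError(f"unknown device {self.name!r}")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmark run.

    The defaults are the benchmark conditions: VFT signal, three devices
    (OECT with soil gate, Ag/AgCl and PEDOT:PSS electrodes), both cage
    conditions, 100 Hz analysis rate, 0.01 Hz order-2 highpass, 200/500 ms
    smoothing windows, and a single master seed from which every trial seed
    is derived.
    """

    kind: str = "vft"
    shape: APShapeParams | WASPShapeParams = None  # type: ignore[assignment]
    noise: NoiseModel = field(default_factory=NoiseModel)
    protocol: SessionProtocol = field(default_factory=SessionProtocol)
    devices: list = field(
        default_factory=lambda: [
            DeviceSpec("oect"),
            DeviceSpec("electrode_agagcl"),
            DeviceSpec("electrode_pedotpss"),
        ]
    )
    cages: list = field(default_factory=lambda: [False, True])
    target_fs: float = TARGET_FS
    hp_fc: float = HIGHPASS_FC
    hp_order: int = HIGHPASS_ORDER
    smooth_s: float | None = None
    seed: int = 0
    save_traces: bool = False

    def __post_init__(self):
        if self.kind not in ("vft", "wasp"):
            raise InvalidArgumentError("kind must be 'vft' or 'wasp'")
        if self.shape is None:
            self.shape = APShapeParams() if self.kind == "vft" else WASPShapeParams()
        if self.smooth_s is None:
            self.smooth_s = SMOOTH_WINDOW_S[self.kind]
        if self.protocol.n_trials < 1:
            raise InvalidArgumentError("n_trials must be at least 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = _plain(dataclasses.asdict(self))
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kind = raw.get("kind", "vft")
        shape_cls = APShapeParams if kind == "vft" else WASPShapeParams
        kw = dict(kind=kind)
        if "shape" in raw:
            kw["shape"] = shape_cls(**raw["shape"])
        if "noise" in raw:
            kw["noise"] = NoiseModel(**raw["noise"])
        if "protocol" in raw:
            kw["protocol"] = SessionProtocol(**raw["protocol"])
        if "devices" in raw:
            devices = []
            for d in raw["devices"]:
                d = dict(d)
                name = d.pop("name")
                spec = DeviceSpec(
                    name,
                    electrode=ElectrodeParams(**d["electrode"]) if d.get("electrode") else None,
                    oect=OECTParams(**d["oect"]) if d.get("oect") else None,
                    gate=GateConfig(**d["gate"]) if d.get("gate") else None,
                )
                devices.append(spec)
            kw["devices"] = devices
        for key in ("cages", "target_fs", "hp_fc", "hp_order", "smooth_s", "seed", "save_traces"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


# ---------------------------------------------------------------------------
# the standard analysis chain


def preprocess_trace(trace: Trace, kind: str, config: ExperimentConfig | None = None) -> Trace:
    """Fixed-order preprocessing for one recorded trace.

    VFT: downsample -> Bessel highpass -> Gaussian smooth (200 ms).
    WASP: downsample -> Gaussian smooth (500 ms); no highpass, which would
    distort the tens-of-seconds tail.
    """
    target_fs = config.target_fs if config else TARGET_FS
    smooth_s = (config.smooth_s if config else None) or SMOOTH_WINDOW_S[kind]
    out = downsample(trace, target_fs)
    if kind == "vft":
        out = highpass_bessel(
            out,
            fc=config.hp_fc if config else HIGHPASS_FC,
            order=config.hp_order if config else HIGHPASS_ORDER,
        )
    return gaussian_smooth(out, smooth_s)


def trace_features(trace: Trace, kind: str, config: ExperimentConfig | None = None) -> dict:
    """Preprocess one recorded session trace and extract its statistics.

    Returns a flat feature row (the one-row-per-waveform table format that
    the statistics module consumes).  SNR is computed on the *raw* trace —
    decimation filtering would strip the very interference it quantifies.
    """
    s = snr_of_trace(trace)
    pre = preprocess_trace(trace, kind, config)
    stim_label = "stimulus" if kind == "vft" else "laser_on"
    t_stim = pre.event_time(stim_label)
    i_stim = pre.index_of(t_stim)
    i_guard = max(0, i_stim - int(round(BASELINE_GUARD_S * pre.fs)))
    baseline = pre.values[:i_guard]
    row = {
        "device": trace.device,
        "cage": bool(trace.meta.get("cage", False)),
        "plant": trace.meta.get("plant", ""),
        "trap": trace.meta.get("trap", ""),
        "kind": kind,
        "snr": s.snr,
        "peak_amplitude": s.peak_amplitude,
        "baseline_sd": s.baseline_sd,
    }
    if kind == "vft":
        f = ap_features(pre.values, pre.fs, baseline)
        row.update(
            min_amplitude=f.min_amplitude,
            peak_to_peak=f.peak_to_peak,
            max_down_slope=f.max_down_slope,
            max_up_slope=f.max_up_slope,
            half_width_s=f.half_width_s,
        )
    else:
        f = wasp_features(pre.values, pre.fs, pre.times - t_stim, baseline)
        row.update(
            latency_s=f.latency_s,
            duration_s=f.duration_s,
            amplitude=f.amplitude,
            recovered=f.recovered,
        )
    return row


def ground_truth_features(
    kind: str,
    shape,
    protocol: SessionProtocol,
    config: ExperimentConfig | None = None,
) -> dict:
    """Features of the noise-free template pushed through the same chain.

    This is the operational ground truth for parameter-recovery checks: the
    templates have no closed-form half-width or duration, so the reference
    is the identical measurement applied to the clean waveform.
    """
    clean = noise_free_template(
        kind, shape, protocol.fs_acquire, protocol.duration_s, onset_s=protocol.baseline_s
    )
    if kind == "wasp":
        clean.events = [
            ("laser_on", protocol.baseline_s),
            ("laser_off", protocol.baseline_s + protocol.laser_s),
        ]
    pre = preprocess_trace(clean, kind, config)
    stim_label = "stimulus" if kind == "vft" else "laser_on"
    t_stim = pre.event_time(stim_label)
    i_guard = max(0, pre.index_of(t_stim) - int(round(BASELINE_GUARD_S * pre.fs)))
    baseline = pre.values[:i_guard]
    if kind == "vft":
        f = ap_features(pre.values, pre.fs, baseline)
        return {
            "min_amplitude": f.min_amplitude,
            "peak_to_peak": f.peak_to_peak,
            "half_width_s": f.half_width_s,
        }
    f = wasp_features(pre.values, pre.fs, pre.times - t_stim, baseline)
    return {
        "amplitude": f.amplitude,
        "latency_s": f.latency_s,
        "duration_s": f.duration_s,
    }


# ---------------------------------------------------------------------------
# orchestration


def _record(surface: Trace, spec: DeviceSpec, noise: NoiseModel, seed) -> Trace:
    if spec.name == "oect":
        return record_with_oect(surface, spec.oect, spec.gate, noise, seed)
    return record_with_electrode(surface, spec.electrode, noise, seed)


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run the full benchmark and write its report bundle.

    For every device x cage condition, ``n_trials`` clean surface-potential
    trials are simulated and recorded through the device model under that
    cage's noise; the feature/SNR table, statistical comparison, and a run
    manifest (all parameters, seed, package version) are written to
    ``outdir``.  Deterministic given the master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    silent = NoiseModel(baseline_sd=0, drift_amp=0, mains_amp_50hz=0, laser_amp_40hz=0)

    rows = []
    for ci, (spec, cage) in enumerate(
        (s, c) for s in config.devices for c in config.cages
    ):
        cond_noise = dataclasses.replace(config.noise, cage=cage)
        cond_seed = int(child_rng(config.seed, ci).integers(2**31))
        protocol = dataclasses.replace(config.protocol, seed=cond_seed)
        surfaces = generate_session(config.kind, config.shape, silent, protocol)
        for trial, surface in enumerate(surfaces):
            rec = _record(surface, spec, cond_noise, child_rng(cond_seed, trial, 2))
            rec.meta["cage"] = cage
            if config.save_traces:
                tdir = outdir / "traces"
                tdir.mkdir(exist_ok=True)
                write_trace(rec, tdir / f"{spec.name}_cage{int(cage)}_trial{trial:02d}.csv")
            row = trace_features(rec, config.kind, config)
            row["trial"] = trial
            rows.append(row)

    features = pd.DataFrame(rows)
    features.to_csv(outdir / "features.csv", index=False, float_format="%.12g")

    stats = {}
    report_lines = [f"phytoephys benchmark report (kind={config.kind}, seed={config.seed})", ""]
    if len(config.devices) >= 2 and len(config.cages) >= 2 and config.protocol.n_trials >= 2:
        metrics = ["snr"] + (
            ["half_width_s"] if config.kind == "vft" else ["latency_s", "duration_s"]
        )
        for metric in metrics:
            cmp_res = two_way_anova_tukey(
                features.rename(columns={metric: "value"})[["value", "device", "cage"]]
            )
            stats[metric] = {
                "p_device": cmp_res.p_value("device"),
                "p_cage": cmp_res.p_value("cage"),
                "p_interaction": cmp_res.p_value("interaction"),
                "significant_within_cage": cmp_res.within_cage,
                "significant_within_device": cmp_res.within_device,
            }
            report_lines.append(f"== two-way ANOVA on {metric} (device x cage) ==")
            report_lines.append(str(cmp_res.anova))
            report_lines.append("Tukey pairs (within-cage device contrasts): "
                                f"{cmp_res.within_cage}")
            report_lines.append("Tukey pairs (within-device cage contrasts): "
                                f"{cmp_res.within_device}")
            report_lines.append("")
    med = features.groupby(["device", "cage"])["snr"].median()
    report_lines.append("== median SNR per condition ==")
    report_lines.append(med.to_string())
    (outdir / "stats_report.txt").write_text("\n".join(report_lines) + "\n")
    with open(outdir / "stats.json", "w") as fh:
        json.dump(_plain(stats), fh, indent=2)

    manifest = {
        "package": "phytoephys",
        "version": __version__,
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {"features": features, "stats": stats, "outdir": outdir}
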
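"""Recording-device models: passive surface electrodes and OECTs.

The organic electrochemical transistor (OECT) is modeled as a depletion-mode
device: the PEDOT:PSS channel is conducting at zero gate bias and is dedoped
(|I_D| falls) as the gate-source voltage increases.  The steady-state
transfer curve is a smooth monotone saturating function

    I_D(V_GS) = -i_d_max * logistic((v_th - V_GS) / slope_V)

(negative drain current under V_DS = -0.4 V bias).  Its derivative dI_D/dV_GS
is the transconductance g_m, the voltage-to-current amplification factor; in
the small-signal regime the recorded current deflection is
``g_m(bias) * coupling * delta_v``.

Noise pathways are phenomenological: ambient interference (drift, mains,
laser artifact) reaches the electrode output at unity susceptibility, but
reaches the OECT output referred through g_m and scaled by a much smaller
susceptibility, on top of a cage-independent intrinsic current-noise floor.
This reproduces the empirical benchmark result — the OECT holds a far higher
SNR outside a Faraday cage, and the gap narrows inside one — without
modeling the underlying output-impedance physics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError
from .synthetic_signals import NoiseModel, ambient_interference
from .trace import Trace

__all__ = [
    "OECTParams",
    "TransferCurve",
    "GateConfig",
    "ElectrodeParams",
    "drain_current",
    "transconductance",
    "transfer_curve",
    "record_with_oect",
    "record_with_electrode",
]


@dataclass
class OECTParams:
    """Steady-state OECT description and operating point.

    ``i_d_max_A`` is the on-state drain-current magnitude, ``v_th_V`` the
    pinch-off parameter (the transfer curve's inflection, where g_m peaks),
    ``slope_V`` the transition width.  ``v_ds_V``/``v_gs_bias_V`` are the
    biases used in the benchmark (-0.4 V and +0.3 V).
    ``noise_susceptibility`` scales ambient interference reaching the
    output; ``i_noise_sd_A`` is the intrinsic current-noise floor.
    """

    i_d_max_A: float = 1e-3
    v_th_V: float = 0.3
    slope_V: float = 0.15
    v_ds_V: float = -0.4
    v_gs_bias_V: float = 0.3
    noise_susceptibility: float = 0.005
    i_noise_sd_A: float = 4.6e-8

    def __post_init__(self):
        if self.i_d_max_A <= 0:
            raise InvalidArgumentError("i_d_max_A must be positive")
        if self.slope_V <= 0:
            raise InvalidArgumentError("slope_V must be positive")
        if not (0 <= self.noise_susceptibility <= 1):
            raise InvalidArgumentError("noise_susceptibility must be in [0, 1]")
        if self.i_noise_sd_A < 0:
            raise InvalidArgumentError("i_noise_sd_A must be non-negative")


@dataclass
class TransferCurve:
    """Sampled transfer curve I_D(V_GS) with its transconductance.

    ``g_m`` is the numerical derivative dI_D/dV_GS on the grid (central
    differences); ``g_m_max`` / ``v_gs_at_g_m_max`` locate the maximum of
    |g_m|, the figure of merit quoted for gate-configuration comparisons.
    """

    v_gs_grid: np.ndarray
    i_d: np.ndarray
    g_m: np.ndarray
    g_m_max: float
    v_gs_at_g_m_max: float

    def as_array(self) -> np.ndarray:
        """(n, 3) array of (v_gs, i_d, g_m) rows for delimited-text export."""
        return np.column_stack([self.v_gs_grid, self.i_d, self.g_m])


@dataclass
class GateConfig:
    """Gate-electrode placement and its coupling to the plant signal.

    ``coupling`` is the fraction of the plant surface potential appearing as
    effective gate-source modulation: 1.0 for a Ag/AgCl gate in soil
    (slightly the best modulation), 0.9 on non-active plant tissue, and 0.0
    for a co-planar gate — with the gate on the same device substrate the
    plant is not part of the transistor circuit and no plant signal is
    recorded.
    """

    mode: str = "soil"
    coupling: float = field(default=None)  # type: ignore[assignment]

    _DEFAULT_COUPLING = {"coplanar": 0.0, "plant_surface": 0.9, "soil": 1.0}

    def __post_init__(self):
        if self.mode not in self._DEFAULT_COUPLING:
            raise InvalidArgumentError(
                f"mode must be one of {sorted(self._DEFAULT_COUPLING)}"
            )
        if self.coupling is None:
            self.coupling = self._DEFAULT_COUPLING[self.mode]
        if self.mode == "coplanar":
            if self.coupling != 0.0:
                raise InvalidArgumentError("coplanar gate must have coupling 0")
        elif not (0 < self.coupling <= 1):
            raise InvalidArgumentError("coupling must be in (0, 1] for this mode")


@dataclass
class ElectrodeParams:
    """Passive surface electrode: a unity-gain voltage probe.

    ``noise_susceptibility`` multiplies ambient interference at the output;
    the default (1.0) is deliberately much larger than the OECT's.
    """

    gain: float = 1.0
    noise_susceptibility: float = 1.0
    name: str = "electrode_agagcl"

    def __post_init__(self):
        if self.gain <= 0:
            raise InvalidArgumentError("gain must be positive")
        if self.noise_susceptibility < 0:
            raise InvalidArgumentError("noise_susceptibility must be non-negative")
        if self.name not in ("electrode_agagcl", "electrode_pedotpss"):
            raise InvalidArgumentError("name must be an electrode device")


# ---------------------------------------------------------------------------
# steady-state curves


def drain_current(params: OECTParams, v_gs) -> np.ndarray:
    """Drain current at gate voltage(s) ``v_gs`` (depletion-mode, I_D < 0)."""
    return -params.i_d_max_A * expit((params.v_th_V - np.asarray(v_gs, float)) / params.slope_V)


def transconductance(params: OECTParams, v_gs) -> np.ndarray:
    """Closed-form g_m = dI_D/dV_GS of the logistic transfer model."""
    x = (params.v_th_V - np.asarray(v_gs, float)) / params.slope_V
    s = expit(x)
    return params.i_d_max_A / params.slope_V * s * (1.0 - s)


def transfer_curve(
    params: OECTParams,
    v_gs_range: tuple[float, float] = (-0.2, 0.6),
    n_points: int = 81,
) -> TransferCurve:
    """Sweep the transfer curve and locate the transconductance maximum.

    g_m is computed by central differences on the grid (the measurement
    procedure applied to a real sweep), not from the closed form.
    """
    lo, hi = v_gs_range
    if not hi > lo:
        raise InvalidArgumentError("v_gs_range must be increasing")
    if n_points < 3:
        raise InvalidArgumentError("need at least 3 grid points")
    v = np.linspace(lo, hi, n_points)
    i_d = drain_current(params, v)
    g_m = np.gradient(i_d, v)
    k = int(np.argmax(np.abs(g_m)))
    return TransferCurve(
        v_gs_grid=v, i_d=i_d, g_m=g_m,
        g_m_max=float(g_m[k]), v_gs_at_g_m_max=float(v[k]),
    )


# ---------------------------------------------------------------------------
# recording pathways


def record_with_oect(
    surface: Trace,
    params: OECTParams,
    gate: GateConfig,
    noise: NoiseModel,
    seed=None,
) -> Trace:
    """Record a surface-potential trace as OECT drain current.

    The plant signal modulates the gate operating point through the gate
    coupling; the output is the full transfer curve evaluated at
    ``v_gs_bias + coupling * v(t)`` (small signals reduce to
    ``g_m(bias) * coupling * delta_v``), plus susceptibility-scaled ambient
    interference referred through g_m and the intrinsic current noise.
    """
    if surface.units != "V":
        raise InvalidArgumentError("OECT input must be a voltage trace")
    rng = np.random.default_rng(seed)
    v_gs = params.v_gs_bias_V + gate.coupling * surface.values
    out = drain_current(params, v_gs)
    gm_bias = float(transconductance(params, params.v_gs_bias_V))
    ambient = ambient_interference(surface, noise, rng)
    out = out + params.noise_susceptibility * gm_bias * ambient
    if params.i_noise_sd_A > 0:
        out = out + rng.normal(0.0, params.i_noise_sd_A, surface.n)
    rec = surface.replace(values=out, units="A", device="oect")
    rec.meta.update(gate_mode=gate.mode, coupling=gate.coupling, cage=noise.cage)
    rec.log_stage(
        "record_with_oect",
        v_ds_V=params.v_ds_V, v_gs_bias_V=params.v_gs_bias_V, gm_bias_S=gm_bias,
    )
    return rec


def record_with_electrode(
    surface: Trace,
    params: ElectrodeParams,
    noise: NoiseModel,
    seed=None,
) -> Trace:
    """Record a surface-potential trace with a passive electrode.

    Output (volts) is ``gain * v(t)`` plus susceptibility-scaled ambient
    interference and the Gaussian sensor-noise floor of the noise model.
    """
    if surface.units != "V":
        raise InvalidArgumentError("electrode input must be a voltage trace")
    rng = np.random.default_rng(seed)
    out = params.gain * surface.values
    out = out + params.noise_susceptibility * ambient_interference(surface, noise, rng)
    if noise.baseline_sd > 0:
        out = out + rng.normal(0.0, noise.baseline_sd, surface.n)
    rec = surface.replace(values=out, units="V", device=params.name)
    rec.meta.update(cage=noise.cage)
    rec.log_stage("record_with_electrode", gain=params.gain)
    return rec
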
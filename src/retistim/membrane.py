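"""Retinal ganglion cell excitability under an extracellular current drive.

Single-compartment membrane model with the five voltage-gated conductances
of the classic retinal ganglion cell parameterization — fast sodium,
calcium, delayed-rectifier potassium, A-type potassium, and
calcium-activated potassium — plus an ohmic leak, with intracellular
calcium handling and a Nernstian calcium reversal.  The membrane equation
is the standard current balance

    C_m dV/dt = −(I_Na + I_Ca + I_K + I_A + I_KCa + I_L) + J_c(t)

where J_c(t) is the surface-averaged extracellular boundary current
density delivered by the volume-conduction field, entering directly as an
areal current (A/m² → µA/cm²) with depolarizing sign for positive drive.
The model detects activation as a membrane excursion of at least +30 mV
above rest (the action-potential criterion), and finds threshold stimulus
amplitudes by incremental search, reusing the linearity of the field
problem across amplitudes.

Internal units are the conventional ones for this model family: mV, ms,
mS/cm², µA/cm², µF/cm², mM.  The public API takes drives in A/m² and
durations in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ChannelParams",
    "MembraneState",
    "MembraneTrace",
    "MembraneError",
    "load_default_params",
    "resting_state",
    "simulate",
    "detect_activation",
    "threshold_search",
    "threshold_density",
]

FARADAY = 96485.33212  # C/mol
GAS_R = 8.31446  # J/(mol K)
ACTIVATION_SHIFT_MV = 30.0  # inclusive threshold on max(V) - V_rest
BLOWUP_MV = 500.0

A_PER_M2_TO_UA_PER_CM2 = 100.0


class MembraneError(RuntimeError):
    """Membrane integration or threshold search failure."""


def _vtrap(x: np.ndarray | float, y: float):
    """x / (exp(x/y) − 1) with the removable singularity at x = 0 patched."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            np.abs(x / y) < 1e-6,
            y * (1.0 - x / (2.0 * y)),
            x / np.expm1(np.clip(x / y, -500, 500)),
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ChannelParams:
    """Maximal conductances, reversals, gating kinetics and Ca handling.

    Values live in a versioned JSON document (``data/membrane_fohlmeister.json``)
    so alternative printed parameter sets can be swapped without code change.
    """

    c_m: float  # µF/cm²
    g_na: float  # mS/cm²
    g_ca: float
    g_k: float
    g_a: float
    g_kca: float
    g_leak: float
    e_na: float  # mV
    e_k: float
    e_leak: float
    ca_external: float  # mM
    ca_resting: float  # mM
    ca_dissociation: float  # mM
    ca_tau: float  # ms
    shell_radius: float  # µm
    temperature: float  # K
    name: str = "fohlmeister-rgc-5conductance"

    def __post_init__(self) -> None:
        for g in (self.g_na, self.g_ca, self.g_k, self.g_a, self.g_kca, self.g_leak):
            if g < 0:
                raise ValueError("conductances must be >= 0")
        if self.c_m <= 0:
            raise ValueError("membrane capacitance must be > 0")

    # --- gating rate functions (ms⁻¹, V in mV) -------------------------
    def rates(self, v: float) -> dict[str, tuple[float, float]]:
        """(α, β) for each gate at membrane potential ``v``."""
        return {
            "m": (0.6 * _vtrap(-(v + 30.0), 10.0), 20.0 * math.exp(-(v + 55.0) / 18.0)),
            "h": (0.4 * math.exp(-(v + 50.0) / 20.0), 6.0 / (1.0 + math.exp(-0.1 * (v + 20.0)))),
            "c": (0.3 * _vtrap(-(v + 13.0), 10.0), 10.0 * math.exp(-(v + 38.0) / 18.0)),
            "n": (0.02 * _vtrap(-(v + 40.0), 10.0), 0.4 * math.exp(-(v + 50.0) / 80.0)),
            "a": (0.006 * _vtrap(-(v + 90.0), 10.0), 0.1 * math.exp(-(v + 30.0) / 10.0)),
            "ha": (0.04 * math.exp(-(v + 70.0) / 20.0), 0.6 / (1.0 + math.exp(-0.1 * (v + 40.0)))),
        }

    def steady_gates(self, v: float) -> dict[str, float]:
        return {k: a / (a + b) for k, (a, b) in self.rates(v).items()}

    def e_ca(self, ca_i: float) -> float:
        """Nernstian calcium reversal (mV) at intracellular [Ca] (mM)."""
        k = 1000.0 * GAS_R * self.temperature / (2.0 * FARADAY)
        return k * math.log(self.ca_external / max(ca_i, 1e-12))

    def ionic_current(self, v: float, gates: dict[str, float], ca_i: float) -> float:
        """Total ionic membrane current (µA/cm², outward positive)."""
        i_na = self.g_na * gates["m"] ** 3 * gates["h"] * (v - self.e_na)
        i_ca = self.g_ca * gates["c"] ** 3 * (v - self.e_ca(ca_i))
        i_k = self.g_k * gates["n"] ** 4 * (v - self.e_k)
        i_a = self.g_a * gates["a"] ** 3 * gates["ha"] * (v - self.e_k)
        x = (ca_i / self.ca_dissociation) ** 2
        i_kca = self.g_kca * x / (1.0 + x) * (v - self.e_k)
        i_l = self.g_leak * (v - self.e_leak)
        return i_na + i_ca + i_k + i_a + i_kca + i_l


_GATE_ORDER = ("m", "h", "c", "n", "a", "ha")


@dataclass(frozen=True)
class MembraneState:
    """Membrane potential (mV), gating variables, intracellular [Ca] (mM)."""

    v: float
    gates: tuple[float, ...]  # m, h, c, n, a, ha
    ca_i: float

    def __post_init__(self) -> None:
        if not all(-1e-9 <= g <= 1.0 + 1e-9 for g in self.gates):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.ca_i <= 0:
            raise ValueError("intracellular calcium must be > 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.v, *self.gates, self.ca_i])


@dataclass
class MembraneTrace:
    """Time course of the membrane under a given drive."""

    t: np.ndarray  # s
    v: np.ndarray  # mV
    drive: np.ndarray  # A/m²
    v_rest: float  # mV
    drive_end: float  # s, end of the stimulation pulse

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.v)):
            raise MembraneError("membrane trace contains non-finite voltages")

    @property
    def peak_v(self) -> float:
        return float(self.v.max())

    @property
    def peak_shift(self) -> float:
        return self.peak_v - self.v_rest

    @property
    def activated(self) -> bool:
        return self.peak_shift >= ACTIVATION_SHIFT_MV

    @property
    def spike_time(self) -> float | None:
        above = self.v - self.v_rest >= ACTIVATION_SHIFT_MV
        return float(self.t[above][0]) if above.any() else None


def load_default_params() -> ChannelParams:
    """Load the packaged membrane parameter document."""
    with resources.files("retistim.data").joinpath("membrane_fohlmeister.json").open() as f:
        doc = json.load(f)
    g = doc["conductances_mS_cm2"]
    e = doc["reversals_mV"]
    ca = doc["calcium"]
    return ChannelParams(
        c_m=doc["capacitance_uF_cm2"],
        g_na=g["g_na"], g_ca=g["g_ca"], g_k=g["g_k"], g_a=g["g_a"],
        g_kca=g["g_kca"], g_leak=g["g_leak"],
        e_na=e["e_na"], e_k=e["e_k"], e_leak=e["e_leak"],
        ca_external=ca["ca_external_mM"], ca_resting=ca["ca_resting_mM"],
        ca_dissociation=ca["ca_dissociation_mM"], ca_tau=ca["removal_tau_ms"],
        shell_radius=ca["shell_radius_um"], temperature=ca["temperature_K"],
        name=doc["name"],
    )


def _rhs(params: ChannelParams):
    """Autonomous-part RHS factory; drive supplied as a callable of t (ms).

    The gating kinetics are inlined (rather than routed through
    ``ChannelParams.rates``) to keep the integrator's per-step cost low;
    the two code paths are held consistent by the equilibrium tests.
    """
    kca = 3.0 / (2.0 * FARADAY * params.shell_radius * 1e-6) * 1e-5  # mM/ms per µA/cm²
    p = params
    e_ca_k = 1000.0 * GAS_R * p.temperature / (2.0 * FARADAY)
    exp, log = math.exp, math.log

    def vtrap(x: float, y: float) -> float:
        if abs(x / y) < 1e-6:
            return y * (1.0 - x / (2.0 * y))
        return x / (exp(min(max(x / y, -500.0), 500.0)) - 1.0)

    def rhs(t_ms: float, y: np.ndarray, drive_ua) -> np.ndarray:
        v = y[0]
        m = min(max(y[1], 0.0), 1.0)
        h = min(max(y[2], 0.0), 1.0)
        c = min(max(y[3], 0.0), 1.0)
        n = min(max(y[4], 0.0), 1.0)
        a = min(max(y[5], 0.0), 1.0)
        ha = min(max(y[6], 0.0), 1.0)
        ca_i = max(y[7], 1e-9)

        e_ca = e_ca_k * log(p.ca_external / ca_i)
        i_na = p.g_na * m * m * m * h * (v - p.e_na)
        i_ca = p.g_ca * c * c * c * (v - e_ca)
        i_k = p.g_k * n * n * n * n * (v - p.e_k)
        i_a = p.g_a * a * a * a * ha * (v - p.e_k)
        x = (ca_i / p.ca_dissociation) ** 2
        i_kca = p.g_kca * x / (1.0 + x) * (v - p.e_k)
        i_l = p.g_leak * (v - p.e_leak)
        dv = (-(i_na + i_ca + i_k + i_a + i_kca + i_l) + drive_ua(t_ms)) / p.c_m

        am = 0.6 * vtrap(-(v + 30.0), 10.0)
        bm = 20.0 * exp(-(v + 55.0) / 18.0)
        ah = 0.4 * exp(-(v + 50.0) / 20.0)
        bh = 6.0 / (1.0 + exp(-0.1 * (v + 20.0)))
        ac = 0.3 * vtrap(-(v + 13.0), 10.0)
        bc = 10.0 * exp(-(v + 38.0) / 18.0)
        an = 0.02 * vtrap(-(v + 40.0), 10.0)
        bn = 0.4 * exp(-(v + 50.0) / 80.0)
        aa = 0.006 * vtrap(-(v + 90.0), 10.0)
        ba = 0.1 * exp(-(v + 30.0) / 10.0)
        aha = 0.04 * exp(-(v + 70.0) / 20.0)
        bha = 0.6 / (1.0 + exp(-0.1 * (v + 40.0)))

        return np.array([
            dv,
            am * (1.0 - m) - bm * m,
            ah * (1.0 - h) - bh * h,
            ac * (1.0 - c) - bc * c,
            an * (1.0 - n) - bn * n,
            aa * (1.0 - a) - ba * a,
            aha * (1.0 - ha) - bha * ha,
            -kca * i_ca - (ca_i - p.ca_resting) / p.ca_tau,
        ])

    return rhs


def resting_state(
    params: ChannelParams, settle_ms: float = 500.0, tol: float = 1e-6
) -> MembraneState:
    """Zero-drive steady state of the membrane.

    Integrates the autonomous system to equilibrium and verifies that the
    residual dV/dt is below ``tol`` (mV/ms).
    """
    gates0 = params.steady_gates(params.e_leak)
    y0 = np.array([params.e_leak, *[gates0[k] for k in _GATE_ORDER], params.ca_resting])
    rhs = _rhs(params)
    sol = solve_ivp(
        rhs, (0.0, settle_ms), y0, args=(lambda t: 0.0,),
        method="LSODA", rtol=1e-8, atol=1e-9,
    )
    if not sol.success:
        raise MembraneError(f"resting-state integration failed: {sol.message}")
    yf = sol.y[:, -1]
    if abs(rhs(0.0, yf, lambda t: 0.0)[0]) > tol:
        raise MembraneError("no membrane equilibrium found within the integration horizon")
    return MembraneState(v=float(yf[0]), gates=tuple(np.clip(yf[1:7], 0, 1)), ca_i=float(yf[7]))


def simulate(
    params: ChannelParams,
    state0: MembraneState,
    drive,
    duration: float,
    dt: float = 5e-6,
    drive_end: float | None = None,
    v_rest: float | None = None,
) -> MembraneTrace:
    """Integrate the membrane under drive ``J_c(t)`` (A/m², t in seconds).

    ``drive`` may be a callable of time in seconds or a
    :class:`~retistim.fieldsolver.BoundaryDrive`.  The integrator is the
    stiff-capable LSODA scheme with a fixed output grid of spacing ``dt``;
    the run is deterministic for fixed inputs.  Raises on numerical blow-up
    (|V| > 500 mV).
    """
    if hasattr(drive, "series"):
        bd = drive
        if drive_end is None:
            drive_end = bd.waveform.duration
        drive_fn = bd.series
    else:
        drive_fn = drive
        if drive_end is None:
            raise ValueError("drive_end (pulse end, seconds) required for a bare callable")
    if drive_end > 0 and dt > drive_end / 20.0 + 1e-15:
        raise ValueError("dt must resolve the waveform: dt <= phase_width / 20")

    def drive_ua(t_ms: float) -> float:
        return float(drive_fn(t_ms * 1e-3)) * A_PER_M2_TO_UA_PER_CM2

    rhs = _rhs(params)
    y0 = state0.as_vector()
    t_end_ms = duration * 1e3
    pulse_ms = min(drive_end * 1e3, t_end_ms)
    dt_ms = dt * 1e3

    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    segments = [(0.0, pulse_ms, dt_ms)]
    if t_end_ms > pulse_ms:
        segments.append((pulse_ms, t_end_ms, min(0.025, max(dt_ms, 0.001))))
    y = y0
    for t0, t1, step in segments:
        tt = np.arange(t0, t1, step)
        if tt.size == 0 or tt[-1] < t1:
            tt = np.append(tt, t1)
        sol = solve_ivp(
            rhs, (t0, t1), y, args=(drive_ua,), method="LSODA",
            t_eval=tt, rtol=1e-8, atol=1e-6, max_step=max(step, dt_ms),
        )
        if not sol.success:
            raise MembraneError(f"membrane integration failed: {sol.message}")
        if np.abs(sol.y[0]).max() > BLOWUP_MV:
            raise MembraneError("numerical blow-up: |V_m| exceeded 500 mV")
        skip = 1 if t_out else 0
        t_out.append(sol.t[skip:])
        y_out.append(sol.y[:, skip:])
        y = sol.y[:, -1]

    t_ms = np.concatenate(t_out)
    v = np.concatenate([yy[0] for yy in y_out])
    t_s = t_ms * 1e-3
    if v_rest is None:
        v_rest = state0.v
    return MembraneTrace(
        t=t_s,
        v=v,
        drive=np.asarray(drive_fn(t_s), dtype=float),
        v_rest=v_rest,
        drive_end=drive_end,
    )


def detect_activation(trace: MembraneTrace) -> bool:
    """True iff the membrane shifted ≥ +30 mV above rest (inclusive).

    Requires at least 10 ms of trace beyond the stimulation pulse so a
    late-developing action potential is not missed.
    """
    post = trace.t[-1] - trace.drive_end
    if post < 10e-3 - 1e-9:
        raise MembraneError(
            f"trace too short: {post * 1e3:.2f} ms after the pulse, need >= 10 ms"
        )
    return trace.peak_shift >= ACTIVATION_SHIFT_MV


def _activates(params, rest, jc_unit, wf, amplitude, duration, dt) -> bool:
    from .fieldsolver import BoundaryDrive

    bd = BoundaryDrive(jc_unit=jc_unit, waveform=wf.with_amplitude(amplitude))
    try:
        trace = simulate(params, rest, bd, duration=duration, dt=dt, v_rest=rest.v)
    except MembraneError:
        # a drive strong enough to push |V| past the blow-up guard is far
        # beyond threshold; count it as activated so bracketing can proceed
        return True
    return detect_activation(trace)


def threshold_search(
    params: ChannelParams,
    jc_unit: float,
    wf_template,
    i_start: float,
    di: float,
    i_cap: float | None = None,
    duration: float = 12e-3,
    dt: float = 2e-6,
    rest: MembraneState | None = None,
) -> float:
    """Smallest tested amplitude ``i_start + k*di`` that elicits activation.

    ``jc_unit`` is the unit-field coupling (A/m² of boundary current density
    per injected ampere); the linearity of the field problem lets the unit
    solution be reused across amplitudes.  Raises ``MembraneError`` when the
    cap is reached without activation.
    """
    if di <= 0:
        raise ValueError("amplitude step must be > 0")
    if i_cap is None:
        i_cap = i_start + 200 * di
    if rest is None:
        rest = resting_state(params)
    amp = i_start
    while amp <= i_cap * (1 + 1e-12):
        if _activates(params, rest, jc_unit, wf_template, amp, duration, dt):
            return amp
        amp += di
    raise MembraneError(f"no activation up to the amplitude cap {i_cap:g} A")


def threshold_density(
    params: ChannelParams,
    wf_template,
    tol: float = 0.01,
    j_lo: float = 0.05,
    j_hi: float = 200.0,
    duration: float = 12e-3,
    dt: float = 2e-6,
    rest: MembraneState | None = None,
) -> float:
    """Bisection-refined peak boundary current density (A/m²) at threshold.

    The membrane-side activation threshold for the given pulse shape,
    independent of any particular electrode geometry: the smallest peak
    J_c for which the +30 mV criterion is met, to relative tolerance
    ``tol``.
    """
    if rest is None:
        rest = resting_state(params)
    if _activates(params, rest, 1.0, wf_template, j_lo, duration, dt):
        return j_lo
    if not _activates(params, rest, 1.0, wf_template, j_hi, duration, dt):
        raise MembraneError(f"no activation at J_c = {j_hi} A/m²")
    lo, hi = j_lo, j_hi
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        if _activates(params, rest, 1.0, wf_template, mid, duration, dt):
            hi = mid
        else:
            lo = mid
    return hi
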
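"""Electrochemical safety calculus for stimulation electrodes.

Charge per phase divided by the flat disc cross-section area of the
electrode, compared against published charge-injection limits per
electrode material (bulk platinum 0.1–0.35 mC/cm², platinum gray
1.0 mC/cm², titanium nitride 0.9 mC/cm²).  The conservative default limit
is the lower platinum bound, which is also applied to coated materials
whose effective limit is not established here.  Heating is reported as an
ohmic dissipated-power estimate P(t) = i(t)²·R_access from the unit-field
access resistance — a deliberately simple Joule figure, with no tissue
temperature model attached.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .fieldsolver import FieldSolution
from .waveforms import StimWaveform, charge_per_phase

__all__ = [
    "CHARGE_LIMITS_MC_CM2",
    "SafetyReport",
    "charge_density",
    "check_safety",
    "dissipated_power",
    "safety_report",
]

# charge-injection limits, mC/cm² per phase
CHARGE_LIMITS_MC_CM2: dict[str, float] = {
    "platinum": 0.1,  # conservative lower bound of the 0.1–0.35 range
    "platinum-upper": 0.35,
    "platinum-gray": 1.0,
    "titanium-nitride": 0.9,
    "PEDOT-coated": 0.1,  # effective limit not established; conservative default
    "default": 0.1,
}


def charge_density(wf: StimWaveform, electrode_diameter: float) -> float:
    """Charge per phase over the disc cross-section, in mC/cm².

    ``electrode_diameter`` in µm.  The geometric (flat) disc area is used,
    not a coated effective surface area.
    """
    if electrode_diameter <= 0:
        raise ValueError("electrode diameter must be > 0")
    q_c = charge_per_phase(wf)  # C
    d_cm = electrode_diameter * 1e-4
    area_cm2 = 3.141592653589793 * d_cm * d_cm / 4.0
    return (q_c * 1e3) / area_cm2  # mC/cm²


def check_safety(cd_mc_cm2: float, material: str) -> str:
    """``"safe"`` iff the charge density does not exceed the material limit.

    The comparison is inclusive at the limit.  Unknown materials raise.
    """
    if material not in CHARGE_LIMITS_MC_CM2:
        raise KeyError(
            f"unknown electrode material {material!r}; known: "
            f"{sorted(CHARGE_LIMITS_MC_CM2)}"
        )
    return "safe" if cd_mc_cm2 <= CHARGE_LIMITS_MC_CM2[material] else "unsafe"


def dissipated_power(sol: FieldSolution, wf: StimWaveform) -> tuple[float, float]:
    """(peak, pulse-averaged) ohmic power in watts.

    P(t) = i(t)² · R_access with the access resistance taken from the
    unit-current field solution (active-electrode potential per ampere,
    ground at 0 V); by energy balance this equals the volume integral of
    σ|∇V|² to solver tolerance.
    """
    r = sol.access_resistance
    p_peak = wf.peak_amplitude ** 2 * r
    if wf.duration == 0 or wf.peak_amplitude == 0:
        return 0.0, 0.0
    # mean of i(t)² over the active pulse, in closed form per shape
    if wf.shape == "biphasic-rectangular":
        frac = 2.0 * wf.phase_width / wf.duration  # gap carries no current
        mean_i2 = wf.peak_amplitude ** 2 * frac
    else:  # linear decrease: mean of (1 - t/w)² = 1/3
        mean_i2 = wf.peak_amplitude ** 2 / 3.0
    return p_peak, mean_i2 * r


@dataclass(frozen=True)
class SafetyReport:
    """Electrochemical verdict for one electrode/waveform combination."""

    charge_per_phase_c: float
    electrode_area_cm2: float
    charge_density_mc_cm2: float
    material: str
    limit_mc_cm2: float
    verdict: str
    dissipated_power_peak_w: float | None = None
    dissipated_power_avg_w: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def safety_report(
    wf: StimWaveform,
    electrode_diameter: float,
    material: str = "platinum",
    sol: FieldSolution | None = None,
) -> SafetyReport:
    """Full safety report; includes dissipated power when a field solution is given."""
    cd = charge_density(wf, electrode_diameter)
    d_cm = electrode_diameter * 1e-4
    p_peak = p_avg = None
    if sol is not None:
        p_peak, p_avg = dissipated_power(sol, wf)
    return SafetyReport(
        charge_per_phase_c=charge_per_phase(wf),
        electrode_area_cm2=3.141592653589793 * d_cm * d_cm / 4.0,
        charge_density_mc_cm2=cd,
        material=material,
        limit_mc_cm2=CHARGE_LIMITS_MC_CM2[material],
        verdict=check_safety(cd, material),
        dissipated_power_peak_w=p_peak,
        dissipated_power_avg_w=p_avg,
    )
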
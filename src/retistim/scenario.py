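"""Scenario configuration, reproducible runs, and result serialization.

A scenario is a JSON (or YAML) document validated against a pydantic
schema; :func:`run_scenario` executes it deterministically and writes a
result bundle — field summary, membrane traces, percept GeoJSON or
selectivity criterion, and a safety report — each stamped with the
configuration hash so a bundle is reproducible from its embedded config
alone.  :func:`render_report` turns a bundle into a one-page summary
without recomputation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import __version__, fixtures, membrane, phosphene, safety
from .fieldsolver import surface_current_density

__all__ = [
    "Scenario",
    "HexSettings",
    "LceSettings",
    "ScenarioError",
    "load_scenario",
    "run_scenario",
    "render_report",
]


class ScenarioError(ValueError):
    """Invalid scenario configuration."""


class SearchSettings(BaseModel):
    rays: int = 16
    coarse_step_um: float = 5.0
    tol_um: float = 0.5
    current_factor: float = 2.0
    current_cap: float = 4.0
    max_radius_um: float = 1500.0

    def to_config(self) -> phosphene.SearchConfig:
        return phosphene.SearchConfig(
            rays=self.rays, coarse_step=self.coarse_step_um, tol=self.tol_um,
            current_factor=self.current_factor, current_cap=self.current_cap,
            max_radius=self.max_radius_um,
        )


class SolverSettings(BaseModel):
    tol: float = 1e-8
    maxiter: int = 20000


class HexSettings(BaseModel):
    preset: str | None = None  # subject id: 1 | 2 | 3 | 6
    pairs: list[tuple[int, int]] | None = None
    proximity_um: float = 10.0
    theta_deg: float = 0.0
    amplitude_uA: float = 13.0
    phase_width_us: float = 94.0
    frequency_hz: float = 100.0
    reduced_conductivity: bool = False
    grid_um: float = 10.0
    margin_um: float = 1000.0


class LceSettings(BaseModel):
    rho_v_peak_per_um3: float = 8.05e-4
    electrode_diameter_um: float = 7.5
    pulse_width_us: float = 100.0
    cell_diameter_um: float = 10.0
    i_start_nA: float = 0.1
    i_step_nA: float = 0.1
    i_cap_nA: float = 20.0
    grid_um: float | None = None  # default: λ/10


class Scenario(BaseModel):
    """Validated top-level scenario document."""

    schema_version: int = 1
    kind: Literal["lce", "hex"]
    material: str = "platinum"
    hex: HexSettings = Field(default_factory=HexSettings)
    lce: LceSettings = Field(default_factory=LceSettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    search: SearchSettings = Field(default_factory=SearchSettings)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario config (JSON; YAML when available)."""
    text = Path(path).read_text()
    try:
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return Scenario.model_validate(doc)
    except (json.JSONDecodeError, ValidationError) as exc:
        raise ScenarioError(str(exc)) from exc


def _stamp(cfg: Scenario) -> dict:
    return {
        "config_hash": cfg.config_hash,
        "retistim_version": __version__,
        "solver_tol": cfg.solver.tol,
        "config": cfg.model_dump(),
    }


def _run_lce(cfg: Scenario, out: Path) -> dict:
    s = cfg.lce
    scene = fixtures.make_lce_scene(
        rho_v_peak=s.rho_v_peak_per_um3,
        electrode_diameter=s.electrode_diameter_um,
        pulse_width=s.pulse_width_us * 1e-6,
        cell_diameter=s.cell_diameter_um,
        h=s.grid_um,
    )
    sol = scene.solve(tol=cfg.solver.tol)
    jc_unit = surface_current_density(sol, scene.cell)
    params = membrane.load_default_params()
    rest = membrane.resting_state(params)
    thr = membrane.threshold_search(
        params, jc_unit, scene.waveform,
        i_start=s.i_start_nA * 1e-9, di=s.i_step_nA * 1e-9,
        i_cap=s.i_cap_nA * 1e-9, rest=rest,
    )
    wf = scene.waveform.with_amplitude(thr)
    from . import carrier3d

    crit = carrier3d.evaluate_selectivity(sol, thr, jc_unit * thr, scene.cube,
                                          cell_activated=True)
    report = safety.safety_report(wf, s.electrode_diameter_um, cfg.material, sol)

    from .fieldsolver import BoundaryDrive

    drive = BoundaryDrive(jc_unit=jc_unit, waveform=wf)
    trace = membrane.simulate(params, rest, drive, duration=wf.duration + 11e-3,
                              dt=2e-6, v_rest=rest.v)
    trace_csv = out / "membrane_trace.csv"
    np.savetxt(
        trace_csv,
        np.column_stack([trace.t, trace.v, trace.drive]),
        delimiter=",", header="t_s,V_m_mV,J_c_A_per_m2", comments="",
    )
    bundle = {
        **_stamp(cfg),
        "kind": "lce",
        "threshold_A": thr,
        "threshold_nA": thr * 1e9,
        "jc_unit_A_per_m2_per_A": jc_unit,
        "jc_peak_at_threshold_A_per_m2": jc_unit * thr,
        "cube_criterion": crit.as_dict(),
        "safety": report.as_dict(),
        "field": {
            "grid_shape": list(sol.grid.shape),
            "h_um": sol.grid.h,
            "residual": sol.residual,
            "access_resistance_ohm": sol.access_resistance,
        },
        "artifacts": {"membrane_trace": trace_csv.name},
        "membrane": {"peak_shift_mV": trace.peak_shift, "activated": trace.activated},
    }
    return bundle


def _run_hex(cfg: Scenario, out: Path) -> dict:
    s = cfg.hex
    scene = fixtures.make_hex_scene(
        preset=s.preset, pairs=s.pairs,
        proximity=s.proximity_um, theta=s.theta_deg,
        amplitude=s.amplitude_uA * 1e-6, phase_width=s.phase_width_us * 1e-6,
        frequency=s.frequency_hz, reduced_conductivity=s.reduced_conductivity,
        h=s.grid_um, margin=s.margin_um,
    )
    params = membrane.load_default_params()
    percept = phosphene.compose_percept(scene, params=params, cfg=cfg.search.to_config())
    gj = phosphene.percept_to_geojson(percept, properties={"config_hash": cfg.config_hash})
    (out / "percept.geojson").write_text(json.dumps(gj, indent=1))
    wf = scene.waveform
    report = safety.safety_report(wf, scene.array.electrode(0).diameter, cfg.material)
    bundle = {
        **_stamp(cfg),
        "kind": "hex",
        "pairs": [list(p) for p in scene.pairs],
        "percept": {
            "union_area_um2": percept.union_area,
            "shape_class": percept.shape_class,
            "cell_count": percept.cell_count,
            "components": percept.component_count,
        },
        "safety": report.as_dict(),
        "artifacts": {"percept_geojson": "percept.geojson"},
    }
    return bundle


def run_scenario(config: Scenario | str | Path, output_dir: str | Path) -> dict:
    """Execute a scenario and write its result bundle under ``output_dir``.

    Deterministic: the same configuration produces byte-identical numeric
    outputs.  Returns the bundle dict (also written as ``run.json``).
    """
    cfg = config if isinstance(config, Scenario) else load_scenario(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = _run_lce(cfg, out) if cfg.kind == "lce" else _run_hex(cfg, out)
    (out / "run.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle


def render_report(bundle: dict) -> str:
    """One-page human-readable summary of a result bundle (no recomputation)."""
    missing = [k for k in ("kind", "config_hash", "safety") if k not in bundle]
    if missing:
        raise ScenarioError(f"incomplete bundle, missing: {missing}")
    lines = [
        "# retistim run summary",
        f"- kind: {bundle['kind']}",
        f"- config hash: {bundle['config_hash'][:16]}…",
        f"- version: {bundle.get('retistim_version', '?')}",
    ]
    if bundle["kind"] == "lce":
        for k in ("threshold_nA", "jc_peak_at_threshold_A_per_m2"):
            if k not in bundle:
                raise ScenarioError(f"incomplete bundle, missing: {k}")
        lines += [
            f"- threshold peak amplitude: {bundle['threshold_nA']:.3g} nA",
            f"- peak boundary current density at threshold: "
            f"{bundle['jc_peak_at_threshold_A_per_m2']:.3g} A/m²",
        ]
        cc = bundle["cube_criterion"]
        lines += [
            f"- cube volume {cc['cube_volume_um3']:.4g} µm³ (λ = {cc['cube_length_um']:.4g} µm), "
            f"suprathreshold volume {cc['suprathreshold_volume_um3']:.4g} µm³",
            f"- selectivity verdict: **{cc['verdict']}**",
        ]
    else:
        p = bundle.get("percept")
        if p is None:
            raise ScenarioError("incomplete bundle, missing: percept")
        if p["union_area_um2"] == 0:
            lines.append("- percept: no stimulation")
        else:
            lines += [
                f"- percept area: {p['union_area_um2']:.4g} µm² "
                f"({p['components']} component(s), class {p['shape_class']})",
                f"- estimated activated cells: {p['cell_count']}",
            ]
    sf = bundle["safety"]
    lines += [
        f"- charge density: {sf['charge_density_mc_cm2']:.3g} mC/cm² "
        f"(limit {sf['limit_mc_cm2']:.3g}, {sf['material']}): **{sf['verdict']}**",
    ]
    return "\n".join(lines) + "\n"
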
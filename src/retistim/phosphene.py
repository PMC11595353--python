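"""Percept footprint mapping: the cell-shifting boundary-search algorithm.

The percept evoked by one electrode pair is the *stimulus criterion*: the
region of the retina where a model cell, shifted laterally through the
ganglion layer, is activated by the stimulus.  The search starts with the
cell concentric to the active electrode and marches outward along radial
rays in the retinal plane, bisecting each activation transition to a
sub-micrometre tolerance:

* centre activated → march to the outer boundary (a filled percept);
* centre silent but an annulus activated → record the inner boundary then
  the outer one (a ring percept);
* nothing activated within the search radius → no stimulation; the caller
  may raise the injected current (by the configured factor, up to a cap)
  and retry.

Because the field problem is linear, one unit-current field solve per
electrode pair serves every cell position and stimulus amplitude: a cell
position is activated iff its surface-averaged boundary current density at
the stimulus peak reaches the membrane activation threshold for the pulse
shape (amplitude monotonicity of activation is property-tested against the
full membrane integration).  Percepts from several pairs, delivered
separately in time, combine as a geometric union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from . import membrane
from .fieldsolver import BoundaryDrive, FieldSolution, surface_current_density
from .geometry import CellPlacement, GeometryError, LayerStack
from .membrane import ChannelParams
from .waveforms import StimWaveform

__all__ = [
    "SearchConfig",
    "PerceptBoundary",
    "Percept",
    "is_activated",
    "trace_boundary",
    "trace_pair_boundary",
    "compose_percept",
    "estimate_cell_count",
    "mirror_asymmetry",
    "percept_to_geojson",
]


@dataclass(frozen=True)
class SearchConfig:
    """Boundary-search resolution and current-escalation policy."""

    rays: int = 16
    coarse_step: float = 5.0  # µm
    tol: float = 0.5  # µm bisection tolerance
    current_factor: float = 2.0  # escalation factor when nothing activates
    current_cap: float = 4.0  # max amplitude multiple of the base stimulus
    max_radius: float = 1500.0  # µm

    def __post_init__(self) -> None:
        if self.rays < 8:
            raise ValueError("need at least 8 rays")
        if self.coarse_step <= 0 or self.tol <= 0:
            raise ValueError("steps must be > 0")
        if self.tol > self.coarse_step:
            raise ValueError("bisection tolerance must not exceed the coarse step")


@dataclass
class PerceptBoundary:
    """Closed activation outline(s) for one electrode pair."""

    outer: np.ndarray  # (n, 2) ordered vertices, µm
    inner: np.ndarray | None = None  # ring percepts
    pair: tuple[int, int] | None = None
    stimulus: str = ""
    clipped: bool = False  # outer boundary hit the search radius

    def __post_init__(self) -> None:
        poly = self.polygon
        if not poly.is_valid or poly.is_empty:
            raise GeometryError(
                f"activation boundary is not a simple polygon (pair {self.pair}): "
                f"{shapely.validation.explain_validity(poly)}"
            )
        if self.inner is not None and not Polygon(self.outer).contains(Polygon(self.inner)):
            raise GeometryError("inner boundary is not strictly inside the outer one")

    @property
    def polygon(self) -> Polygon:
        if self.inner is not None:
            return Polygon(self.outer, [self.inner[::-1]])
        return Polygon(self.outer)

    @property
    def area(self) -> float:
        """Enclosed (outer minus hole) area, µm²."""
        return self.polygon.area


@dataclass
class Percept:
    """Union of per-pair activation regions: the total evoked phosphene."""

    boundaries: list[PerceptBoundary]
    geometry: shapely.Geometry
    union_area: float  # µm²
    shape_class: str  # dot | ring | elongated | composite
    cell_count: int | None = None

    @property
    def component_count(self) -> int:
        g = self.geometry
        return len(g.geoms) if hasattr(g, "geoms") else (0 if g.is_empty else 1)


def is_activated(
    placement: CellPlacement,
    sol: FieldSolution,
    wf: StimWaveform,
    params: ChannelParams,
    rest: membrane.MembraneState | None = None,
) -> bool:
    """Full-model activation check for one cell placement.

    Composes the boundary-current-density coupling, the membrane
    integration and the +30 mV detection; deterministic.
    """
    if rest is None:
        rest = membrane.resting_state(params)
    drive = BoundaryDrive(
        jc_unit=surface_current_density(sol, placement), waveform=wf
    )
    dt = min(2e-6, wf.phase_width / 20.0)
    trace = membrane.simulate(params, rest, drive, duration=wf.duration + 11e-3,
                              dt=dt, v_rest=rest.v)
    return membrane.detect_activation(trace)


def _bisect(predicate, r_true: float, r_false: float, ang: tuple[float, float],
            cx: float, cy: float, tol: float) -> float:
    """Radius of the activation transition along one ray, to ``tol``."""
    ca, sa = ang
    while abs(r_false - r_true) > tol:
        mid = 0.5 * (r_true + r_false)
        if predicate(cx + mid * ca, cy + mid * sa):
            r_true = mid
        else:
            r_false = mid
    return 0.5 * (r_true + r_false)


def trace_boundary(
    predicate,
    center: tuple[float, float],
    cfg: SearchConfig = SearchConfig(),
    pair: tuple[int, int] | None = None,
    stimulus: str = "",
) -> PerceptBoundary | None:
    """Trace the activation boundary of ``predicate`` around ``center``.

    ``predicate(x, y) -> bool`` is any deterministic activation field.
    Returns ``None`` when nothing activates within ``cfg.max_radius``
    (the no-stimulation signal).
    """
    cx, cy = center
    angles = [(math.cos(2 * math.pi * k / cfg.rays), math.sin(2 * math.pi * k / cfg.rays))
              for k in range(cfg.rays)]
    center_on = bool(predicate(cx, cy))
    radii = np.arange(cfg.coarse_step, cfg.max_radius + cfg.coarse_step, cfg.coarse_step)

    outer_pts: list[tuple[float, float]] = []
    inner_pts: list[tuple[float, float]] = []
    clipped = False
    any_activation = center_on

    for ca, sa in angles:
        on = center_on
        r_prev = 0.0
        r_inner = None
        r_outer = None
        for r in radii:
            now = bool(predicate(cx + r * ca, cy + r * sa))
            if not on and now:
                r_inner = _bisect(predicate, r, r_prev, (ca, sa), cx, cy, cfg.tol)
                on = True
                any_activation = True
            elif on and not now:
                r_outer = _bisect(predicate, r_prev, r, (ca, sa), cx, cy, cfg.tol)
                on = False
                break
            r_prev = r
        if on and r_outer is None:
            r_outer = cfg.max_radius
            clipped = True
        if r_outer is not None:
            outer_pts.append((cx + r_outer * ca, cy + r_outer * sa))
            if not center_on and r_inner is not None:
                inner_pts.append((cx + r_inner * ca, cy + r_inner * sa))

    if not any_activation or len(outer_pts) < 3:
        return None
    inner = None
    if not center_on and len(inner_pts) == cfg.rays:
        inner = np.array(inner_pts)
    return PerceptBoundary(
        outer=np.array(outer_pts), inner=inner, pair=pair,
        stimulus=stimulus, clipped=clipped,
    )


def activation_predicate(
    scene,
    sol: FieldSolution,
    amplitude: float,
    jc_threshold: float,
):
    """Threshold-comparison activation predicate from a unit field.

    A cell at (x, y) activates iff its unit-field boundary current density
    times the stimulus peak amplitude reaches the membrane threshold
    density for the pulse shape.  Positions whose cell surface leaves the
    solved subdomain are treated as silent.
    """

    def predicate(x: float, y: float) -> bool:
        cell = scene.cell_at(x, y)
        try:
            jc = surface_current_density(sol, cell)
        except Exception:
            return False
        return jc * amplitude >= jc_threshold

    return predicate


def trace_pair_boundary(
    scene,
    pair: tuple[int, int],
    params: ChannelParams,
    cfg: SearchConfig = SearchConfig(),
    jc_threshold: float | None = None,
) -> PerceptBoundary | None:
    """Percept boundary for one electrode pair, with current escalation.

    Solves (or reuses) the pair's unit field, starts the search concentric
    with the active electrode, and — if nothing activates at the base
    amplitude — raises the current by ``cfg.current_factor`` steps up to
    ``cfg.current_cap`` times the base before giving up.
    """
    sol = scene.solve_pair(pair)
    if jc_threshold is None:
        jc_threshold = membrane.threshold_density(params, scene.waveform)
    center = scene.active_center_xy(pair)
    amp = scene.waveform.peak_amplitude
    while True:
        pred = activation_predicate(scene, sol, amp, jc_threshold)
        b = trace_boundary(
            pred, center, cfg, pair=pair,
            stimulus=f"{amp * 1e6:.3g} µA, {scene.waveform.phase_width * 1e6:.3g} µs",
        )
        if b is not None:
            return b
        next_amp = amp * cfg.current_factor
        if cfg.current_factor <= 1 or next_amp > scene.waveform.peak_amplitude * cfg.current_cap * (1 + 1e-9):
            return None
        amp = next_amp


def compose_percept(
    scene,
    pairs: list[tuple[int, int]] | None = None,
    params: ChannelParams | None = None,
    cfg: SearchConfig = SearchConfig(),
    stack: LayerStack | None = None,
) -> Percept:
    """Total evoked phosphene across electrode pairs.

    Pairs are stimulated separately in time (the pulse-train spacing lets
    the membrane return to rest between pairs, which is verified in the
    membrane test suite), so the total percept is the geometric union of
    the per-pair activation regions.
    """
    if pairs is None:
        pairs = scene.pairs
    if not pairs:
        raise ValueError("need at least one electrode pair")
    if params is None:
        params = membrane.load_default_params()
    jc_threshold = membrane.threshold_density(params, scene.waveform)
    boundaries = [
        b for b in (
            trace_pair_boundary(scene, tuple(p), params, cfg, jc_threshold)
            for p in pairs
        ) if b is not None
    ]
    geom = unary_union([b.polygon for b in boundaries]) if boundaries else Polygon()
    percept = Percept(
        boundaries=boundaries,
        geometry=geom,
        union_area=float(geom.area),
        shape_class=_classify(geom, boundaries),
    )
    if stack is None:
        stack = getattr(scene, "stack", None)
    if stack is not None:
        percept.cell_count = estimate_cell_count(percept, stack)
    return percept


def _classify(geom, boundaries) -> str:
    if geom.is_empty:
        return "none"
    parts = list(geom.geoms) if hasattr(geom, "geoms") else [geom]
    if len(parts) > 1:
        return "composite"
    poly = parts[0]
    if poly.interiors:
        return "ring"
    rect = poly.minimum_rotated_rectangle
    xs, ys = rect.exterior.coords.xy
    e1 = math.hypot(xs[1] - xs[0], ys[1] - ys[0])
    e2 = math.hypot(xs[2] - xs[1], ys[2] - ys[1])
    lo, hi = sorted((e1, e2))
    return "elongated" if lo > 0 and hi / lo >= 2.0 else "dot"


def estimate_cell_count(p: Percept, stack: LayerStack) -> int:
    """Approximate activated-cell count: union area × areal density, floored."""
    return int(p.union_area * 1e-6 * stack.areal_density)


def mirror_asymmetry(boundary: PerceptBoundary | Polygon, axis: str = "x",
                     origin: float = 0.0) -> float:
    """Reflection asymmetry of a percept outline, in [0, 1].

    Reflects the polygon about the line ``x = origin`` (``axis="x"``) or
    ``y = origin`` and returns the symmetric-difference area over the union
    area; 0 means perfectly mirror-symmetric.
    """
    poly = boundary.polygon if isinstance(boundary, PerceptBoundary) else boundary
    if axis == "x":
        mirrored = shapely.affinity.scale(poly, xfact=-1, yfact=1, origin=(origin, 0.0))
    elif axis == "y":
        mirrored = shapely.affinity.scale(poly, xfact=1, yfact=-1, origin=(0.0, origin))
    else:
        raise ValueError("axis must be 'x' or 'y'")
    union = poly.union(mirrored)
    if union.area == 0:
        return 0.0
    return poly.symmetric_difference(mirrored).area / union.area


def percept_to_geojson(p: Percept, properties: dict | None = None) -> dict:
    """GeoJSON FeatureCollection of the percept (coordinates in µm)."""
    features = []
    for b in p.boundaries:
        features.append({
            "type": "Feature",
            "geometry": shapely.geometry.mapping(b.polygon),
            "properties": {
                "pair": list(b.pair) if b.pair else None,
                "stimulus": b.stimulus,
                "area_um2": b.area,
                "clipped": b.clipped,
            },
        })
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "union_area_um2": p.union_area,
            "shape_class": p.shape_class,
            "cell_count": p.cell_count,
            **(properties or {}),
        },
    }
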
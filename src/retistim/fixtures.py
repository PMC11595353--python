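"""Deterministic synthetic scenes and analytic oracles.

Everything here is a pure function of its parameters: building the same
scene twice yields bit-identical configurations, which keeps the whole
pipeline testable without any external data.  Three families are provided:

* canned layered-retina scenes — the 3D linear-carrier pair
  (:func:`make_lce_scene`) and the 25-electrode hexagonal array
  (:func:`make_hex_scene`) with the published material and waveform
  parameters as defaults;
* closed-form fields (monopole, dipole) used as solver oracles; and
* radial activation predicates used as boundary-tracer oracles.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import carrier3d, membrane, waveforms
from .fieldsolver import ConductivityGrid, FieldSolution, solve_unit_field
from .geometry import (
    CellPlacement,
    HexArray,
    LayerStack,
    LinearCarrierPair,
    build_hex_array,
    build_layer_stack,
    place_cell,
)

__all__ = [
    "table1_layer_table",
    "table3_layer_table",
    "table1_stack",
    "table3_stack",
    "LCEScene",
    "HexScene",
    "make_lce_scene",
    "make_hex_scene",
    "make_analytic_field",
    "MonopoleField",
    "DipoleField",
    "RadialPredicate",
    "subject_pairs",
    "list_presets",
]

SIGMA_POLYIMIDE = 1e-17  # S/m
RGC_DIAMETER_UM = 10.0
RGC_AREAL_DENSITY_MM2 = 31_300.0
GANGLION_THICKNESS_3D_UM = 60.0


# --------------------------------------------------------------------------
# layer tables
# --------------------------------------------------------------------------

def table1_layer_table(vitreous_thickness: float = 300.0) -> list[dict]:
    """Slab rows of the 2D hexagonal-array tissue model.

    The vitreous is an effectively unbounded medium; ``vitreous_thickness``
    is the modelled slab extent (its nominal 22 mm eye diameter is stack
    metadata).  Conductivities in S/m, thicknesses in µm.
    """
    return [
        {"name": "vitreous", "conductivity": 1.5, "relative_permittivity": 98.0,
         "thickness": vitreous_thickness},
        {"name": "ganglionic", "conductivity": 0.1, "relative_permittivity": 1.0,
         "thickness": 65.0},
        {"name": "photoreceptor", "conductivity": 28.5e-3, "relative_permittivity": 1.0,
         "thickness": 200.0},
        {"name": "epithelium", "conductivity": 2e-3, "relative_permittivity": 1.0,
         "thickness": 65.0},
    ]


def table3_layer_table(vitreous_thickness: float = 100.0) -> list[dict]:
    """Slab rows of the 3D linear-carrier tissue model.

    Adds the inner nuclear layer between the (thinner, 60 µm) ganglion
    layer and the photoreceptor layer; remaining materials are shared with
    the 2D model.
    """
    return [
        {"name": "vitreous", "conductivity": 1.5, "relative_permittivity": 98.0,
         "thickness": vitreous_thickness},
        {"name": "ganglionic", "conductivity": 0.1, "relative_permittivity": 1.0,
         "thickness": GANGLION_THICKNESS_3D_UM},
        {"name": "inner-nuclear", "conductivity": 15e-3, "relative_permittivity": 1.0,
         "thickness": 100.0},
        {"name": "photoreceptor", "conductivity": 28.5e-3, "relative_permittivity": 1.0,
         "thickness": 200.0},
        {"name": "epithelium", "conductivity": 2e-3, "relative_permittivity": 1.0,
         "thickness": 65.0},
    ]


_COMMON_METADATA = {
    "eye_outer_diameter_mm": 22.33,
    "nominal_layer_diameters_mm": {
        "vitreous": 22.0, "ganglionic": 22.065, "photoreceptor": 22.265,
        "epithelium": 22.33,
    },
    "contact_conductivity_S_per_m": 321.0,  # electrode-tissue interface, metadata only
    "cell_membrane": {"conductivity_S_per_m": 1e-8, "thickness_um": 0.001},
    "intracellular": {"conductivity_S_per_m": 0.1, "thickness_um": 30.0},
    "pedot_coating": {"conductivity_S_per_m": 400.0, "thickness_um": 0.2},
    "polyimide": {"conductivity_S_per_m": SIGMA_POLYIMIDE},
}


def table1_stack(vitreous_thickness: float = 300.0) -> LayerStack:
    return build_layer_stack(
        table1_layer_table(vitreous_thickness),
        areal_density=RGC_AREAL_DENSITY_MM2,
        metadata=dict(_COMMON_METADATA),
    )


def table3_stack(vitreous_thickness: float = 100.0) -> LayerStack:
    return build_layer_stack(
        table3_layer_table(vitreous_thickness),
        areal_density=RGC_AREAL_DENSITY_MM2,
        metadata=dict(_COMMON_METADATA),
    )


def _scene_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


# --------------------------------------------------------------------------
# 3D linear-carrier scene
# --------------------------------------------------------------------------

@dataclass
class LCEScene:
    """Face-to-face linear-carrier electrode pair with a mid-placed cell.

    The pair axis is x: the active electrode disc faces +x at
    x = −λ/2, the ground disc faces −x at x = +λ/2, both at the
    peak-density depth of the ganglion layer; the model cell sits midway,
    equidistant from both electrodes.
    """

    stack: LayerStack
    carrier: LinearCarrierPair
    cell: CellPlacement
    waveform: waveforms.StimWaveform  # amplitude is the search template peak
    electrode_depth: float  # µm below the retinal surface (negative z)
    h: float  # µm grid spacing
    half_extent_xy: float  # µm
    z_range: tuple[float, float]  # (z_min, z_max) µm
    cube: carrier3d.CubeCriterion
    _solution: FieldSolution | None = field(default=None, repr=False)

    @property
    def config_hash(self) -> str:
        return _scene_hash({
            "kind": "lce",
            "lambda": self.carrier.inter_carrier_length,
            "electrode_diameter": self.carrier.electrode_diameter,
            "electrode_depth": self.electrode_depth,
            "h": self.h, "half_extent_xy": self.half_extent_xy,
            "z_range": self.z_range,
            "cell": (self.cell.center, self.cell.diameter),
            "waveform": (self.waveform.shape, self.waveform.phase_width),
            "layers": [(ly.name, ly.conductivity, ly.thickness) for ly in self.stack.layers],
        })

    def build_grid(self) -> ConductivityGrid:
        h = self.h
        lam = self.carrier.inter_carrier_length
        half_gap = lam / 2.0
        # voxel centres offset by h/2 so the electrode faces x = ±λ/2 land
        # exactly on voxel boundaries (h is chosen as λ/10)
        m = int(round(self.half_extent_xy / h))
        cx = (np.arange(2 * m) - m + 0.5) * h
        cy = cx.copy()
        z0, z1 = self.z_range
        nz = int(round((z1 - z0) / h))
        cz = z0 + (np.arange(nz) + 0.5) * h
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")

        sigma = self.stack.conductivity_at(Z.ravel()).reshape(Z.shape)

        # insulating carrier shanks spanning the ganglion layer
        gl = self.stack.ganglion_layer
        depth = max(self.carrier.lce_depth, h)
        half_w = self.carrier.lce_outer_diameter / 2.0
        in_z = (Z <= gl.z_top + 1e-9) & (Z >= gl.z_bottom - 1e-9)
        in_y = np.abs(Y) <= half_w
        left = (X < -half_gap) & (X >= -half_gap - depth)
        right = (X > half_gap) & (X <= half_gap + depth)
        sigma[(left | right) & in_y & in_z] = SIGMA_POLYIMIDE

        # electrode discs: first tissue voxel layer on the gap side of each face
        r_e = self.carrier.electrode_diameter / 2.0
        ze = -self.electrode_depth if self.electrode_depth > 0 else self.electrode_depth
        disc = np.hypot(Y, Z - ze) <= r_e
        # first tissue voxel-centre column on the gap side of each face
        xa = cx[np.argmin(np.abs(cx - (-half_gap + h / 2.0)))]
        xg = cx[np.argmin(np.abs(cx - (half_gap - h / 2.0)))]
        col_a = np.abs(X - xa) < h / 4.0
        col_g = np.abs(X - xg) < h / 4.0
        active = disc & col_a
        ground = disc & col_g
        return ConductivityGrid(
            h=h,
            origin=(float(cx[0]), float(cy[0]), float(cz[0])),
            sigma=sigma,
            active_mask=active,
            ground_mask=ground,
        )

    def solve(self, tol: float = 1e-8) -> FieldSolution:
        if self._solution is None:
            self._solution = solve_unit_field(self.build_grid(), tol=tol)
        return self._solution


def make_lce_scene(
    rho_v_peak: float = carrier3d.RHO_V_PEAK,
    electrode_diameter: float = 7.5,
    pulse_width: float = 100e-6,
    cell_diameter: float = RGC_DIAMETER_UM,
    h: float | None = None,
    half_extent_xy: float | None = None,
) -> LCEScene:
    """The 3D linear-carrier scene at the published operating point.

    λ is derived from the peak volumetric density via the cube criterion
    (λ = ρ_v^{−1/3}); electrodes sit face-to-face at the peak-density depth
    (mid-layer) and the cell is concentric between them.  The default grid
    spacing is λ/10 so the electrode faces coincide with voxel boundaries.
    """
    cube = carrier3d.cube_from_density(rho_v_peak, cell_diameter)
    lam = cube.cube_length
    if h is None:
        h = lam / 10.0
    if half_extent_xy is None:
        half_extent_xy = round(43 * h, 6)
    stack = table3_stack()
    gl = stack.ganglion_layer
    depth_mid = 0.5 * (gl.z_top + gl.z_bottom)  # peak-density depth, mid-layer
    carrier = LinearCarrierPair(
        lce_length=GANGLION_THICKNESS_3D_UM,
        lce_depth=2.0,
        lce_outer_diameter=9.0,
        inter_carrier_length=lam,
        electrode_diameter=electrode_diameter,
        electrode_z=(depth_mid,),
    )
    cell = place_cell(
        stack, (0.0, 0.0),
        proximity=-depth_mid - cell_diameter / 2.0,  # electrode plane at z=0 reference
        diameter=cell_diameter,
        electrode_plane_z=0.0,
    )
    wf = waveforms.linear_decrease(0.1e-9, pulse_width)
    z_min = depth_mid - 60.0
    z_max = 20.0
    return LCEScene(
        stack=stack,
        carrier=carrier,
        cell=cell,
        waveform=wf,
        electrode_depth=depth_mid,
        h=h,
        half_extent_xy=half_extent_xy,
        z_range=(z_min, z_max),
        cube=cube,
    )


# --------------------------------------------------------------------------
# 2D hexagonal-array scene
# --------------------------------------------------------------------------

def subject_pairs(subject: str | int) -> list[tuple[int, int]]:
    """Electrode-pair list for a subject preset (reconstructed from figures)."""
    with resources.files("retistim.data").joinpath("hex_subject_pairs.json").open() as f:
        doc = json.load(f)
    key = str(subject)
    if key not in doc["subjects"]:
        raise KeyError(f"unknown subject preset {subject!r}; known: {sorted(doc['subjects'])}")
    return [tuple(p) for p in doc["subjects"][key]["pairs"]]


@dataclass
class HexScene:
    """Epiretinal hexagonal-array scene for percept mapping.

    The array floats in the vitreous at proximity ``p`` above the retinal
    surface (cell tops); each electrode pair is solved on its own subdomain
    centred on the pair, reusing the unit field across cell shifts and
    stimulus amplitudes.
    """

    stack: LayerStack
    array: HexArray
    pairs: list[tuple[int, int]]
    waveform: waveforms.StimWaveform
    proximity: float  # µm
    theta: float  # degrees
    cell_diameter: float = RGC_DIAMETER_UM
    h: float = 10.0
    margin: float = 1000.0  # µm of subdomain around the pair bounding box
    z_bottom: float = -165.0  # µm, subdomain floor
    reduced_conductivity: bool = False
    _solutions: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        return _scene_hash({
            "kind": "hex", "pairs": self.pairs, "p": self.proximity,
            "theta": self.theta, "h": self.h, "margin": self.margin,
            "z_bottom": self.z_bottom, "reduced": self.reduced_conductivity,
            "wf": (self.waveform.shape, self.waveform.peak_amplitude,
                   self.waveform.phase_width, self.waveform.frequency),
            "layers": [(ly.name, ly.conductivity, ly.thickness) for ly in self.stack.layers],
        })

    def cell_at(self, x: float, y: float) -> CellPlacement:
        return place_cell(
            self.stack, (x, y), proximity=self.proximity,
            diameter=self.cell_diameter,
        )

    def build_pair_grid(self, pair: tuple[int, int]) -> ConductivityGrid:
        h = self.h
        ea, eg = (self.array.electrode(pair[0]), self.array.electrode(pair[1]))
        xs = [ea.center[0], eg.center[0]]
        ys = [ea.center[1], eg.center[1]]
        x0, x1 = min(xs) - self.margin, max(xs) + self.margin
        y0, y1 = min(ys) - self.margin, max(ys) + self.margin
        z_top = max(ea.center[2], eg.center[2]) + 80.0
        cx = np.arange(x0, x1 + h / 2, h)
        cy = np.arange(y0, y1 + h / 2, h)
        cz = np.arange(self.z_bottom, z_top + h / 2, h)
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        sigma = self.stack.conductivity_at(Z.ravel()).reshape(Z.shape)

        # polyimide substrate above the (possibly tilted) electrode plane
        xy = self.array.centers
        x_pivot = xy[:, 0].min()
        th = math.radians(self.theta)
        plane = self.proximity - (X - x_pivot) * math.sin(th)
        in_substrate = (
            (Z > plane) & (Z <= plane + 65.0)
            & (np.abs(Y) <= self.array.substrate[0] / 2.0)
        )
        sigma[in_substrate] = SIGMA_POLYIMIDE

        conductive = sigma > 1e-12

        def disc_mask(e):
            # first conductive voxel layer under the local (tilted) array plane
            r = e.diameter / 2.0
            within = np.hypot(X - e.center[0], Y - e.center[1]) <= r
            layer = (Z <= plane) & (Z > plane - h)
            return within & layer & conductive

        active = disc_mask(ea)
        ground = disc_mask(eg)
        return ConductivityGrid(
            h=h, origin=(float(cx[0]), float(cy[0]), float(cz[0])),
            sigma=sigma, active_mask=active, ground_mask=ground,
        )

    def solve_pair(self, pair: tuple[int, int], tol: float = 1e-8) -> FieldSolution:
        key = tuple(pair)
        if key not in self._solutions:
            self._solutions[key] = solve_unit_field(self.build_pair_grid(pair), tol=tol)
        return self._solutions[key]

    def active_center_xy(self, pair: tuple[int, int]) -> tuple[float, float]:
        c = self.array.electrode(pair[0]).center
        return (c[0], c[1])


def make_hex_scene(
    preset: str | int | None = None,
    pairs: list[tuple[int, int]] | None = None,
    proximity: float = 10.0,
    theta: float = 0.0,
    amplitude: float = 13e-6,
    phase_width: float = 94e-6,
    frequency: float = 100.0,
    reduced_conductivity: bool = False,
    h: float = 10.0,
    margin: float = 1000.0,
) -> HexScene:
    """Hexagonal-array scene: 25 electrodes, 100 µm discs, 500 µm pitch.

    ``preset`` selects a subject pair list (reconstructed from figure
    panels); alternatively give explicit ``pairs``.  The default stimulus
    is the clinical setting: 13 µA, 94 µs per phase, 100 Hz, charge-balanced
    biphasic.  ``reduced_conductivity`` applies the factor-10 reduction of
    the ganglionic (and intracellular, metadata) conductivity used for the
    dot-percept restoration scenario.
    """
    if pairs is None:
        if preset is None:
            raise ValueError("give a subject preset or an explicit pair list")
        pairs = subject_pairs(preset)
    stack = table1_stack(vitreous_thickness=max(300.0, proximity + 150.0))
    if reduced_conductivity:
        stack = stack.with_conductivity_factor(("ganglionic",), 0.1)
    array = build_hex_array(100.0, 500.0, theta=theta, plane_z=proximity)
    wf = waveforms.biphasic_rectangular(amplitude, phase_width, frequency)
    return HexScene(
        stack=stack, array=array, pairs=list(pairs), waveform=wf,
        proximity=proximity, theta=theta, h=h, margin=margin,
        reduced_conductivity=reduced_conductivity,
    )


# --------------------------------------------------------------------------
# analytic fields and predicates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MonopoleField:
    """Point current source in an unbounded homogeneous medium.

    V(r) = I / (4πσr); J(r) = I r̂ / (4πr²).  Lengths in µm, I in A, σ in S/m.
    """

    sigma: float
    current: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def potential(self, points) -> np.ndarray:
        r = np.linalg.norm(np.atleast_2d(points) - np.asarray(self.center), axis=-1) * 1e-6
        r = np.maximum(r, 1e-12)  # clamp the r→0 singularity at the source
        return self.current / (4.0 * math.pi * self.sigma * r)

    def current_density(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - np.asarray(self.center)
        r = np.linalg.norm(d, axis=-1, keepdims=True) * 1e-6
        return self.current * (d * 1e-6) / (4.0 * math.pi * r ** 3)


@dataclass(frozen=True)
class DipoleField:
    """Superposed source/sink pair (±I); net injected current is zero."""

    sigma: float
    current: float
    source: tuple[float, float, float]
    sink: tuple[float, float, float]

    def _parts(self):
        return (
            MonopoleField(self.sigma, self.current, self.source),
            MonopoleField(self.sigma, -self.current, self.sink),
        )

    def potential(self, points) -> np.ndarray:
        a, b = self._parts()
        return a.potential(points) + b.potential(points)

    def current_density(self, points) -> np.ndarray:
        a, b = self._parts()
        return a.current_density(points) + b.current_density(points)

    @property
    def net_source(self) -> float:
        return 0.0


@dataclass(frozen=True)
class RadialPredicate:
    """Activation iff r_inner ≤ |xy − center| ≤ r_outer (µm)."""

    r_outer: float
    r_inner: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __call__(self, x, y) -> np.ndarray:
        r = np.hypot(np.asarray(x) - self.center[0], np.asarray(y) - self.center[1])
        return (r >= self.r_inner) & (r <= self.r_outer)


def make_analytic_field(kind: str, **params):
    """Closed-form field or activation predicate by name.

    Kinds: ``monopole`` (sigma, current, center), ``dipole`` (sigma,
    current, source, sink), ``radial-predicate`` (r_outer, r_inner,
    center).
    """
    if kind == "monopole":
        return MonopoleField(**params)
    if kind == "dipole":
        return DipoleField(**params)
    if kind == "radial-predicate":
        return RadialPredicate(**params)
    raise KeyError(f"unknown analytic field kind {kind!r}")


def list_presets() -> dict:
    """Catalogue of shipped presets (for the fixtures CLI)."""
    return {
        "stacks": ["table1", "table3"],
        "scenes": ["lce", "hex"],
        "hex_subjects": ["1", "2", "3", "6"],
        "analytic": ["monopole", "dipole", "radial-predicate"],
    }
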
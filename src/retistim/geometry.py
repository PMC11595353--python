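"""Layered retina geometry, electrode arrays, and model-cell placement.

Coordinate convention (right-handed): x and y span the retinal plane, z is
positive toward the vitreous, and z = 0 sits at the retinal surface, i.e.
the top of the ganglion-cell layer.  All lengths are micrometres
internally; electrical quantities are SI.

The retina is modelled as a stack of plane-parallel tissue slabs.  At the
sub-millimetre feature scale of electrode arrays and single cells, the
~22 mm curvature of the eye wall is negligible, so spherical shells are
replaced by slabs; nominal eye diameters can be attached as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueLayer",
    "LayerStack",
    "ElectrodeSpec",
    "HexArray",
    "LinearCarrierPair",
    "CellPlacement",
    "GeometryError",
    "build_layer_stack",
    "build_hex_array",
    "place_cell",
]


class GeometryError(ValueError):
    """Invalid geometric configuration (overlap, out-of-layer placement, ...)."""


@dataclass(frozen=True)
class TissueLayer:
    """One plane-parallel tissue slab with its electrical properties."""

    name: str
    conductivity: float  # S/m
    relative_permittivity: float
    thickness: float  # µm
    z_top: float  # µm
    z_bottom: float  # µm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise GeometryError(f"layer {self.name!r}: thickness must be > 0")
        if self.conductivity < 0:
            raise GeometryError(f"layer {self.name!r}: conductivity must be >= 0")
        if not math.isclose(self.z_top - self.z_bottom, self.thickness, rel_tol=1e-9, abs_tol=1e-9):
            raise GeometryError(f"layer {self.name!r}: z_top - z_bottom != thickness")

    def contains(self, z: float) -> bool:
        return self.z_bottom <= z < self.z_top


@dataclass(frozen=True)
class LayerStack:
    """Ordered, contiguous tissue slabs from the vitreous downward.

    Exactly one layer is the ganglion-cell layer; it carries the areal
    density of retinal ganglion cells used for percept cell counts.
    """

    layers: tuple[TissueLayer, ...]
    ganglion_layer_name: str
    areal_density: float  # RGC per mm² of retina
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise GeometryError("layer stack is empty")
        for above, below in zip(self.layers, self.layers[1:]):
            if not math.isclose(above.z_bottom, below.z_top, rel_tol=0, abs_tol=1e-9):
                raise GeometryError(
                    f"layers {above.name!r} and {below.name!r} are not contiguous"
                )
        names = [ly.name for ly in self.layers]
        if names.count(self.ganglion_layer_name) != 1:
            raise GeometryError(
                f"stack must contain exactly one ganglion layer named "
                f"{self.ganglion_layer_name!r}; got {names}"
            )
        if self.areal_density <= 0:
            raise GeometryError("areal_density must be > 0")

    @property
    def z_top(self) -> float:
        return self.layers[0].z_top

    @property
    def z_bottom(self) -> float:
        return self.layers[-1].z_bottom

    @property
    def ganglion_layer(self) -> TissueLayer:
        return next(ly for ly in self.layers if ly.name == self.ganglion_layer_name)

    @property
    def ganglion_thickness(self) -> float:
        return self.ganglion_layer.thickness

    def layer_at(self, z: float) -> TissueLayer:
        """Layer containing depth ``z``.

        Each interface belongs to the layer above it; the outermost
        boundaries are inclusive, so every z in the stack range maps to
        exactly one layer.
        """
        if not (self.z_bottom <= z <= self.z_top):
            raise GeometryError(f"z = {z} µm outside stack [{self.z_bottom}, {self.z_top}]")
        if z == self.z_top:
            return self.layers[0]
        for ly in self.layers:
            if ly.contains(z):
                return ly
        return self.layers[-1]  # z == z_bottom exactly

    def conductivity_at(self, z) -> np.ndarray:
        """Vectorized conductivity lookup (S/m) clamped to the stack range."""
        z = np.asarray(z, dtype=float)
        tops = np.array([ly.z_top for ly in self.layers])
        sig = np.array([ly.conductivity for ly in self.layers])
        idx = np.clip(np.searchsorted(-tops, -z, side="right") - 1, 0, len(sig) - 1)
        return sig[idx]

    def with_conductivity_factor(self, names: tuple[str, ...], factor: float) -> "LayerStack":
        """Stack with the named layers' conductivities scaled by ``factor``."""
        new = tuple(
            replace(ly, conductivity=ly.conductivity * factor) if ly.name in names else ly
            for ly in self.layers
        )
        return replace(self, layers=new)


def build_layer_stack(
    layer_table: list[dict],
    ganglion_layer_name: str = "ganglionic",
    areal_density: float = 31_300.0,
    surface_layer_name: str | None = None,
    metadata: dict | None = None,
) -> LayerStack:
    """Build a contiguous stack from ordered layer descriptors.

    Each descriptor needs ``name``, ``conductivity`` (S/m), ``thickness``
    (µm), and optionally ``relative_permittivity`` (default 1).  Descriptors
    are ordered from the vitreous downward.  z = 0 is placed at the top of
    ``surface_layer_name`` (default: the ganglion layer), so any layers
    listed above it (the vitreous) get positive z.
    """
    if surface_layer_name is None:
        surface_layer_name = ganglion_layer_name
    names = [d["name"] for d in layer_table]
    if surface_layer_name not in names:
        raise GeometryError(f"no layer named {surface_layer_name!r} to anchor z = 0")
    # thickness above the surface layer
    above = 0.0
    for d in layer_table:
        if d["name"] == surface_layer_name:
            break
        above += float(d["thickness"])
    layers = []
    z_top = above
    for d in layer_table:
        th = float(d["thickness"])
        layers.append(
            TissueLayer(
                name=d["name"],
                conductivity=float(d["conductivity"]),
                relative_permittivity=float(d.get("relative_permittivity", 1.0)),
                thickness=th,
                z_top=z_top,
                z_bottom=z_top - th,
            )
        )
        z_top -= th
    return LayerStack(
        layers=tuple(layers),
        ganglion_layer_name=ganglion_layer_name,
        areal_density=areal_density,
        metadata=dict(metadata or {}),
    )


@dataclass(frozen=True)
class ElectrodeSpec:
    """A disc electrode: centre, diameter, stimulation role, material."""

    center: tuple[float, float, float]  # µm
    diameter: float  # µm
    role: str  # "active" | "ground"
    material: str = "platinum"
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)  # disc face normal

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("electrode diameter must be > 0")
        if self.role not in ("active", "ground"):
            raise GeometryError(f"electrode role must be active|ground, got {self.role!r}")

    @property
    def area_m2(self) -> float:
        """Disc face area in m²."""
        d_m = self.diameter * 1e-6
        return math.pi * d_m * d_m / 4.0


@dataclass(frozen=True)
class HexArray:
    """Hexagonally packed epiretinal disc-electrode array.

    25 electrodes in five staggered rows of five; nearest-neighbour spacing
    equals ``pitch`` when untilted.  A tilt angle θ rotates the array plane
    about an axis along the array width through its near edge (the edge
    electrodes keep their height; the far edge approaches the retina).
    """

    electrodes: tuple[ElectrodeSpec, ...]
    pitch: float  # µm
    substrate: tuple[float, float] = (2000.0, 4000.0)  # µm (width, length)
    tilt_angle: float = 0.0  # degrees
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        if len(self.electrodes) != 25:
            raise GeometryError(f"hex array needs 25 electrodes, got {len(self.electrodes)}")

    @property
    def centers(self) -> np.ndarray:
        return np.array([e.center for e in self.electrodes])

    def electrode(self, index: int) -> ElectrodeSpec:
        return self.electrodes[index]


def _hex_lattice_25(pitch: float) -> np.ndarray:
    """5 staggered rows of 5: centred hexagonal packing, 25 sites, in-plane."""
    pts = []
    dy = pitch * math.sqrt(3.0) / 2.0
    for row in range(5):
        y = (row - 2) * dy
        x0 = -2.0 * pitch + (pitch / 2.0 if row % 2 else 0.0)
        for col in range(5):
            pts.append((x0 + col * pitch, y))
    pts = np.array(pts)
    pts -= pts.mean(axis=0)  # centre the array on the origin
    return pts


def build_hex_array(
    diameter: float,
    pitch: float,
    theta: float = 0.0,
    plane_z: float = 0.0,
    material: str = "PEDOT-coated",
    substrate: tuple[float, float] = (2000.0, 4000.0),
) -> HexArray:
    """Build the 25-electrode hexagonal array at height ``plane_z`` (µm).

    ``theta`` tilts the array about a width-parallel (y) axis through the
    near edge (minimum-x electrode column), bringing larger-x electrodes
    closer to the retina; the near edge keeps its height, so the minimum
    electrode-retina proximity is preserved.
    """
    if diameter >= pitch:
        raise GeometryError(f"electrodes overlap: diameter {diameter} >= pitch {pitch}")
    xy = _hex_lattice_25(pitch)
    x_pivot = xy[:, 0].min()
    th = math.radians(theta)
    x = x_pivot + (xy[:, 0] - x_pivot) * math.cos(th)
    z = plane_z - (xy[:, 0] - x_pivot) * math.sin(th)
    normal = (math.sin(th), 0.0, math.cos(th))
    electrodes = tuple(
        ElectrodeSpec(
            center=(float(xi), float(yi), float(zi)),
            diameter=diameter,
            role="active",
            material=material,
            normal=normal,
        )
        for xi, yi, zi in zip(x, xy[:, 1], z)
    )
    return HexArray(
        electrodes=electrodes,
        pitch=pitch,
        substrate=substrate,
        tilt_angle=theta,
        tilt_axis="y",
    )


@dataclass(frozen=True)
class LinearCarrierPair:
    """Two facing linear carrier elements (LCEs) penetrating the retina.

    Each LCE is a vertical insulating shank spanning the ganglion layer and
    carrying disc electrodes on the face looking across the inter-carrier
    gap λ.  The pair axis is x; electrode faces are separated by λ.
    """

    lce_length: float  # µm, vertical extent of each shank
    lce_depth: float  # µm, shank thickness along the pair axis
    lce_outer_diameter: float  # µm, shank width across the pair axis
    inter_carrier_length: float  # µm, λ: face-to-face electrode separation
    electrode_diameter: float  # µm
    electrode_z: tuple[float, ...]  # µm, electrode centre depths on each shank

    def __post_init__(self) -> None:
        if self.inter_carrier_length <= 0:
            raise GeometryError("inter-carrier length λ must be > 0")
        if self.electrode_diameter <= 0:
            raise GeometryError("electrode diameter must be > 0")

    @property
    def electrodes(self) -> tuple[ElectrodeSpec, ...]:
        """Facing disc electrodes: active on the -x shank, ground on the +x shank."""
        half = self.inter_carrier_length / 2.0
        specs = []
        for z in self.electrode_z:
            specs.append(
                ElectrodeSpec((-half, 0.0, z), self.electrode_diameter, "active",
                              material="platinum", normal=(1.0, 0.0, 0.0)))
            specs.append(
                ElectrodeSpec((half, 0.0, z), self.electrode_diameter, "ground",
                              material="platinum", normal=(-1.0, 0.0, 0.0)))
        return tuple(specs)


@dataclass(frozen=True)
class CellPlacement:
    """A spherical model RGC inside the ganglion layer.

    ``proximity`` records the distance from the electrode plane down to the
    top of the cell.  Shifts accumulate in an offset vector relative to the
    original placement, so a shift followed by its exact inverse restores
    the original coordinates bit-exactly.
    """

    base_center: tuple[float, float, float]  # µm
    diameter: float  # µm
    base_proximity: float  # µm, at zero offset
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("cell diameter must be > 0")

    @property
    def center(self) -> tuple[float, float, float]:
        return (
            self.base_center[0] + self.offset[0],
            self.base_center[1] + self.offset[1],
            self.base_center[2] + self.offset[2],
        )

    @property
    def proximity(self) -> float:
        """Electrode plane to cell top, tracking any vertical shift."""
        return self.base_proximity - self.offset[2]

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def shifted(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "CellPlacement":
        """Placement translated by (dx, dy, dz); proximity tracks the z shift."""
        return replace(
            self,
            offset=(self.offset[0] + dx, self.offset[1] + dy, self.offset[2] + dz),
        )

    def validate_in_layer(self, layer: TissueLayer) -> "CellPlacement":
        zc = self.center[2]
        if zc + self.radius > layer.z_top + 1e-9 or zc - self.radius < layer.z_bottom - 1e-9:
            raise GeometryError(
                f"cell sphere [z {zc - self.radius:g}, {zc + self.radius:g}] leaves "
                f"layer {layer.name!r} [{layer.z_bottom:g}, {layer.z_top:g}]"
            )
        return self


def place_cell(
    stack: LayerStack,
    xy: tuple[float, float],
    proximity: float,
    diameter: float,
    electrode_plane_z: float | None = None,
) -> CellPlacement:
    """Place a spherical cell below the electrode plane inside the ganglion layer.

    The initial placement of the percept-mapping loop is concentric with the
    active electrode in the retinal plane; ``xy`` is that lateral position.
    ``electrode_plane_z`` defaults to ``proximity``, which puts the top of
    the cell at the retinal surface (z = 0).  Raises ``GeometryError`` when
    the sphere would leave the ganglion layer — the stop signal for the
    cell-shifting loop.
    """
    if electrode_plane_z is None:
        electrode_plane_z = proximity
    zc = electrode_plane_z - proximity - diameter / 2.0
    placement = CellPlacement(
        base_center=(float(xy[0]), float(xy[1]), float(zc)),
        diameter=float(diameter),
        base_proximity=float(proximity),
    )
    return placement.validate_in_layer(stack.ganglion_layer)
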
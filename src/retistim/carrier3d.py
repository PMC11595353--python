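"""Single-cell selectivity analysis for the 3D linear electrode carrier.

The selectivity criterion compares the stimulation volume produced by the
current-density distribution at threshold with the volume statistically
enclosed by one retinal ganglion cell, v = ρ_v⁻¹, where ρ_v is the
volumetric cell density (µm⁻³).  Assuming a locally homogeneous cell
distribution, that volume is characterized as a cube of edge λ = v^{1/3};
λ is also the face-to-face separation of electrodes on adjacent linear
carrier elements.  An electrode pair is single-cell selective when the
suprathreshold |J| region at the threshold stimulus fits within v and the
mid-placed cell actually fires.

The vertical density profile through the ganglion layer is modelled as a
3rd-order polynomial whose integral over the layer reproduces the measured
areal density.  The peak volumetric density near the fovea,
``RHO_V_PEAK = 8.05e-4 µm⁻³`` (31,300 mm⁻² areal density over a 60 µm
layer, peaking mid-layer), ships as a named constant;
:func:`fit_density_profile` regenerates profiles from photomicrograph
samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import Polynomial

from .fieldsolver import FieldSolution, suprathreshold_volume

__all__ = [
    "RHO_V_PEAK",
    "DensityProfile",
    "CubeCriterion",
    "cube_from_density",
    "fit_density_profile",
    "evaluate_selectivity",
]

RHO_V_PEAK = 8.05e-4  # µm⁻³, peak volumetric RGC density at the modelled location


@dataclass(frozen=True)
class DensityProfile:
    """Cubic volumetric-density profile ρ_v(z) through the ganglion layer.

    ``poly`` maps depth-below-layer-top (µm, 0 at the top) to ρ_v in µm⁻³;
    its integral over the thickness times 10⁶ µm²/mm² equals the areal
    density (mm⁻²).
    """

    poly: Polynomial
    thickness: float  # µm
    areal_density: float  # mm⁻²
    clipped: bool = False

    def __call__(self, depth) -> np.ndarray:
        return self.poly(np.asarray(depth, dtype=float))

    @property
    def peak(self) -> tuple[float, float]:
        """(ρ_v,peak in µm⁻³, depth of the peak in µm below the layer top)."""
        zz = np.linspace(0.0, self.thickness, 2001)
        vals = self.poly(zz)
        i = int(np.argmax(vals))
        return float(vals[i]), float(zz[i])


@dataclass(frozen=True)
class CubeCriterion:
    """Cube-of-stimulation selectivity verdict for one electrode pair."""

    cube_volume: float  # µm³, v = 1/ρ_v
    cube_length: float  # µm, λ = v^(1/3)
    cell_volume: float  # µm³
    volume_ratio: float  # v / cell volume
    threshold_amplitude: float | None = None  # A
    suprathreshold_volume_um3: float | None = None
    cell_activated: bool | None = None
    verdict: str | None = None  # "selective" | "not-selective"

    def as_dict(self) -> dict:
        return {
            "cube_volume_um3": self.cube_volume,
            "cube_length_um": self.cube_length,
            "cell_volume_um3": self.cell_volume,
            "volume_ratio": self.volume_ratio,
            "threshold_amplitude_A": self.threshold_amplitude,
            "suprathreshold_volume_um3": self.suprathreshold_volume_um3,
            "cell_activated": self.cell_activated,
            "verdict": self.verdict,
        }


def cube_from_density(rho_v: float, cell_diameter: float) -> CubeCriterion:
    """Geometric part of the criterion: v = ρ_v⁻¹, λ = v^{1/3}.

    ``rho_v`` in µm⁻³, ``cell_diameter`` in µm.  The cell volume is the
    sphere volume (π/6)d³ and the ratio v / cell volume measures how much
    spare room the cube leaves around one cell.
    """
    if rho_v <= 0:
        raise ValueError("volumetric density must be > 0")
    if cell_diameter <= 0:
        raise ValueError("cell diameter must be > 0")
    v = 1.0 / rho_v
    cell_v = math.pi / 6.0 * cell_diameter ** 3
    return CubeCriterion(
        cube_volume=v,
        cube_length=v ** (1.0 / 3.0),
        cell_volume=cell_v,
        volume_ratio=v / cell_v,
    )


def fit_density_profile(
    samples: list[tuple[float, float]],
    areal_density: float,
    thickness: float,
) -> DensityProfile:
    """Least-squares cubic fit of relative density samples, then rescaling.

    ``samples`` are (depth below layer top in µm, relative density) pairs in
    arbitrary units spanning the layer; the fitted cubic is rescaled so its
    integral over the thickness equals ``areal_density`` per mm².  The fit
    is therefore invariant to uniform rescaling of the inputs.  A fit that
    goes negative inside the layer is clipped at zero before normalization
    and flagged.
    """
    if len(samples) < 4:
        raise ValueError("need at least 4 samples for a cubic fit")
    z = np.array([s[0] for s in samples], dtype=float)
    d = np.array([s[1] for s in samples], dtype=float)
    if z.min() < -1e-9 or z.max() > thickness + 1e-9:
        raise ValueError("sample depths must lie within the layer thickness")
    poly = Polynomial.fit(z, d, deg=3, domain=[0.0, thickness]).convert()
    zz = np.linspace(0.0, thickness, 2001)
    vals = poly(zz)
    clipped = bool(np.any(vals < -1e-12 * max(1.0, np.abs(vals).max())))
    if clipped:
        warnings.warn("fitted density is negative inside the layer; clipping to 0")
        vals = np.clip(vals, 0.0, None)
        integral = np.trapezoid(vals, zz)  # µm⁻³ · µm = µm⁻²
    else:
        integral = (poly.integ()(thickness) - poly.integ()(0.0))
    target = areal_density / 1e6  # mm⁻² → µm⁻²
    if integral <= 0:
        raise ValueError("fitted density integrates to zero; cannot normalize")
    scale = target / integral
    return DensityProfile(
        poly=poly * scale,
        thickness=thickness,
        areal_density=areal_density,
        clipped=clipped,
    )


def evaluate_selectivity(
    sol: FieldSolution,
    threshold_amplitude: float,
    j_threshold: float,
    cube: CubeCriterion,
    cell_activated: bool = True,
) -> CubeCriterion:
    """Complete the criterion with the suprathreshold volume at threshold.

    ``j_threshold`` is the membrane-side activation current density (A/m²);
    the pair is selective iff the |J| ≥ j_threshold region at the threshold
    amplitude does not exceed the single-cell cube volume *and* the
    mid-placed cell fires at that amplitude.
    """
    vol = suprathreshold_volume(sol, threshold_amplitude, j_threshold)
    selective = cell_activated and vol <= cube.cube_volume
    return replace(
        cube,
        threshold_amplitude=threshold_amplitude,
        suprathreshold_volume_um3=vol,
        cell_activated=cell_activated,
        verdict="selective" if selective else "not-selective",
    )
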
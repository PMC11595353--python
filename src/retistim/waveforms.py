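"""Parametric stimulation current waveforms and their charge integrals.

A waveform is a callable ``i(t)`` returning the instantaneous electrode
current in amperes at time ``t`` (seconds, array-friendly).  Two shapes are
provided:

* a charge-balanced biphasic rectangular pulse (the 2D hexagonal-array
  stimulus), cathodic-first by default, and
* a monophasic linearly decreasing pulse (the 3D linear-carrier stimulus),
  falling from the peak at t = 0 to zero at the phase width.

Charge accounting is per phase: the integral of |i(t)| over one phase
(for the monophasic shape, over the whole pulse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimWaveform",
    "biphasic_rectangular",
    "linear_decrease",
    "charge_per_phase",
]

BIPHASIC_RECTANGULAR = "biphasic-rectangular"
MONOPHASIC_LINEAR_DECREASE = "monophasic-linear-decrease"


@dataclass(frozen=True)
class StimWaveform:
    """A single-pulse stimulation current waveform.

    Parameters
    ----------
    shape:
        ``"biphasic-rectangular"`` or ``"monophasic-linear-decrease"``.
    peak_amplitude:
        Peak current magnitude in amperes (>= 0).
    phase_width:
        Duration of one phase in seconds (> 0).  For the biphasic shape both
        phases have this width; for the monophasic shape it is the whole
        pulse duration.
    frequency:
        Pulse-train repetition rate in Hz (``None`` for a solitary pulse).
    polarity_order:
        ``"cathodic-first"`` (default) or ``"anodic-first"``; the cathodic
        phase is represented with negative sign.
    interphase_gap:
        Zero-current gap between the two phases of a biphasic pulse, in
        seconds.  Defaults to 0 (contiguous phases).
    """

    shape: str
    peak_amplitude: float
    phase_width: float
    frequency: float | None = None
    polarity_order: str = "cathodic-first"
    interphase_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in (BIPHASIC_RECTANGULAR, MONOPHASIC_LINEAR_DECREASE):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.phase_width <= 0:
            raise ValueError("phase_width must be > 0")
        if self.polarity_order not in ("cathodic-first", "anodic-first"):
            raise ValueError(f"unknown polarity order {self.polarity_order!r}")
        if self.interphase_gap < 0:
            raise ValueError("interphase_gap must be >= 0")
        if self.frequency is not None and self.frequency > 0:
            if self.frequency * self.duration > 1.0 + 1e-12:
                raise ValueError(
                    "pulse phases do not fit in one period: "
                    f"f*duration = {self.frequency * self.duration:g} > 1"
                )

    @property
    def duration(self) -> float:
        """Total active pulse duration in seconds."""
        if self.shape == BIPHASIC_RECTANGULAR:
            return 2.0 * self.phase_width + self.interphase_gap
        return self.phase_width

    def __call__(self, t):
        """Signed current in amperes at time ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        i = np.zeros_like(t)
        w = self.phase_width
        if self.shape == BIPHASIC_RECTANGULAR:
            first = -1.0 if self.polarity_order == "cathodic-first" else 1.0
            in1 = (t >= 0) & (t < w)
            in2 = (t >= w + self.interphase_gap) & (t < self.duration)
            i = np.where(in1, first * self.peak_amplitude, i)
            i = np.where(in2, -first * self.peak_amplitude, i)
        else:
            inp = (t >= 0) & (t < w)
            i = np.where(inp, self.peak_amplitude * (1.0 - t / w), i)
        if i.ndim == 0:
            return float(i)
        return i

    def normalized_shape(self, t):
        """Unit-peak signed shape ``i(t)/I_peak`` (zero waveform maps to 0)."""
        if self.peak_amplitude == 0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return self(t) / self.peak_amplitude

    def depolarizing_shape(self, t):
        """Unit-peak shape with the leading phase taken as depolarizing.

        The sign convention linking the extracellular drive to membrane
        depolarization is not fixed by the field solution alone; the model
        convention (documented, switchable by negation) is that the first
        non-zero lobe of the pulse depolarizes the cell.
        """
        s = self.normalized_shape(t)
        if self.shape == BIPHASIC_RECTANGULAR and self.polarity_order == "cathodic-first":
            return -s
        return s

    def with_amplitude(self, peak_amplitude: float) -> "StimWaveform":
        """Same pulse shape at a different peak amplitude."""
        return StimWaveform(
            shape=self.shape,
            peak_amplitude=peak_amplitude,
            phase_width=self.phase_width,
            frequency=self.frequency,
            polarity_order=self.polarity_order,
            interphase_gap=self.interphase_gap,
        )

    def sample(self, dt: float):
        """Two-column (t [s], i [A]) sampling of one pulse for export."""
        t = np.arange(0.0, self.duration + dt, dt)
        return np.column_stack([t, self(t)])


def biphasic_rectangular(
    current: float,
    phase_width: float,
    frequency: float | None = None,
    polarity_order: str = "cathodic-first",
    interphase_gap: float = 0.0,
) -> StimWaveform:
    """Charge-balanced biphasic rectangular pulse.

    Two equal-magnitude, opposite-sign phases of width ``phase_width`` each;
    net charge over the pulse is zero by construction.
    """
    return StimWaveform(
        shape=BIPHASIC_RECTANGULAR,
        peak_amplitude=current,
        phase_width=phase_width,
        frequency=frequency,
        polarity_order=polarity_order,
        interphase_gap=interphase_gap,
    )


def linear_decrease(peak_current: float, width: float) -> StimWaveform:
    """Monophasic pulse falling linearly from ``peak_current`` to 0 over ``width``."""
    return StimWaveform(
        shape=MONOPHASIC_LINEAR_DECREASE,
        peak_amplitude=peak_current,
        phase_width=width,
    )


def charge_per_phase(wf: StimWaveform) -> float:
    """Charge delivered in one phase, in coulombs.

    Integral of |i(t)| over one phase: ``I*w`` for the rectangular phase,
    ``I*w/2`` for the triangular monophasic pulse.
    """
    if wf.shape == BIPHASIC_RECTANGULAR:
        return wf.peak_amplitude * wf.phase_width
    return 0.5 * wf.peak_amplitude * wf.phase_width
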
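"""Retinal ganglion cell membrane model: equilibrium, excitation, thresholds."""

import numpy as np
import pytest
from scipy.optimize import brentq

import retistim as rs
from retistim import membrane
from retistim.fieldsolver import BoundaryDrive
from retistim.membrane import (
    MembraneError,
    MembraneTrace,
    detect_activation,
    simulate,
    threshold_density,
    threshold_search,
)


def _drive(params, rest, jc_peak, wf, duration=12e-3, dt=2e-6):
    bd = BoundaryDrive(jc_unit=1.0, waveform=wf.with_amplitude(jc_peak))
    return simulate(params, rest, bd, duration=duration, dt=dt, v_rest=rest.v)


class TestRestingState:
    def test_rest_is_a_fixed_point_over_50ms(self, params, rest):
        bd = BoundaryDrive(jc_unit=1.0, waveform=rs.linear_decrease(0.0, 100e-6))
        trace = simulate(params, rest, bd, duration=50e-3, dt=5e-6, v_rest=rest.v)
        assert np.max(np.abs(trace.v - rest.v)) < 0.1

    def test_gates_equal_steady_state_values(self, params, rest):
        inf = params.steady_gates(rest.v)
        for val, key in zip(rest.gates, ("m", "h", "c", "n", "a", "ha")):
            assert val == pytest.approx(inf[key], abs=1e-4)

    def test_rest_matches_algebraic_root_solve(self, params, rest):
        """Independent oracle: V where the total steady-state ionic current is 0."""

        def steady_ca(v):
            ca = params.ca_resting
            kca = 3.0 / (2.0 * membrane.FARADAY * params.shell_radius * 1e-6) * 1e-5
            for _ in range(50):
                c = params.steady_gates(v)["c"]
                i_ca = params.g_ca * c ** 3 * (v - params.e_ca(ca))
                ca = params.ca_resting - params.ca_tau * kca * i_ca
            return ca

        def net_current(v):
            return params.ionic_current(v, params.steady_gates(v), steady_ca(v))

        # bracket around the stable equilibrium (the depolarized sign change
        # near −52 mV is the unstable firing threshold, not the rest point)
        v_root = brentq(net_current, -80.0, -60.0, xtol=1e-10)
        assert rest.v == pytest.approx(v_root, abs=0.05)


class TestSimulate:
    def test_suprathreshold_drive_elicits_action_potential(self, params, rest):
        """The published carrier-scene operating point (cell-boundary 3.1 A/m²,
        100 µs linear decrease) fires the cell."""
        trace = _drive(params, rest, 3.1, rs.linear_decrease(1.0, 100e-6))
        assert detect_activation(trace)
        assert trace.peak_v > 0.0  # overshooting spike, not a passive bump

    def test_subthreshold_drive_stays_passive(self, params, rest):
        trace = _drive(params, rest, 1.0, rs.linear_decrease(1.0, 100e-6))
        assert not detect_activation(trace)
        assert trace.peak_shift < 10.0

    def test_peak_converges_under_step_halving(self, params, rest):
        wf = rs.linear_decrease(1.0, 100e-6)
        peaks = [
            _drive(params, rest, 3.1, wf, dt=dt).peak_v for dt in (4e-6, 2e-6, 1e-6)
        ]
        assert abs(peaks[2] - peaks[1]) < 0.5
        assert abs(peaks[2] - peaks[1]) <= abs(peaks[1] - peaks[0]) + 0.05

    def test_gating_variables_and_calcium_stay_physical(self, params, rest):
        """Gates remain in [0,1] and [Ca] positive through a strong spike."""
        bd = BoundaryDrive(jc_unit=1.0, waveform=rs.linear_decrease(6.0, 100e-6))
        rhs = membrane._rhs(params)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(rhs, (0.0, 12.0), rest.as_vector(),
                        args=(lambda t_ms: 100.0 * float(bd.series(t_ms * 1e-3)),),
                        method="LSODA", rtol=1e-8, atol=1e-9, max_step=0.002)
        gates = sol.y[1:7]
        assert gates.min() >= -1e-6 and gates.max() <= 1.0 + 1e-6
        assert sol.y[7].min() > 0.0

    def test_membrane_recovers_within_10ms_after_pulse(self, params, rest, jstar_linear):
        """10 ms after a pulse at twice threshold the membrane is back near
        rest (within the model's few-mV afterhyperpolarization) and a second
        identical pulse still fires — the independence assumption that lets
        separately pulsed electrode pairs combine as a geometric union at a
        100 Hz train rate."""
        wf = rs.linear_decrease(1.0, 100e-6).with_amplitude(2 * jstar_linear)

        def two_pulses(t):
            t = np.asarray(t, dtype=float)
            return wf(t) + wf(t - 10e-3)

        trace = simulate(params, rest, two_pulses, duration=22e-3, dt=2e-6,
                         drive_end=10.1e-3, v_rest=rest.v)
        near_10ms = trace.v[(trace.t >= 9.9e-3) & (trace.t <= 10.0e-3)]
        assert np.all(np.abs(near_10ms - rest.v) < 5.0)
        # both pulses elicit full spikes: two separate +30 mV crossings
        above = (trace.v - rest.v) >= 30.0
        crossings = np.nonzero(np.diff(above.astype(int)) == 1)[0]
        assert len(crossings) == 2
        assert trace.t[crossings[1]] > 10e-3

    def test_instability_guard_raises(self, params, rest):
        with pytest.raises(MembraneError, match="500 mV|blow-up"):
            _drive(params, rest, 500.0, rs.linear_decrease(1.0, 100e-6))

    def test_dt_must_resolve_waveform(self, params, rest):
        bd = BoundaryDrive(jc_unit=1.0, waveform=rs.linear_decrease(1.0, 100e-6))
        with pytest.raises(ValueError, match="dt"):
            simulate(params, rest, bd, duration=12e-3, dt=50e-6)


class TestDetectActivation:
    def _trace(self, t, v, v_rest=-65.0, drive_end=100e-6):
        return MembraneTrace(t=t, v=v, drive=np.zeros_like(t), v_rest=v_rest,
                             drive_end=drive_end)

    def test_flat_trace_is_silent(self):
        t = np.linspace(0, 12e-3, 500)
        assert not detect_activation(self._trace(t, np.full_like(t, -65.0)))

    def test_35mv_excursion_detected(self):
        t = np.linspace(0, 12e-3, 500)
        v = np.full_like(t, -65.0)
        v[100] = -30.0
        assert detect_activation(self._trace(t, v))

    def test_exactly_30mv_is_inclusive(self):
        t = np.linspace(0, 12e-3, 500)
        v = np.full_like(t, -65.0)
        v[100] = -35.0
        assert detect_activation(self._trace(t, v))

    def test_truncated_trace_rejected(self):
        t = np.linspace(0, 5e-3, 100)
        with pytest.raises(MembraneError, match="10 ms"):
            detect_activation(self._trace(t, np.full_like(t, -65.0)))


class TestThresholdSearch:
    def test_incremental_equals_bisection_within_step(self, params, rest, jstar_linear):
        wf = rs.linear_decrease(1.0, 100e-6)
        di = 0.25
        thr = threshold_search(params, 1.0, wf, i_start=di, di=di, rest=rest)
        assert thr - di < jstar_linear <= thr + 1e-9

    def test_already_active_start_returns_start(self, params, rest, jstar_linear):
        wf = rs.linear_decrease(1.0, 100e-6)
        start = 2 * jstar_linear
        assert threshold_search(params, 1.0, wf, i_start=start, di=0.5,
                                rest=rest) == start

    def test_cap_without_activation_raises(self, params, rest):
        wf = rs.linear_decrease(1.0, 100e-6)
        with pytest.raises(MembraneError, match="cap"):
            threshold_search(params, 1.0, wf, i_start=0.1, di=0.1, i_cap=0.5,
                             rest=rest)

    def test_threshold_grows_with_electrode_cell_distance(self, params, rest):
        """Monopole coupling at increasing separations: the amplitude needed
        for activation is non-decreasing with distance."""
        wf = rs.linear_decrease(1.0, 100e-6)
        # inverse-square couplings at three separations (A/m² per A)
        field = lambda r: 1.0 / (4 * np.pi * (r * 1e-6) ** 2)
        thresholds = [
            threshold_search(params, field(r), wf, i_start=2e-9, di=2e-9,
                             i_cap=100e-9, rest=rest)
            for r in (15.0, 25.0, 40.0)
        ]
        assert thresholds == sorted(thresholds)
        assert thresholds[2] > thresholds[0]

    def test_strength_duration_monotone(self, params, rest):
        """Longer pulses need lower peak current density (50–500 µs)."""
        thr = [
            threshold_density(params, rs.linear_decrease(1.0, w), tol=0.02, rest=rest)
            for w in (50e-6, 100e-6, 200e-6, 500e-6)
        ]
        assert all(a > b for a, b in zip(thr, thr[1:]))
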
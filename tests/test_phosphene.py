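"""Boundary tracer, percept composition, and activation-predicate checks."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from retistim import fixtures, phosphene
from retistim.phosphene import (
    Percept,
    SearchConfig,
    estimate_cell_count,
    mirror_asymmetry,
    trace_boundary,
)

CFG = SearchConfig()


def grid_scan_radii(predicate, center, angles, r_max=300.0, step=1.0):
    """Brute-force oracle: outer/inner transition radii at 1 µm resolution."""
    out = []
    for a in angles:
        ca, sa = math.cos(a), math.sin(a)
        rr = np.arange(0.0, r_max, step)
        on = np.array([bool(predicate(center[0] + r * ca, center[1] + r * sa))
                       for r in rr])
        trans = np.nonzero(np.diff(on.astype(int)))[0]
        out.append([(rr[i] + rr[i + 1]) / 2.0 for i in trans])
    return out


class TestTraceBoundaryAgainstGridOracle:
    def test_disc_predicate(self):
        pred = fixtures.make_analytic_field("radial-predicate", r_outer=80.0)
        b = trace_boundary(lambda x, y: pred(x, y), (0.0, 0.0), CFG)
        assert b is not None and b.inner is None
        radii = np.linalg.norm(b.outer, axis=1)
        angles = [2 * math.pi * k / CFG.rays for k in range(CFG.rays)]
        oracle = grid_scan_radii(pred, (0.0, 0.0), angles)
        for r, trans in zip(radii, oracle):
            assert len(trans) == 1
            assert abs(r - trans[0]) <= CFG.tol + 0.5  # tracer tol + oracle grid
        # all vertices within one tolerance of the true radius
        assert np.all(np.abs(radii - 80.0) <= CFG.tol)
        # polygon area equals the inscribed 16-gon closed form, i.e. the
        # disc area times (n/2π)·sin(2π/n)
        ngon = 0.5 * CFG.rays * 80.0 ** 2 * math.sin(2 * math.pi / CFG.rays)
        assert b.area == pytest.approx(ngon, rel=5e-3)
        assert b.area == pytest.approx(math.pi * 80.0 ** 2, rel=0.03)

    def test_ring_predicate(self):
        pred = fixtures.make_analytic_field("radial-predicate", r_outer=80.0,
                                            r_inner=40.0)
        b = trace_boundary(lambda x, y: pred(x, y), (0.0, 0.0), CFG)
        assert b is not None and b.inner is not None
        r_out = np.linalg.norm(b.outer, axis=1)
        r_in = np.linalg.norm(b.inner, axis=1)
        assert np.all(np.abs(r_out - 80.0) <= CFG.tol)
        assert np.all(np.abs(r_in - 40.0) <= CFG.tol)
        # enclosed area excludes the hole
        ngon = lambda r: 0.5 * CFG.rays * r * r * math.sin(2 * math.pi / CFG.rays)
        assert b.area == pytest.approx(ngon(80.0) - ngon(40.0), rel=0.01)

    def test_always_false_predicate_signals_no_stimulation(self):
        assert trace_boundary(lambda x, y: False, (0.0, 0.0), CFG) is None

    def test_offset_disc(self):
        pred = fixtures.make_analytic_field("radial-predicate", r_outer=50.0,
                                            center=(200.0, -100.0))
        b = trace_boundary(lambda x, y: pred(x, y), (200.0, -100.0), CFG)
        radii = np.linalg.norm(b.outer - np.array([200.0, -100.0]), axis=1)
        assert np.all(np.abs(radii - 50.0) <= CFG.tol)


class _FakeScene:
    """Scene protocol stub driven by an analytic activation predicate."""

    def __init__(self, pred_for_amp, amplitude=13e-6):
        import retistim as rs

        self.pred_for_amp = pred_for_amp
        self.waveform = rs.biphasic_rectangular(amplitude, 94e-6, 100.0)
        self.pairs = [(0, 1)]

    def solve_pair(self, pair):
        return None

    def active_center_xy(self, pair):
        return (0.0, 0.0)

    def cell_at(self, x, y):
        raise NotImplementedError


def test_current_escalation_recovers_a_percept(monkeypatch):
    """When nothing activates at the base amplitude, the injected current is
    raised stepwise (factor 2, cap 4×) until a percept appears."""
    def fake_predicate(scene, sol, amplitude, jc_threshold):
        radius = 60.0 if amplitude >= 2 * 13e-6 else -1.0
        return lambda x, y: math.hypot(x, y) <= radius

    monkeypatch.setattr(phosphene, "activation_predicate", fake_predicate)
    scene = _FakeScene(None)
    b = phosphene.trace_pair_boundary(scene, (0, 1), params=None, cfg=CFG,
                                      jc_threshold=1.0)
    assert b is not None
    assert "26" in b.stimulus  # escalated to 2× the 13 µA base
    radii = np.linalg.norm(b.outer, axis=1)
    assert np.all(np.abs(radii - 60.0) <= CFG.tol)


def test_escalation_cap_gives_no_stimulation(monkeypatch):
    monkeypatch.setattr(phosphene, "activation_predicate",
                        lambda *a: (lambda x, y: False))
    scene = _FakeScene(None)
    assert phosphene.trace_pair_boundary(scene, (0, 1), params=None, cfg=CFG,
                                         jc_threshold=1.0) is None


class TestComposePercept:
    def _boundary(self, center, r=80.0):
        pred = fixtures.make_analytic_field("radial-predicate", r_outer=r,
                                            center=center)
        return trace_boundary(lambda x, y: pred(x, y), center,
                              SearchConfig(rays=32))

    def _percept(self, boundaries):
        from shapely.ops import unary_union

        geom = unary_union([b.polygon for b in boundaries])
        return Percept(boundaries=boundaries, geometry=geom,
                       union_area=geom.area,
                       shape_class=phosphene._classify(geom, boundaries))

    def test_single_pair_percept_equals_its_boundary(self):
        b = self._boundary((0.0, 0.0))
        p = self._percept([b])
        assert p.union_area == pytest.approx(b.area)
        assert p.component_count == 1
        assert p.shape_class == "dot"

    def test_disjoint_pairs_sum_their_areas(self):
        b1 = self._boundary((0.0, 0.0))
        b2 = self._boundary((500.0, 0.0))
        p = self._percept([b1, b2])
        assert p.component_count == 2
        assert p.shape_class == "composite"
        assert p.union_area == pytest.approx(b1.area + b2.area, rel=1e-9)

    def test_overlapping_discs_match_lens_closed_form(self):
        """Two r=80 discs with centres 80 apart: union area from the
        circle-circle lens formula."""
        r, d = 80.0, 80.0
        b1 = self._boundary((0.0, 0.0), r)
        b2 = self._boundary((d, 0.0), r)
        p = self._percept([b1, b2])
        lens = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)
        exact = 2 * math.pi * r * r - lens
        assert p.union_area == pytest.approx(exact, rel=0.02)

    def test_union_never_exceeds_component_sum(self):
        b1 = self._boundary((0.0, 0.0))
        b2 = self._boundary((60.0, 0.0))
        p = self._percept([b1, b2])
        assert p.union_area <= b1.area + b2.area


class TestCellCount:
    def _square_percept(self, side_um):
        poly = Polygon([(0, 0), (side_um, 0), (side_um, side_um), (0, side_um)])
        return Percept(boundaries=[], geometry=poly, union_area=poly.area,
                       shape_class="dot")

    def test_area_density_product(self):
        stack = fixtures.table1_stack()  # 31,300 mm⁻²
        p = self._square_percept(100.0)  # 0.01 mm²
        assert estimate_cell_count(p, stack) == 313

    def test_empty_percept_has_no_cells(self):
        stack = fixtures.table1_stack()
        p = Percept(boundaries=[], geometry=Polygon(), union_area=0.0,
                    shape_class="none")
        assert estimate_cell_count(p, stack) == 0

    def test_count_monotone_in_area(self):
        stack = fixtures.table1_stack()
        counts = [estimate_cell_count(self._square_percept(s), stack)
                  for s in (50.0, 100.0, 200.0)]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]


class TestAsymmetryMetric:
    def test_symmetric_polygon_scores_zero(self):
        disc = Point(0, 0).buffer(80.0, quad_segs=64)
        assert mirror_asymmetry(disc, axis="x", origin=0.0) < 1e-9

    def test_shifted_polygon_scores_positive(self):
        disc = Point(40.0, 0).buffer(80.0, quad_segs=64)
        assert mirror_asymmetry(disc, axis="x", origin=0.0) > 0.2


def test_shape_classification():
    from shapely.ops import unary_union

    dot = Point(0, 0).buffer(50.0)
    ring = Point(0, 0).buffer(80.0).difference(Point(0, 0).buffer(40.0))
    bar = Polygon([(0, 0), (300, 0), (300, 60), (0, 60)])
    two = unary_union([Point(0, 0).buffer(50.0), Point(500, 0).buffer(50.0)])
    assert phosphene._classify(dot, []) == "dot"
    assert phosphene._classify(ring, []) == "ring"
    assert phosphene._classify(bar, []) == "elongated"
    assert phosphene._classify(two, []) == "composite"
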
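"""Traction rules of the boundary force actuators."""

import numpy as np
import pytest

import morphofem as mf
from morphofem.actuators import (Actuator, ConfigurationError,
                                 line_tension_traction,
                                 neg_surface_tension_traction,
                                 normal_pressure_traction,
                                 shear_pair_traction,
                                 tension_gradient_traction)
from morphofem.geometry import CurvatureField, _chain_curvature
from morphofem.mechanics import traction_loads


def field_from_polyline(pts, closed):
    kap, nor, tan, s, end = _chain_curvature(np.asarray(pts, float), closed)
    n = len(pts)
    return CurvatureField(np.arange(n), kap, nor, tan, s, end,
                          [(slice(0, n), closed)])


def circle_field(r, n):
    th = 2 * np.pi * np.arange(n) / n
    return field_from_polyline(np.column_stack([r * np.cos(th),
                                                r * np.sin(th)]), True)


def hstrip_field(n=11, length=1.0):
    pts = np.column_stack([np.linspace(0, length, n), np.zeros(n)])
    return field_from_polyline(pts, False)


# --------------------------------------------------------------------------
# line tension
# --------------------------------------------------------------------------


def test_laplace_traction_on_circle_is_t_over_r_inward():
    curv = circle_field(0.5, 64)
    tr = line_tension_traction(curv, 1.0)
    mags = np.linalg.norm(tr, axis=1)
    assert np.allclose(mags, 2.0, rtol=0.02)          # T/R = 1/0.5
    # inward: anti-parallel to the outward normal
    assert np.allclose((tr * curv.normal).sum(1), -mags, rtol=1e-9)
    assert np.allclose(line_tension_traction(curv, 0.0), 0.0)


def test_laplace_traction_vanishes_on_straight_segment():
    tr = line_tension_traction(hstrip_field(), 1.0)
    assert np.allclose(tr, 0.0, atol=1e-12)


def test_laplace_traction_self_equilibrated_on_closed_contour():
    m = mf.build_annulus(1.0, 0.3, 0.05)
    act = Actuator("line_tension", "hole", {"T": 1.0})
    F = traction_loads(m, act.evaluate(m))
    total = F.sum(axis=0)
    scale = np.abs(F).sum()
    assert np.linalg.norm(total) / scale < 1e-6


# --------------------------------------------------------------------------
# pressure
# --------------------------------------------------------------------------


def test_pressure_traction_is_unit_inward_and_total_force_tracks_perimeter():
    curv = circle_field(0.5, 64)
    tr = normal_pressure_traction(curv, 1.0)
    assert np.allclose(np.linalg.norm(tr, axis=1), 1.0)
    assert np.allclose((tr * curv.normal).sum(1), -1.0)
    for r in (0.5, 0.25):
        m = mf.build_annulus(1.0, r, 0.05)
        act = Actuator("normal_pressure", "hole", {"P": 1.0})
        F = traction_loads(m, act.evaluate(m))
        total_mag = np.linalg.norm(F, axis=1).sum()
        assert total_mag == pytest.approx(2 * np.pi * r, rel=0.01)


def test_pressure_closes_a_hole_rim():
    """On a hole loop (total turning -2 pi) positive pressure must point
    into the void, i.e. along the domain-outward normal."""
    m = mf.build_annulus(1.0, 0.4, 0.08)
    curv = mf.boundary_curvature(m, "hole")
    tr = normal_pressure_traction(curv, 1.0)
    pts = m.vertices[curv.indices]
    rhat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    assert np.all((tr * rhat).sum(1) < 0)      # toward the hole center


def test_pressure_corner_normal_is_half_angle_bisector():
    sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    # refine each side so corners are genuine corner vertices
    pts = []
    for i in range(4):
        seg = np.linspace(sq[i], sq[(i + 1) % 4], 5)[:-1]
        pts.extend(seg)
    curv = field_from_polyline(np.asarray(pts), True)
    tr = normal_pressure_traction(curv, 1.0)
    corner = tr[0]          # vertex (0,0): bisector points inward (+1,+1)
    expect = np.array([1.0, 1.0]) / np.sqrt(2)
    assert np.allclose(corner, expect, atol=1e-9)


# --------------------------------------------------------------------------
# shear pairs
# --------------------------------------------------------------------------


def test_shear_pair_halves_point_at_each_other():
    curv = hstrip_field(21)
    tr = shear_pair_traction(curv, 1.0)
    s_mid = 0.5
    left = curv.s < s_mid - 1e-9
    right = curv.s > s_mid + 1e-9
    assert np.allclose(tr[left], [1.0, 0.0])
    assert np.allclose(tr[right], [-1.0, 0.0])
    assert np.allclose(shear_pair_traction(curv, 0.0), 0.0)


def test_shear_pair_asymmetry_scales_second_half_and_breaks_balance():
    curv = hstrip_field(21)
    tr = shear_pair_traction(curv, 1.0, asymmetry=0.5)
    assert np.allclose(np.abs(tr[curv.s < 0.5 - 1e-9][:, 0]), 1.0)
    assert np.allclose(np.abs(tr[curv.s > 0.5 + 1e-9][:, 0]), 0.5)
    # net tangential force: edge-lumped sum is nonzero
    seg = np.diff(curv.s)
    w = np.zeros_like(curv.s)
    w[:-1] += 0.5 * seg
    w[1:] += 0.5 * seg
    net = (tr[:, 0] * w).sum()
    assert net > 0.1
    balanced = shear_pair_traction(curv, 1.0, asymmetry=1.0)
    assert abs((balanced[:, 0] * w).sum()) < 1e-12


def test_extend_sense_negates_contract_exactly():
    curv = hstrip_field(16)
    a = shear_pair_traction(curv, 2.0, 0.7, "contract")
    b = shear_pair_traction(curv, 2.0, 0.7, "extend")
    assert np.array_equal(a, -b)


def test_shear_pair_needs_four_vertices():
    with pytest.raises(ConfigurationError):
        shear_pair_traction(hstrip_field(3), 1.0)


# --------------------------------------------------------------------------
# tension gradient
# --------------------------------------------------------------------------


def test_tension_gradient_points_toward_direction():
    pts = np.column_stack([np.zeros(9), np.linspace(0, 1, 9)])
    curv = field_from_polyline(pts, False)
    tr = tension_gradient_traction(curv, 0.7, (0.0, 1.0))
    assert np.allclose(tr, [0.0, 0.7])
    assert np.allclose(tension_gradient_traction(curv, 0.0, (0, 1)), 0.0)
    with pytest.raises(ConfigurationError):
        tension_gradient_traction(curv, 1.0, (0.0, 0.0))


def test_tension_gradient_advects_contour_centroid_dorsally(gradient_run,
                                                            crenel_runs):
    """Over a run, the gradient pulls the ear territory toward the median
    axis: its centroid ends higher than the no-gradient control."""
    with_g = gradient_run.trace.observables["ear_centroid_y"][-1]
    control = crenel_runs[0.06].trace.observables["ear_centroid_y"][-1]
    assert with_g > control


# --------------------------------------------------------------------------
# negative surface tension
# --------------------------------------------------------------------------


def test_growth_traction_magnitudes_and_flat_clamp():
    curv = circle_field(0.5, 64)
    t1 = neg_surface_tension_traction(curv, 1.0, 1)
    t2 = neg_surface_tension_traction(curv, 1.0, 2)
    assert np.allclose(np.linalg.norm(t1, axis=1), 2.0, rtol=0.02)
    assert np.allclose(np.linalg.norm(t2, axis=1), 4.0, rtol=0.04)
    # outward
    assert np.all((t1 * curv.normal).sum(1) > 0)
    flat = hstrip_field()
    assert np.allclose(neg_surface_tension_traction(flat, 1.0, 1), 0.0,
                       atol=1e-12)
    assert np.allclose(neg_surface_tension_traction(flat, 1.0, 2), 0.0,
                       atol=1e-12)
    with pytest.raises(ConfigurationError):
        neg_surface_tension_traction(curv, 1.0, 3)


def test_quadratic_growth_tip_ratio_scales_as_curvature_squared():
    big = circle_field(1.0, 128)
    small = circle_field(0.5, 128)
    tb = np.linalg.norm(neg_surface_tension_traction(big, 1.0, 2), axis=1)
    ts = np.linalg.norm(neg_surface_tension_traction(small, 1.0, 2), axis=1)
    assert ts.mean() / tb.mean() == pytest.approx(4.0, rel=1e-6)


def test_concave_clamp_on_hole_rim():
    m = mf.build_annulus(1.0, 0.4, 0.08)
    curv = mf.boundary_curvature(m, "hole")     # kappa < 0 everywhere
    clamped = neg_surface_tension_traction(curv, 1.0, 1, clamp_concave=True)
    assert np.allclose(clamped, 0.0)
    free = neg_surface_tension_traction(curv, 1.0, 1, clamp_concave=False)
    assert np.abs(free).max() > 0


# --------------------------------------------------------------------------
# declarative layer
# --------------------------------------------------------------------------


def test_missing_label_is_configuration_error():
    m = mf.build_body(1.0, 1.0, [], 0.0, 0.2)
    act = Actuator("line_tension", "no_such_edge", {"T": 1.0})
    with pytest.raises(ConfigurationError):
        act.evaluate(m)
    with pytest.raises(ConfigurationError):
        Actuator("warp_drive", "mouth", {})


def test_actuator_round_trips_through_dict():
    act = Actuator("tension_gradient", "ear_crenel",
                   {"strength": 0.15, "direction": [0.0, 1.0]})
    assert Actuator.from_dict(act.to_dict()) == act
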
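"""Mesh builders, discrete curvature and remeshing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

import morphofem as mf
from morphofem.geometry import (Chain, ParameterError, SelfIntersectionError,
                                TriMesh, _chain_curvature,
                                triangulate_polygon)


def circle_points(radius, n, center=(0.0, 0.0)):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


# --------------------------------------------------------------------------
# annulus
# --------------------------------------------------------------------------


def test_annulus_measures_match_closed_forms():
    m = mf.build_annulus(1.0, 0.3, 0.05)
    m.validate()
    assert m.perimeter("hole") == pytest.approx(2 * np.pi * 0.3, rel=0.01)
    assert m.perimeter("outer") == pytest.approx(2 * np.pi, rel=0.01)
    assert m.area() == pytest.approx(np.pi * (1 - 0.09), rel=0.01)
    hole = m.chains_for("hole")[0]
    assert len(hole.vertices) >= 16


@pytest.mark.parametrize("outer,hole,h", [
    (1.0, 0.999, 0.05),       # annular gap thinner than one element
    (1.0, 1.2, 0.05),         # hole larger than the disc
    (1.0, 0.3, 0.4),          # elements coarser than the hole
    (1.0, -0.1, 0.05),
])
def test_annulus_rejects_degenerate_parameters(outer, hole, h):
    with pytest.raises(ParameterError):
        mf.build_annulus(outer, hole, h)


# --------------------------------------------------------------------------
# body
# --------------------------------------------------------------------------


def test_plain_rectangle_labels_and_area():
    m = mf.build_body(2.0, 1.0, [], 0.0, 0.05)
    m.validate()
    assert set(m.labels) == {"mouth", "neck", "dorsal", "ventral"}
    assert m.area() == pytest.approx(2.0, rel=0.01)
    assert m.boundary_polygon().length == pytest.approx(6.0, abs=1e-9)


def test_crenel_outline_matches_polygon_oracle():
    """The generated boundary must equal the constructed outline polygon:
    a crenel protruding from the dorsal line adds exactly its two vertical
    sides to the rectangle perimeter."""
    w, d = 0.3, 0.2
    m = mf.build_body(2.0, 1.0, [mf.PlacodeSpec(1.0, w, d)], 0.0, 0.05)
    m.validate()
    oracle = Polygon([(0, 0), (2, 0), (2, 1), (1.15, 1), (1.15, 1.2),
                      (0.85, 1.2), (0.85, 1), (0, 1)])
    assert m.boundary_polygon().length == pytest.approx(oracle.length,
                                                        abs=1e-9)
    assert m.boundary_polygon().length == pytest.approx(6.0 + 2 * d,
                                                        abs=1e-9)
    assert m.area() == pytest.approx(oracle.area, rel=1e-9)
    # the placode interior carries its own material tag
    assert set(np.unique(m.tri_tags)) == {0, 1}
    assert m.chain_length("ear_base") == pytest.approx(w, abs=1e-12)


def test_trapeze_placode_and_absent_tissue():
    t = mf.build_body(2.0, 1.0,
                      [mf.PlacodeSpec(1.0, 0.4, 0.2, shape="trapeze")],
                      0.0, 0.05)
    t.validate()
    assert (t.tri_tags == 1).any()
    gone = mf.build_body(2.0, 1.0,
                         [mf.PlacodeSpec(1.0, 0.4, 0.2, softness=0.0)],
                         0.0, 0.05)
    gone.validate()
    assert set(np.unique(gone.tri_tags)) == {0}
    assert gone.area() == pytest.approx(2.0, rel=0.01)
    # footprint stays addressable as external boundary
    assert gone.chain_length("ear_base") == pytest.approx(0.4, abs=1e-12)
    assert not gone.chains_for("ear_base")[0].internal


def test_overlapping_placodes_rejected():
    with pytest.raises(ParameterError):
        mf.build_body(2.0, 1.0, [mf.PlacodeSpec(1.0, 0.4, 0.2),
                                 mf.PlacodeSpec(1.2, 0.4, 0.2)], 0.0, 0.05)


def test_corner_smoothing_curvature_is_arc_curvature():
    rc = 0.1
    m = mf.build_body(2.0, 1.0, [], rc, 0.04)
    m.validate()
    curv = mf.boundary_curvature(m, "all-external")
    assert curv.kappa.max() == pytest.approx(1.0 / rc, rel=0.10)


# --------------------------------------------------------------------------
# curvature
# --------------------------------------------------------------------------


def test_circle_curvature_and_frames():
    m = mf.build_annulus(1.0, 0.5, 0.049)
    curv = mf.boundary_curvature(m, "outer")
    # disc-like convex outer rim: kappa = +1/R
    assert np.allclose(curv.kappa, 1.0, rtol=0.02)
    # frames: unit, orthogonal, outward
    assert np.allclose(np.linalg.norm(curv.normal, axis=1), 1.0)
    assert np.allclose(np.linalg.norm(curv.tangent, axis=1), 1.0)
    assert np.allclose((curv.normal * curv.tangent).sum(1), 0.0, atol=1e-12)
    pts = m.vertices[curv.indices]
    rhat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    assert np.allclose((curv.normal * rhat).sum(1), 1.0, atol=1e-3)
    # hole rim of the same mesh is concave seen from the material
    hole = mf.boundary_curvature(m, "hole")
    assert np.allclose(hole.kappa, -2.0, rtol=0.02)


def test_straight_chain_curvature_zero():
    pts = np.column_stack([np.linspace(0, 1, 11), np.zeros(11)])
    kap, nor, tan, s, end = _chain_curvature(pts, closed=False)
    assert np.allclose(kap, 0.0, atol=1e-12)
    assert end[0] and end[-1] and not end[1:-1].any()
    assert s[-1] == pytest.approx(1.0)


def test_ellipse_tip_curvature_matches_analytic():
    # analytic curvature of x^2/a^2 + y^2/b^2 = 1 at (+-a, 0) is a/b^2
    a, b, n = 1.0, 0.5, 256
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    kap, *_ = _chain_curvature(pts, closed=True)
    assert kap[0] == pytest.approx(a / b**2, rel=0.03)
    assert kap[n // 2] == pytest.approx(a / b**2, rel=0.03)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(r=st.floats(0.2, 5.0), n=st.integers(32, 200))
def test_sampled_circle_curvature_property(r, n):
    kap, *_ = _chain_curvature(circle_points(r, n), closed=True)
    assert np.allclose(kap, 1.0 / r, rtol=0.01)


def test_gauss_bonnet_on_closed_convex_boundary():
    m = mf.build_body(2.0, 1.0, [], 0.1, 0.04)
    curv = mf.boundary_curvature(m, "all-external")
    pts = m.vertices[curv.indices]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    ds = 0.5 * (seg + np.roll(seg, 1))
    assert float(np.sum(curv.kappa * ds)) == pytest.approx(2 * np.pi,
                                                           rel=0.02)


# --------------------------------------------------------------------------
# remeshing
# --------------------------------------------------------------------------


def test_remesh_noop_on_good_mesh():
    m = mf.build_annulus(1.0, 0.3, 0.06)
    assert mf.remesh_if_needed(m, 0.2) is m


def test_remesh_restores_quality_and_preserves_boundary():
    m = mf.build_body(1.0, 1.0, [], 0.0, 0.1)
    # squeeze the interior into slivers without touching the boundary
    bnd = np.unique(m.boundary_edges())
    interior = np.setdiff1d(np.arange(len(m.vertices)), bnd)
    m.vertices[interior, 1] *= 0.15
    m.vertices[interior, 1] += 0.02 * m.vertices[interior, 0]
    assert m.min_quality() < 0.2
    area_before = abs(m.boundary_polygon().area)
    bnd_pts = np.sort(m.vertices[bnd].view("f8,f8"), axis=0)
    out = mf.remesh_if_needed(m, 0.2)
    assert out.min_quality() >= 0.2
    out.validate()
    bnd2 = np.unique(out.boundary_edges())
    bnd2_pts = np.sort(out.vertices[bnd2].view("f8,f8"), axis=0)
    assert np.array_equal(bnd_pts, bnd2_pts)   # boundary vertices exact
    assert abs(out.area() - area_before) / area_before < 0.005


def test_remesh_reassigns_region_tags():
    m = mf.build_body(2.0, 1.0, [mf.PlacodeSpec(1.0, 0.3, 0.3)], 0.0, 0.06)
    area1 = float(np.abs(m.signed_areas()[m.tri_tags == 1]).sum())
    bnd = np.unique(m.boundary_edges())
    chained = np.unique(np.concatenate([c.vertices for c in m.chains]))
    interior = np.setdiff1d(np.arange(len(m.vertices)),
                            np.union1d(bnd, chained))
    m.vertices[interior] += 0.022 * np.sin(7.0 * m.vertices[interior])
    out = mf.remesh_if_needed(m, max(0.95 * m.min_quality(), 0.3))
    assert out is not m
    area2 = float(np.abs(out.signed_areas()[out.tri_tags == 1]).sum())
    assert area2 == pytest.approx(area1, rel=0.02)


def test_bowtie_boundary_raises_self_intersection():
    bow = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    with pytest.raises(SelfIntersectionError) as err:
        triangulate_polygon([(bow, ["x"] * 4)], [], 0.2)
    assert err.value.segment_a is not None


def test_validate_catches_double_label():
    m = mf.build_body(1.0, 1.0, [], 0.0, 0.2)
    m.chains.append(Chain("extra", m.chains_for("mouth")[0].vertices.copy()))
    with pytest.raises(ValueError, match="labeled twice"):
        m.validate()
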
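"""Triangulated 2D domains with labeled boundaries.

The simulator works on a Lagrangian triangle mesh of a flattened lateral
projection of the early embryonic body (or of a wounded tissue disc).  This
module generates those reference configurations, measures discrete boundary
curvature (circumscribed-circle stencil), and re-triangulates the domain when
advection has degraded element quality.

Conventions
-----------
* Boundary edges are oriented with the material domain on their *left*; the
  outward unit normal of an oriented edge ``d`` is ``(d_y, -d_x)/|d|``.
* Signed curvature is positive where the boundary of a simply connected
  domain is convex (a disc boundary has ``kappa = +1/R``); the inner rim of
  an annular wound consequently carries ``kappa = -1/R``.
* All coordinates are dimensionless model units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, MultiLineString, Polygon


def _cross2(a, b):
    """z-component of the cross product of stacked 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class ParameterError(ValueError):
    """Invalid geometric parameters (degenerate or inconsistent input)."""


class SelfIntersectionError(RuntimeError):
    """Boundary polygon crosses itself; carries one offending segment pair."""

    def __init__(self, msg, segment_a=None, segment_b=None):
        super().__init__(msg)
        self.segment_a = segment_a
        self.segment_b = segment_b


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------


@dataclass
class Chain:
    """An ordered run of mesh vertices sharing one boundary label.

    ``closed`` chains are loops (first vertex implicitly follows the last);
    ``internal`` chains are material lines inside the domain (e.g. the
    dorso-ventral segment under a placode) rather than free boundary.
    """

    label: str
    vertices: np.ndarray  # (k,) int vertex indices, ordered
    closed: bool = False
    internal: bool = False

    def copy(self) -> "Chain":
        return Chain(self.label, self.vertices.copy(), self.closed, self.internal)


@dataclass
class TriMesh:
    """Triangulated domain: vertices, positively oriented triangles,
    per-triangle material tag and labeled boundary/internal chains."""

    vertices: np.ndarray        # (n, 2) float
    triangles: np.ndarray       # (m, 3) int, CCW
    tri_tags: np.ndarray        # (m,) int material region tag
    chains: list[Chain] = field(default_factory=list)
    h: float = 0.05             # target edge length used to build the mesh

    # -- bookkeeping ------------------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.tri_tags.copy(),
            [c.copy() for c in self.chains],
            self.h,
        )

    def chains_for(self, label: str) -> list[Chain]:
        out = [c for c in self.chains if c.label == label]
        if not out:
            raise KeyError(f"no chain labeled {label!r}; have "
                           f"{sorted({c.label for c in self.chains})}")
        return out

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.chains:
            if c.label not in seen:
                seen.append(c.label)
        return seen

    # -- measures ---------------------------------------------------------

    def signed_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def area(self) -> float:
        return float(self.signed_areas().sum())

    def triangle_quality(self) -> np.ndarray:
        """Per-triangle 2*inradius/circumradius (1 for equilateral)."""
        p = self.vertices[self.triangles]
        a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
        b = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
        c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
        area = np.abs(self.signed_areas())
        s = a + b + c
        with np.errstate(divide="ignore", invalid="ignore"):
            q = 16.0 * area**2 / (s * a * b * c)
        return np.where(s * a * b * c > 0, q, 0.0)

    def min_quality(self) -> float:
        return float(self.triangle_quality().min())

    def min_edge_length(self) -> float:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.sqrt((d * d).sum(axis=1)).min())

    def chain_points(self, chain: Chain) -> np.ndarray:
        return self.vertices[chain.vertices]

    def chain_length(self, label: str) -> float:
        tot = 0.0
        for c in self.chains_for(label):
            p = self.chain_points(c)
            if c.closed:
                p = np.vstack([p, p[:1]])
            tot += float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
        return tot

    def perimeter(self, label: str) -> float:
        return self.chain_length(label)

    # -- boundary topology ------------------------------------------------

    def boundary_edges(self) -> np.ndarray:
        """Oriented boundary edges (domain on the left), from triangle
        incidence: edges used by exactly one triangle."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        key = np.sort(e, axis=1)
        _, inv, cnt = np.unique(key, axis=0, return_inverse=True,
                                return_counts=True)
        return e[cnt[inv] == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed vertex loops of the boundary, oriented domain-left
        (outer loops CCW, hole loops CW)."""
        edges = self.boundary_edges()
        succ = {int(a): int(b) for a, b in edges}
        loops = []
        seen: set[int] = set()
        for start in succ:
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            v = succ[start]
            while v != start:
                loop.append(v)
                seen.add(v)
                v = succ[v]
            loops.append(np.asarray(loop, dtype=int))
        return loops

    def external_loop(self) -> np.ndarray:
        """The outer boundary loop (largest absolute enclosed area)."""
        loops = self.boundary_loops()
        areas = [abs(_loop_signed_area(self.vertices[lp])) for lp in loops]
        return loops[int(np.argmax(areas))]

    def boundary_polygon(self) -> Polygon:
        loops = self.boundary_loops()
        areas = [_loop_signed_area(self.vertices[lp]) for lp in loops]
        outer = loops[int(np.argmax(np.abs(areas)))]
        holes = [self.vertices[lp] for i, lp in enumerate(loops)
                 if lp is not outer]
        return Polygon(self.vertices[outer], [h for h in holes])

    # -- validation -------------------------------------------------------

    def validate(self, tol: float = 1e-12) -> None:
        """Raise if invariants are broken: positive orientation, labels
        partition the boundary, no duplicate vertices."""
        if (self.signed_areas() <= 0).any():
            bad = int(np.where(self.signed_areas() <= 0)[0][0])
            raise ValueError(f"triangle {bad} not positively oriented")
        # labels partition the boundary edge set
        bnd = {tuple(sorted(e)) for e in self.boundary_edges()}
        labeled: dict[tuple, str] = {}
        for c in self.chains:
            if c.internal:
                continue
            v = c.vertices
            pairs = zip(v, np.roll(v, -1)) if c.closed else zip(v[:-1], v[1:])
            for a, b in pairs:
                k = tuple(sorted((int(a), int(b))))
                if k in labeled:
                    raise ValueError(f"edge {k} labeled twice "
                                     f"({labeled[k]!r}, {c.label!r})")
                labeled[k] = c.label
        if set(labeled) != bnd:
            missing = bnd - set(labeled)
            extra = set(labeled) - bnd
            raise ValueError(f"labels do not partition boundary: "
                             f"{len(missing)} unlabeled, {len(extra)} stray")
        # duplicate vertices
        order = np.lexsort(self.vertices.T)
        d = np.diff(self.vertices[order], axis=0)
        if (np.abs(d).sum(axis=1) < tol).any():
            raise ValueError("duplicate vertices within tolerance")


def _loop_signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# --------------------------------------------------------------------------
# discrete curvature
# --------------------------------------------------------------------------


@dataclass
class CurvatureField:
    """Signed curvature, outward normal, tangent and arclength at the
    vertices of one or more labeled chains.

    Arrays are concatenated over chains; ``slices`` records (slice, closed)
    per chain so per-chain structure (e.g. the arclength midpoint used by
    shear pairs) stays available.  ``endpoint`` flags open-chain ends whose
    curvature comes from a one-sided three-point stencil.
    """

    indices: np.ndarray     # (k,) vertex indices into the mesh
    kappa: np.ndarray       # (k,) signed curvature
    normal: np.ndarray      # (k, 2) unit outward normal
    tangent: np.ndarray     # (k, 2) unit tangent (traversal direction)
    s: np.ndarray           # (k,) arclength coordinate from chain start
    endpoint: np.ndarray    # (k,) bool, one-sided stencil flag
    slices: list[tuple[slice, bool]] = field(default_factory=list)

    def per_chain(self):
        for sl, closed in self.slices:
            yield sl, closed


def _chain_curvature(pts: np.ndarray, closed: bool):
    """Curvature/normal/tangent/arclength for one ordered polyline.

    kappa from the circumscribed circle of three consecutive vertices,
    signed by the cross product of the adjacent edge vectors.
    """
    k = len(pts)
    if k < 3:
        raise ParameterError("chain needs >= 3 vertices for curvature")
    if closed:
        prev = np.roll(pts, 1, axis=0)
        nxt = np.roll(pts, -1, axis=0)
    else:
        # one-sided stencil at the two endpoints: reuse the end triple
        prev = np.vstack([pts[0] + (pts[0] - pts[1]), pts[:-1]])
        nxt = np.vstack([pts[1:], pts[-1] + (pts[-1] - pts[-2])])
        # endpoints handled explicitly below
    u = pts - prev
    w = nxt - pts
    lu = np.linalg.norm(u, axis=1)
    lw = np.linalg.norm(w, axis=1)
    chord = nxt - prev
    lc = np.linalg.norm(chord, axis=1)
    cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = 2.0 * cross / (lu * lw * lc)
    kappa = np.where(lu * lw * lc > 0, kappa, 0.0)

    endpoint = np.zeros(k, dtype=bool)
    if not closed:
        # one-sided: curvature of the first/last vertex from the circle
        # through the three first/last vertices
        def circ_kappa(a, b, c):
            u_, w_ = b - a, c - b
            cr = u_[0] * w_[1] - u_[1] * w_[0]
            den = (np.linalg.norm(u_) * np.linalg.norm(w_)
                   * np.linalg.norm(c - a))
            return 2.0 * cr / den if den > 0 else 0.0

        kappa[0] = circ_kappa(pts[0], pts[1], pts[2])
        kappa[-1] = circ_kappa(pts[-3], pts[-2], pts[-1])
        endpoint[[0, -1]] = True

    # tangent: normalized chord (central difference); one-sided at ends
    tangent = chord / np.where(lc[:, None] > 0, lc[:, None], 1.0)
    if not closed:
        t0 = pts[1] - pts[0]
        t1 = pts[-1] - pts[-2]
        tangent[0] = t0 / np.linalg.norm(t0)
        tangent[-1] = t1 / np.linalg.norm(t1)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])

    seg = lw if closed else np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if closed:
        s = np.concatenate([[0.0], np.cumsum(lw[:-1])])
    else:
        s = np.concatenate([[0.0], np.cumsum(seg)])
    return kappa, normal, tangent, s, endpoint


def boundary_curvature(mesh: TriMesh, label: str) -> CurvatureField:
    """Curvature field on a labeled selection of the boundary.

    ``label`` may be any chain label, or ``"all-external"`` for the whole
    outer contour (ridge growth / negative surface tension acts there only).
    """
    if label == "all-external":
        loop = mesh.external_loop()
        chains = [Chain("all-external", loop, closed=True)]
    else:
        chains = mesh.chains_for(label)
    idx_l, kap_l, nor_l, tan_l, s_l, end_l, slices = [], [], [], [], [], [], []
    off = 0
    for c in chains:
        pts = mesh.chain_points(c)
        kap, nor, tan, s, end = _chain_curvature(pts, c.closed)
        n = len(c.vertices)
        idx_l.append(c.vertices)
        kap_l.append(kap)
        nor_l.append(nor)
        tan_l.append(tan)
        s_l.append(s)
        end_l.append(end)
        slices.append((slice(off, off + n), c.closed))
        off += n
    return CurvatureField(
        np.concatenate(idx_l), np.concatenate(kap_l),
        np.vstack(nor_l), np.vstack(tan_l),
        np.concatenate(s_l), np.concatenate(end_l), slices,
    )


# --------------------------------------------------------------------------
# structured builders
# --------------------------------------------------------------------------


def _quads_to_tris(verts: list, quads: list[tuple[int, int, int, int]],
                   tags: list[int], tag: int):
    """Split each quad (A,B,C,D in CCW order) into 4 triangles around its
    centroid.  The symmetric split keeps mirror-symmetric domains mirror
    symmetric, which the mechanics tests rely on."""
    tris = []
    for (a, b, c, d) in quads:
        pa, pb, pc, pd = verts[a], verts[b], verts[c], verts[d]
        ctr = ((pa[0] + pb[0] + pc[0] + pd[0]) / 4.0,
               (pa[1] + pb[1] + pc[1] + pd[1]) / 4.0)
        m = len(verts)
        verts.append(ctr)
        tris += [(a, b, m), (b, c, m), (c, d, m), (d, a, m)]
        tags += [tag] * 4
    return tris


def build_annulus(outer_radius: float, hole_radius: float,
                  target_edge_length: float) -> TriMesh:
    """Disc with a circular hole — the wound-healing domain.

    Structured polar mesh; boundary labels ``"hole"`` (inner rim, traversed
    clockwise so the material stays on the left) and ``"outer"``.
    """
    R, r, h = float(outer_radius), float(hole_radius), float(target_edge_length)
    if not (0 < r < R):
        raise ParameterError(f"need 0 < hole_radius < outer_radius, "
                             f"got ({r}, {R})")
    if not (0 < h < r):
        raise ParameterError("target_edge_length must be in (0, hole_radius)")
    if R - r < h:
        raise ParameterError("annulus too thin to mesh at this edge length")

    n_r = max(2, math.ceil((R - r) / h))
    n_t = max(16, math.ceil(2 * math.pi * 0.5 * (R + r) / h))
    radii = np.linspace(r, R, n_r + 1)
    theta = 2 * np.pi * np.arange(n_t) / n_t

    verts: list = []
    for ri in radii:
        for th in theta:
            verts.append((ri * math.cos(th), ri * math.sin(th)))

    def vid(i, j):
        return i * n_t + (j % n_t)

    quads = [(vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1))
             for i in range(n_r) for j in range(n_t)]
    tags: list[int] = []
    tris = _quads_to_tris(verts, quads, tags, 0)

    hole = np.array([vid(0, j) for j in range(n_t)][::-1], dtype=int)
    outer = np.array([vid(n_r, j) for j in range(n_t)], dtype=int)
    mesh = TriMesh(np.asarray(verts, float), np.asarray(tris, int),
                   np.asarray(tags, int),
                   [Chain("hole", hole, closed=True),
                    Chain("outer", outer, closed=True)], h)
    return mesh


@dataclass
class PlacodeSpec:
    """A crenel/trapeze notch protruding from the dorsal line: the sensory
    organ primordium inherited from the radial cleavage texture.

    position: center x of the footprint on the dorsal line.
    softness: multiplier on the stiffness-analog inside the notch
        (1 = normal tissue, small = very soft, 0 = absent tissue, in
        which case the notch is simply not meshed and the footprint is
        external boundary).
    """

    position: float
    width: float
    depth: float
    shape: str = "crenel"       # "crenel" (rectangular) or "trapeze"
    softness: float = 1.0

    def footprint(self) -> tuple[float, float]:
        return (self.position - self.width / 2.0,
                self.position + self.width / 2.0)


def _subdivide(x0: float, x1: float, h: float) -> np.ndarray:
    n = max(1, math.ceil((x1 - x0) / h))
    return np.linspace(x0, x1, n + 1)


def build_body(length: float, height: float,
               placodes: list[PlacodeSpec] | None = None,
               corner_smoothing_radius: float = 0.0,
               target_edge_length: float = 0.05) -> TriMesh:
    """Lateral projection of the embryonic body after neurulation.

    Rectangle ``[0, L] x [0, H]`` with the mouth at x=0, neck at x=L,
    dorsal side at y=H, ventral at y=0, plus optional placode notches on
    the dorsal line.  Labels: "mouth", "neck", "dorsal", "ventral",
    "ear_crenel" (notch contour) and "ear_base" (the dorso-ventral line
    segment under the notch; internal when the notch is meshed).
    A second, third ... placode gets suffixed labels ("ear_base_2", ...).

    With ``corner_smoothing_radius > 0`` the four rectangle corners are
    replaced by circular arcs (needed wherever curvature-driven growth acts,
    since curvature is undefined at a sharp corner); the arcs adjacent to
    the mouth edge belong to the "mouth" chain, those at the neck to "neck".
    """
    L, H, h = float(length), float(height), float(target_edge_length)
    rc = float(corner_smoothing_radius)
    placodes = list(placodes or [])
    if L <= 0 or H <= 0 or h <= 0 or h >= min(L, H):
        raise ParameterError("invalid rectangle dimensions or edge length")
    if rc < 0 or 2 * rc >= min(L, H):
        raise ParameterError("invalid corner smoothing radius")
    spans = sorted(p.footprint() for p in placodes)
    for (a0, a1) in spans:
        if a0 <= rc or a1 >= L - rc:
            raise ParameterError("placode footprint outside dorsal line")
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ParameterError("overlapping placode notches")
    for p in placodes:
        if p.depth <= 0 or p.width <= 0:
            raise ParameterError("placode width/depth must be positive")
        if not 0.0 <= p.softness <= 1.0:
            raise ParameterError("placode softness must lie in [0, 1]")
        if p.shape not in ("crenel", "trapeze"):
            raise ParameterError(f"unknown placode shape {p.shape!r}")

    if rc > 0:
        return _build_body_smoothed(L, H, placodes, rc, h)
    return _build_body_structured(L, H, placodes, h)


def _build_body_structured(L, H, placodes, h) -> TriMesh:
    # x breakpoints include every footprint edge exactly
    xs = [0.0, L]
    for p in placodes:
        xs += list(p.footprint())
    xs = sorted(set(xs))
    xg: list[float] = []
    for a, b in zip(xs, xs[1:]):
        xg.extend(_subdivide(a, b, h)[:-1])
    xg.append(L)
    xg = np.asarray(xg)
    yg = _subdivide(0.0, H, h)
    nx, ny = len(xg), len(yg)

    verts: list = [(x, y) for y in yg for x in xg]

    def vid(i, j):  # i = x index, j = y index
        return j * nx + i

    quads = [(vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1))
             for j in range(ny - 1) for i in range(nx - 1)]
    tags: list[int] = []
    tris = _quads_to_tris(verts, quads, tags, 0)

    # placode sub-meshes on top of the dorsal line
    crenel_chains: dict[int, np.ndarray] = {}
    base_chains: dict[int, np.ndarray] = {}
    for pi, p in enumerate(placodes):
        x0, x1 = p.footprint()
        cols = [i for i, x in enumerate(xg) if x0 - 1e-12 <= x <= x1 + 1e-12]
        base = np.array([vid(i, ny - 1) for i in cols], dtype=int)
        base_chains[pi] = base[::-1]  # ordered x-decreasing (loop direction)
        if p.softness == 0.0:
            continue
        xb = xg[cols]
        inset = p.width / 4.0 if p.shape == "trapeze" else 0.0
        xt = x0 + inset + (xb - x0) * (p.width - 2 * inset) / p.width
        n_d = max(1, math.ceil(p.depth / h))
        rows = [list(base)]
        for k in range(1, n_d + 1):
            eta = k / n_d
            xk = (1 - eta) * xb + eta * xt
            yk = H + eta * p.depth
            row = []
            for x, y in zip(xk, yk if np.ndim(yk) else [yk] * len(xk)):
                row.append(len(verts))
                verts.append((float(x), float(yk)))
            rows.append(row)
        pq = [(rows[k][i], rows[k][i + 1], rows[k + 1][i + 1], rows[k + 1][i])
              for k in range(n_d) for i in range(len(cols) - 1)]
        tris += _quads_to_tris(verts, pq, tags, pi + 1)
        # notch contour, loop direction (CCW outer): up the right side,
        # across the top x-decreasing, down the left side
        right = [rows[k][-1] for k in range(1, n_d + 1)]
        top = rows[n_d][::-1][1:]
        left = [rows[k][0] for k in range(n_d - 1, -1, -1)]
        crenel_chains[pi] = np.array([base[-1]] + right + top + left, dtype=int)

    # boundary chains, CCW from the ventral-mouth corner
    ventral = np.array([vid(i, 0) for i in range(nx)], dtype=int)
    neck = np.array([vid(nx - 1, j) for j in range(ny)], dtype=int)
    mouth = np.array([vid(0, j) for j in range(ny - 1, -1, -1)], dtype=int)

    def suffix(name, pi):
        return name if pi == 0 else f"{name}_{pi + 1}"

    chains = [Chain("ventral", ventral), Chain("neck", neck)]
    # dorsal pieces between placode footprints, x-decreasing
    cuts: list[tuple[float, float, int]] = [(x1, x0, pi) for pi, p in
                                            enumerate(placodes)
                                            for (x0, x1) in [p.footprint()]]
    cuts.sort(reverse=True)
    x_hi = L
    dorsal_pieces: list[np.ndarray] = []
    order: list = []  # interleaved dorsal / crenel for bookkeeping
    for (x1, x0, pi) in cuts:
        cols = [i for i in range(nx - 1, -1, -1)
                if x1 - 1e-12 <= xg[i] <= x_hi + 1e-12]
        dorsal_pieces.append(np.array([vid(i, ny - 1) for i in cols], int))
        order.append(("dorsal", dorsal_pieces[-1]))
        if placodes[pi].softness > 0.0:
            order.append((suffix("ear_crenel", pi), crenel_chains[pi]))
        else:
            order.append((suffix("ear_base", pi), base_chains[pi]))
        x_hi = x0
    cols = [i for i in range(nx - 1, -1, -1) if xg[i] <= x_hi + 1e-12]
    order.append(("dorsal", np.array([vid(i, ny - 1) for i in cols], int)))
    for name, arr in order:
        chains.append(Chain(name, arr))
    chains.append(Chain("mouth", mouth))
    for pi, p in enumerate(placodes):
        if p.softness > 0.0:
            chains.append(Chain(suffix("ear_base", pi), base_chains[pi],
                                internal=True))

    return TriMesh(np.asarray(verts, float), np.asarray(tris, int),
                   np.asarray(tags, int), chains, h)


def _arc(center, r, th0, th1, n):
    th = np.linspace(th0, th1, n + 1)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


def _build_body_smoothed(L, H, placodes, rc, h) -> TriMesh:
    """Rounded-corner body outline meshed by the generic Delaunay mesher."""
    n_arc = max(3, math.ceil(0.5 * math.pi * rc / h))
    pieces: list[tuple[str, np.ndarray]] = []

    def seg(label, p0, p1):
        pts = np.linspace(p0, p1, max(1, math.ceil(
            np.linalg.norm(np.subtract(p1, p0)) / h)) + 1)
        pieces.append((label, pts))

    def arc(label, center, th0, th1):
        pieces.append((label, _arc(center, rc, th0, th1, n_arc)))

    spans = sorted((p.footprint(), pi) for pi, p in enumerate(placodes))

    seg("ventral", (rc, 0.0), (L - rc, 0.0))
    arc("neck", (L - rc, rc), -math.pi / 2, 0.0)
    seg("neck", (L, rc), (L, H - rc))
    arc("neck", (L - rc, H - rc), 0.0, math.pi / 2)
    # dorsal, x decreasing, with placode notches
    x_hi = L - rc
    for (x0, x1), pi in reversed(spans):
        p = placodes[pi]
        name = "ear_crenel" if pi == 0 else f"ear_crenel_{pi + 1}"
        bname = "ear_base" if pi == 0 else f"ear_base_{pi + 1}"
        seg("dorsal", (x_hi, H), (x1, H))
        inset = p.width / 4.0 if p.shape == "trapeze" else 0.0
        if p.softness > 0.0:
            seg(name, (x1, H), (x1 - inset, H + p.depth))
            seg(name, (x1 - inset, H + p.depth), (x0 + inset, H + p.depth))
            seg(name, (x0 + inset, H + p.depth), (x0, H))
        else:
            seg(bname, (x1, H), (x0, H))
        x_hi = x0
    seg("dorsal", (x_hi, H), (rc, H))
    arc("mouth", (rc, H - rc), math.pi / 2, math.pi)
    seg("mouth", (0.0, H - rc), (0.0, rc))
    arc("mouth", (rc, rc), math.pi, 1.5 * math.pi)

    loop_pts: list[np.ndarray] = []
    loop_lbl: list[str] = []
    for label, pts in pieces:
        loop_pts.append(pts[:-1])
        loop_lbl += [label] * (len(pts) - 1)
    outline = np.vstack(loop_pts)

    internal = []
    for (x0, x1), pi in spans:
        if placodes[pi].softness > 0.0:
            bname = "ear_base" if pi == 0 else f"ear_base_{pi + 1}"
            pts = np.linspace((x1, H), (x0, H),
                              max(2, math.ceil((x1 - x0) / h)) + 1)
            internal.append((bname, pts))

    mesh = triangulate_polygon([(outline, loop_lbl)], internal, h)
    # region tags by point location inside the placode footprint polygons
    cen = mesh.vertices[mesh.triangles].mean(axis=1)
    for pi, p in enumerate(placodes):
        if p.softness == 0.0:
            continue
        x0, x1 = p.footprint()
        inset = p.width / 4.0 if p.shape == "trapeze" else 0.0
        poly = Polygon([(x0, H), (x1, H), (x1 - inset, H + p.depth),
                        (x0 + inset, H + p.depth)])
        inside = shapely.contains_xy(poly.buffer(1e-9), cen[:, 0], cen[:, 1])
        mesh.tri_tags[inside] = pi + 1
    return mesh


# --------------------------------------------------------------------------
# generic polygon mesher (used for smoothed outlines and for remeshing)
# --------------------------------------------------------------------------


def _hex_grid(bounds, h):
    xmin, ymin, xmax, ymax = bounds
    dy = h * math.sqrt(3.0) / 2.0
    rows = []
    j = 0
    y = ymin
    while y <= ymax:
        off = 0.5 * h if j % 2 else 0.0
        xs = np.arange(xmin + off, xmax + 1e-12, h)
        rows.append(np.column_stack([xs, np.full(len(xs), y)]))
        y += dy
        j += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def triangulate_polygon(loops: list[tuple[np.ndarray, list[str]]],
                        internal_chains: list[tuple[str, np.ndarray]] | None,
                        h: float, smooth_iters: int = 3) -> TriMesh:
    """Triangulate a polygon (outer loop first, then holes) keeping every
    input boundary vertex and per-edge label, plus optional internal
    constraint polylines that must appear as mesh edges.

    Conforming-Delaunay strategy: Delaunay of boundary + interior points,
    triangles kept by centroid-in-polygon; any required segment missing
    from the triangulation is split at its midpoint and the triangulation
    redone (the midpoint lies on the segment, so the polygon is unchanged).
    """
    internal_chains = list(internal_chains or [])
    loops = [(np.asarray(p, float), list(lbl)) for p, lbl in loops]
    for pts, lbl in loops:
        if len(pts) != len(lbl):
            raise ParameterError("per-edge label list must match loop length")

    outer = loops[0][0]
    poly = Polygon(outer, [p for p, _ in loops[1:]])
    if not poly.is_valid:
        a, b = _find_self_intersection(
            [p for p, _ in loops] + [p for _, p in internal_chains])
        raise SelfIntersectionError("boundary polygon self-intersects", a, b)

    eroded = poly.buffer(-0.6 * h)
    grid = _hex_grid(poly.bounds, h)
    if len(grid) and not eroded.is_empty:
        keep = shapely.contains_xy(eroded, grid[:, 0], grid[:, 1])
        grid = grid[keep]
    else:
        grid = np.empty((0, 2))
    if len(grid) and internal_chains:
        lines = MultiLineString([LineString(p) for _, p in internal_chains])
        d = shapely.distance(shapely.points(grid), lines)
        grid = grid[d > 0.55 * h]

    chains = [(lbl, np.asarray(p, float)) for lbl, p in internal_chains]

    for _ in range(12):
        res = _try_triangulate(loops, chains, grid, poly)
        if res is not None:
            verts, tris, loop_idx, chain_idx = res
            break
        # _try_triangulate mutated loops/chains by splitting missing segments
    else:
        raise RuntimeError("segment recovery failed to converge")

    mesh = _assemble_mesh(verts, tris, loops, loop_idx, chains, chain_idx, h)
    _smooth_interior(mesh, loop_idx, chain_idx, smooth_iters)
    return mesh


def _try_triangulate(loops, chains, grid, poly):
    """One Delaunay pass; returns None after splitting missing required
    segments in place (caller retries)."""
    pts: list = []
    index: dict[tuple, int] = {}

    def add(p):
        key = (round(float(p[0]), 9), round(float(p[1]), 9))
        if key not in index:
            index[key] = len(pts)
            pts.append((float(p[0]), float(p[1])))
        return index[key]

    loop_idx = [np.array([add(p) for p in lp], int) for lp, _ in loops]
    chain_idx = [np.array([add(p) for p in cp], int) for _, cp in chains]
    n_fixed = len(pts)
    for g in grid:
        add(g)

    arr = np.asarray(pts)
    tri = Delaunay(arr)
    cen = arr[tri.simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cen[:, 0], cen[:, 1])
    simp = tri.simplices[inside]

    edges = set()
    for t in simp:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edges.add((min(a, b), max(a, b)))

    missing_any = False
    for li, (lp, lbl) in enumerate(loops):
        idx = loop_idx[li]
        n = len(idx)
        new_pts, new_lbl = [], []
        for i in range(n):
            a, b = int(idx[i]), int(idx[(i + 1) % n])
            new_pts.append(lp[i])
            new_lbl.append(lbl[i])
            if (min(a, b), max(a, b)) not in edges:
                missing_any = True
                mid = 0.5 * (lp[i] + lp[(i + 1) % n])
                new_pts.append(mid)
                new_lbl.append(lbl[i])
        loops[li] = (np.asarray(new_pts), new_lbl)
    for ci, (lbl, cp) in enumerate(chains):
        idx = chain_idx[ci]
        new_pts = []
        for i in range(len(idx) - 1):
            a, b = int(idx[i]), int(idx[i + 1])
            new_pts.append(cp[i])
            if (min(a, b), max(a, b)) not in edges:
                missing_any = True
                new_pts.append(0.5 * (cp[i] + cp[i + 1]))
        new_pts.append(cp[-1])
        chains[ci] = (lbl, np.asarray(new_pts))
    if missing_any:
        return None

    # drop unused points, reindex, fix orientation
    used = np.unique(simp)
    remap = -np.ones(len(arr), dtype=int)
    remap[used] = np.arange(len(used))
    verts = arr[used]
    tris = remap[simp]
    p = verts[tris]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = areas < 0
    tris[flip] = tris[flip][:, ::-1]
    keep = np.abs(areas) > 1e-14
    tris = tris[keep]
    loop_idx = [remap[ix] for ix in loop_idx]
    chain_idx = [remap[ix] for ix in chain_idx]
    if any((ix < 0).any() for ix in loop_idx + chain_idx):
        return None  # a fixed point was dropped; shouldn't happen
    return verts, tris, loop_idx, chain_idx


def _assemble_mesh(verts, tris, loops, loop_idx, chains, chain_idx, h):
    mesh_chains: list[Chain] = []
    for (lp, lbl), idx in zip(loops, loop_idx):
        n = len(idx)
        # group consecutive same-label edges into chains; start at a label
        # change so no run is split across the loop seam
        start = 0
        for i in range(n):
            if lbl[i] != lbl[i - 1]:
                start = i
                break
        else:
            mesh_chains.append(Chain(lbl[0], idx, closed=True))
            continue
        i = start
        count = 0
        while count < n:
            j = i
            run = [idx[i]]
            while count < n and lbl[j] == lbl[i]:
                run.append(idx[(j + 1) % n])
                j = (j + 1) % n
                count += 1
            mesh_chains.append(Chain(lbl[i], np.asarray(run, int)))
            i = j
    for (lbl, _), idx in zip(chains, chain_idx):
        mesh_chains.append(Chain(lbl, idx, internal=True))
    tags = np.zeros(len(tris), dtype=int)
    return TriMesh(np.asarray(verts, float), np.asarray(tris, int),
                   tags, mesh_chains, h)


def _smooth_interior(mesh: TriMesh, loop_idx, chain_idx, iters: int):
    """Laplacian smoothing of unconstrained interior vertices with an
    element-inversion guard."""
    fixed = set()
    for ix in loop_idx + chain_idx:
        fixed.update(int(i) for i in ix)
    n = len(mesh.vertices)
    nbrs: list[set] = [set() for _ in range(n)]
    incid: list[list[int]] = [[] for _ in range(n)]
    for ti, t in enumerate(mesh.triangles):
        for a in t:
            incid[a].append(ti)
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
    v = mesh.vertices
    for _ in range(iters):
        for i in range(n):
            if i in fixed or not nbrs[i]:
                continue
            old = v[i].copy()
            v[i] = np.mean([v[j] for j in nbrs[i]], axis=0)
            p = v[mesh.triangles[incid[i]]]
            if (0.5 * _cross2(p[:, 1] - p[:, 0],
                              p[:, 2] - p[:, 0]) <= 1e-14).any():
                v[i] = old


def _find_self_intersection(polylines: list[np.ndarray]):
    """Brute-force search for one pair of properly crossing segments."""
    segs = []
    for pts in polylines:
        closed_pts = np.vstack([pts, pts[:1]])
        for a, b in zip(closed_pts[:-1], closed_pts[1:]):
            segs.append((tuple(a), tuple(b)))
    for i in range(len(segs)):
        li = LineString(segs[i])
        for j in range(i + 1, len(segs)):
            lj = LineString(segs[j])
            if li.crosses(lj):
                return segs[i], segs[j]
    return None, None


# --------------------------------------------------------------------------
# remeshing
# --------------------------------------------------------------------------


def remesh_if_needed(mesh: TriMesh, min_quality: float) -> TriMesh:
    """Re-triangulate the current boundary polygon if any element quality
    (2*inradius/circumradius) has dropped below ``min_quality``.

    Boundary vertex positions, labels and internal constraint chains are
    preserved exactly; region tags are re-assigned by centroid location in
    the old tagged regions.  Returns the input object unchanged when the
    mesh is still good enough.
    """
    if not 0.0 < min_quality < 1.0:
        raise ParameterError("min_quality must lie in (0, 1)")
    if mesh.min_quality() >= min_quality:
        return mesh

    # boundary loops with per-edge labels, taken from the labeled chains
    label_of: dict[tuple, str] = {}
    for c in mesh.chains:
        if c.internal:
            continue
        v = c.vertices
        pairs = zip(v, np.roll(v, -1)) if c.closed else zip(v[:-1], v[1:])
        for a, b in pairs:
            label_of[tuple(sorted((int(a), int(b))))] = c.label
    loops = []
    for lp in mesh.boundary_loops():
        pts = mesh.vertices[lp]
        lbl = [label_of[tuple(sorted((int(lp[i]), int(lp[(i + 1) % len(lp)]))))]
               for i in range(len(lp))]
        loops.append((pts, lbl))
    # outer loop first
    loops.sort(key=lambda pl: -abs(_loop_signed_area(pl[0])))

    internal = [(c.label, mesh.chain_points(c)) for c in mesh.chains
                if c.internal]

    new = triangulate_polygon(loops, internal, mesh.h)

    # region tags by point location in the old tagged regions
    tags = sorted(set(int(t) for t in mesh.tri_tags))
    if len(tags) > 1:
        cen = new.vertices[new.triangles].mean(axis=1)
        for tg in tags:
            if tg == 0:
                continue
            sel = mesh.tri_tags == tg
            region = shapely.unary_union(
                [Polygon(p) for p in mesh.vertices[mesh.triangles[sel]]])
            inside = shapely.contains_xy(region.buffer(1e-9),
                                         cen[:, 0], cen[:, 1])
            new.tri_tags[inside] = tg
    return new
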
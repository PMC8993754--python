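"""Closed-form quadrupolar potential flow of ear winding.

Two vertical source lines at x = a and x = c pull head-on along the segment
y in [-b, b]; their strengths alpha and beta differ to encode the
antero-posterior asymmetry.  The resulting conservative 2D flow derives
from the stream function

    Psi(x, y) =  alpha ln((x-a)^2 + (y-b)^2) - alpha ln((x-a)^2 + (y+b)^2)
               - beta  ln((x-c)^2 + (y-b)^2) + beta  ln((x-c)^2 + (y+b)^2)

with velocity (u, v) = (dPsi/dy, -dPsi/dx), exactly divergence-free, odd in
y, harmonic away from the four logarithmic point sources, and carrying one
saddle stagnation point on the axis between the sources.  A passive contour
advected in this frozen field winds asymmetrically into an ear-like shape;
the flow is deliberately *not* self-consistent (the force term is not
advected) — that upgrade is what the finite-element shear-pair actuators
provide — so this module doubles as an early-time cross-check for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SingularityError(ValueError):
    """Evaluation at (or advection into) a logarithmic source point."""

    def __init__(self, msg, marker_index=None):
        super().__init__(msg)
        self.marker_index = marker_index


@dataclass
class QuadrupoleFlowParams:
    """(a, c): x-positions of the source lines; b: half-length of the
    pulling segment; (alpha, beta): source magnitudes (alpha = beta gives
    the symmetric quadrupole)."""

    a: float = -1.0
    c: float = 1.0
    b: float = 0.5
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.a == self.c:
            raise ValueError("source lines must be distinct (a != c)")
        if self.b <= 0:
            raise ValueError("pulling half-length b must be positive")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("source magnitudes must be finite")

    @property
    def singularities(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.a, -self.b],
                         [self.c, self.b], [self.c, -self.b]])

    @property
    def exclusion_radius(self) -> float:
        return 1e-3 * abs(self.c - self.a)


def _r2(x, y, x0, y0):
    return (x - x0) ** 2 + (y - y0) ** 2


def _check_regular(x, y, params):
    d2 = np.min([_r2(np.asarray(x, float), np.asarray(y, float), sx, sy)
                 for (sx, sy) in params.singularities], axis=0)
    if np.any(d2 == 0.0):
        raise SingularityError("evaluation at a source singularity")


def psi(x, y, params: QuadrupoleFlowParams):
    """Stream function value(s); odd in y, zero on the y = 0 axis."""
    _check_regular(x, y, params)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a, c, b = params.a, params.c, params.b
    al, be = params.alpha, params.beta
    val = (al * np.log(_r2(x, y, a, b)) - al * np.log(_r2(x, y, a, -b))
           - be * np.log(_r2(x, y, c, b)) + be * np.log(_r2(x, y, c, -b)))
    return val if val.shape else float(val)


def velocity(x, y, params: QuadrupoleFlowParams):
    """(u, v) = (dPsi/dy, -dPsi/dx), hand-derived analytic derivatives."""
    _check_regular(x, y, params)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a, c, b = params.a, params.c, params.b
    al, be = params.alpha, params.beta
    r1 = _r2(x, y, a, b)
    r2 = _r2(x, y, a, -b)
    r3 = _r2(x, y, c, b)
    r4 = _r2(x, y, c, -b)
    dpsi_dy = 2 * (al * (y - b) / r1 - al * (y + b) / r2
                   - be * (y - b) / r3 + be * (y + b) / r4)
    dpsi_dx = 2 * (al * (x - a) / r1 - al * (x - a) / r2
                   - be * (x - c) / r3 + be * (x - c) / r4)
    u, v = dpsi_dy, -dpsi_dx
    if u.shape:
        return u, v
    return float(u), float(v)


def check_harmonic(params: QuadrupoleFlowParams, bounds, n: int,
                   r_excl: float | None = None) -> float:
    """Max |finite-difference Laplacian of Psi| on an n x n grid over
    ``bounds`` = (xmin, xmax, ymin, ymax), excluding disks of radius
    ``r_excl`` around the four sources (default: 10 grid spacings).

    Should vanish at second order in the grid spacing, since the sources
    are point-like.
    """
    xmin, xmax, ymin, ymax = bounds
    xs = np.linspace(xmin, xmax, n)
    ys = np.linspace(ymin, ymax, n)
    hx = xs[1] - xs[0]
    hy = ys[1] - ys[0]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    if r_excl is None:
        r_excl = 10.0 * max(hx, hy)
    d2 = np.min([_r2(X, Y, sx, sy) for (sx, sy) in params.singularities],
                axis=0)
    if np.any(d2 == 0.0):
        raise ValueError("grid contains a source singularity")
    P = psi(X, Y, params)
    lap = ((P[2:, 1:-1] - 2 * P[1:-1, 1:-1] + P[:-2, 1:-1]) / hx**2
           + (P[1:-1, 2:] - 2 * P[1:-1, 1:-1] + P[1:-1, :-2]) / hy**2)
    mask = d2[1:-1, 1:-1] > r_excl**2
    if not mask.any():
        raise ValueError("exclusion radius removes the whole grid")
    return float(np.abs(lap[mask]).max())


def advect_contour(contour: np.ndarray, params: QuadrupoleFlowParams,
                   dt: float, n_steps: int) -> np.ndarray:
    """Advect marker points through the frozen flow with classical RK4.

    Returns the (n_steps+1, n_markers, 2) trajectory; halts with
    :class:`SingularityError` (carrying the marker index) if any marker
    enters the exclusion radius of a source.
    """
    pts = np.asarray(contour, float).copy()
    out = np.empty((n_steps + 1,) + pts.shape)
    out[0] = pts
    r2min = params.exclusion_radius ** 2

    def vel(p):
        u, v = velocity(p[:, 0], p[:, 1], params)
        return np.column_stack([u, v])

    def guard(p):
        d2 = np.min([_r2(p[:, 0], p[:, 1], sx, sy)
                     for (sx, sy) in params.singularities], axis=0)
        if np.any(d2 < r2min):
            idx = int(np.argmin(d2))
            raise SingularityError(
                f"marker {idx} entered a source exclusion disk", idx)

    for i in range(1, n_steps + 1):
        guard(pts)
        k1 = vel(pts)
        k2 = vel(pts + 0.5 * dt * k1)
        k3 = vel(pts + 0.5 * dt * k2)
        k4 = vel(pts + dt * k3)
        pts = pts + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = pts
    guard(pts)
    return out


def plot_streamlines(params: QuadrupoleFlowParams, bounds, path,
                     n: int = 200, contour: np.ndarray | None = None):
    """Quick-look PNG of the iso-Psi streamlines (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xmin, xmax, ymin, ymax = bounds
    X, Y = np.meshgrid(np.linspace(xmin, xmax, n),
                       np.linspace(ymin, ymax, n))
    P = psi(X, Y, params)
    lim = np.percentile(np.abs(P), 95)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.contour(X, Y, P, levels=np.linspace(-lim, lim, 31), linewidths=0.7)
    ax.plot(*params.singularities.T, "k+", ms=8)
    if contour is not None:
        ax.plot(contour[:, 0], contour[:, 1], "r-", lw=1.5)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def stagnation_points_on_axis(params: QuadrupoleFlowParams,
                              n_samples: int = 2000) -> np.ndarray:
    """x-positions of stagnation points on the y = 0 axis strictly between
    the sources (v = 0 there by symmetry; roots of u)."""
    from scipy.optimize import brentq

    lo, hi = sorted((params.a, params.c))
    eps = 1e-6 * (hi - lo)
    xs = np.linspace(lo + eps, hi - eps, n_samples)
    u, _ = velocity(xs, np.zeros_like(xs), params)
    roots = []
    for i in range(len(xs) - 1):
        if u[i] == 0.0:
            roots.append(xs[i])
        elif u[i] * u[i + 1] < 0:
            roots.append(brentq(
                lambda x: velocity(x, 0.0, params)[0], xs[i], xs[i + 1]))
    return np.asarray(roots)
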
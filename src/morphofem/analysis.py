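"""Trace analysis: closure-law fitting, shape metrics, regime comparison.

The simulator's central dynamical claim is a dichotomy of closure laws: a
constant contractile tension on a shrinking rim keeps the total Laplace
force constant and closes the hole linearly in time, while a constant
pressure (or a shrinking shear-pair segment) sees its total force decay with
the pulling length, giving exponential self-arrest, dL/dt ~ -L, i.e.
L ~ exp(-t/tau).  ``fit_closure_law`` discriminates the two by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TriMesh, _cross2, _loop_signed_area


class FitError(ValueError):
    pass


@dataclass
class ClosureTrace:
    """A scalar closure observable L(t) with its fitted laws.

    linear:      L ~ intercept + slope * t
    exponential: L ~ L0 * exp(-t / tau)   (log-linear least squares)
    selected:    the lower-AIC law (ties break toward linear).
    """

    times: np.ndarray
    values: np.ndarray
    burn_in: float
    linear: dict = field(default_factory=dict)
    exponential: dict = field(default_factory=dict)
    selected: str = ""

    @property
    def tau(self) -> float:
        return self.exponential.get("tau", np.nan)


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def fit_closure_law(times, values, burn_in: float = 0.2) -> ClosureTrace:
    """Fit linear and exponential closure laws to L(t) and select by AIC.

    ``burn_in`` discards the leading fraction of the *time range* (the
    initial deformation transient) before fitting.  Both residual sums are
    evaluated on the original scale; the exponential is fitted by linear
    regression on log L, which requires positive values.
    """
    t = np.asarray(times, float)
    L = np.asarray(values, float)
    if t.ndim != 1 or t.shape != L.shape:
        raise FitError("times and values must be 1D and equally long")
    if np.any(np.diff(t) <= 0):
        raise FitError("times must be strictly increasing")
    if not 0.0 <= burn_in < 1.0:
        raise FitError("burn_in must lie in [0, 1)")
    t_cut = t[0] + burn_in * (t[-1] - t[0])
    keep = t >= t_cut
    t, L = t[keep], L[keep]
    if len(t) < 10:
        raise FitError("need >= 10 points after burn-in")
    if np.any(L <= 0):
        raise FitError("closure observable must stay positive")

    out = ClosureTrace(t, L, burn_in)
    n = len(t)

    slope, intercept = np.polyfit(t, L, 1)
    rss_lin = float(((intercept + slope * t - L) ** 2).sum())
    out.linear = {"slope": float(slope), "intercept": float(intercept),
                  "rss": rss_lin, "aic": _aic(rss_lin, n, 2)}

    lslope, lint = np.polyfit(t, np.log(L), 1)
    logL = lint + lslope * t
    ss_res = float(((np.log(L) - logL) ** 2).sum())
    ss_tot = float(((np.log(L) - np.log(L).mean()) ** 2).sum())
    r2_log = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pred = np.exp(logL)
    rss_exp = float(((pred - L) ** 2).sum())
    out.exponential = {"L0": float(np.exp(lint)), "rate": float(lslope),
                       "rss": rss_exp, "aic": _aic(rss_exp, n, 2),
                       "r2_log": r2_log}
    if lslope < 0:
        out.exponential["tau"] = float(-1.0 / lslope)

    if lslope >= 0 or out.linear["aic"] <= out.exponential["aic"]:
        out.selected = "linear"
    else:
        out.selected = "exponential"
    return out


# --------------------------------------------------------------------------
# shape metrics
# --------------------------------------------------------------------------


def _region_triangles(mesh: TriMesh, region) -> np.ndarray:
    sel = np.where(mesh.tri_tags == int(region))[0]
    if len(sel) == 0:
        raise ValueError(f"no triangles carry region tag {region}")
    return sel


def _region_boundary_length(mesh: TriMesh, sel: np.ndarray) -> float:
    t = mesh.triangles[sel]
    e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, inv, cnt = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    bnd = uniq[cnt == 1]
    d = mesh.vertices[bnd[:, 0]] - mesh.vertices[bnd[:, 1]]
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def shape_metrics(mesh: TriMesh, region) -> dict:
    """Area, perimeter, centroid, principal-axis aspect ratio and
    isoperimetric ratio of a tagged region, or chord-deflection metrics of
    a labeled boundary chain.

    ``region``: an int material tag, or a string chain label.  For chains,
    deflection is measured perpendicular to the chord through the chain
    endpoints: ``deflection_in`` toward the material (invagination depth),
    ``deflection_out`` away from it (tip extension).
    """
    if isinstance(region, str):
        return _chain_metrics(mesh, region)
    sel = _region_triangles(mesh, region)
    p = mesh.vertices[mesh.triangles[sel]]
    a = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = float(a.sum())
    cen = (p.mean(axis=1) * a[:, None]).sum(axis=0) / area
    # exact second area moments per triangle (vertex + midpoint rule is
    # exact for quadratics: integral of x_i x_j over a triangle)
    mids = 0.5 * (p + np.roll(p, -1, axis=1))
    q = mids - cen
    cov = np.einsum("t,tki,tkj->ij", a / 3.0, q, q) / area
    evals = np.linalg.eigvalsh(cov)
    aspect = float(np.sqrt(max(evals) / max(min(evals), 1e-300)))
    perim = _region_boundary_length(mesh, sel)
    return {
        "area": area,
        "perimeter": perim,
        "centroid": (float(cen[0]), float(cen[1])),
        "aspect_ratio": aspect,
        "isoperimetric_ratio": 4 * np.pi * area / perim**2,
    }


def _chain_metrics(mesh: TriMesh, label: str) -> dict:
    chains = mesh.chains_for(label)
    pts = np.vstack([mesh.chain_points(c) for c in chains])
    closed = all(c.closed for c in chains)
    seg = np.diff(np.vstack([pts, pts[:1]]) if closed else pts, axis=0)
    length = float(np.linalg.norm(seg, axis=1).sum())
    out: dict = {"length": length}
    if closed:
        area = abs(_loop_signed_area(pts))
        out["area"] = area
        out["isoperimetric_ratio"] = 4 * np.pi * area / length**2
        out["centroid"] = tuple(pts.mean(axis=0))
        return out
    chord = pts[-1] - pts[0]
    lc = np.linalg.norm(chord)
    if lc == 0:
        raise ValueError(f"chain {label!r} chord degenerate")
    d = _cross2(chord / lc, pts - pts[0])
    # chains run with the domain on their left: positive offsets point into
    # the material (inward), negative away from it (outward)
    out["deflection_in"] = float(np.max(d))
    out["deflection_out"] = float(-np.min(d))
    out["chord_length"] = float(lc)
    return out


# --------------------------------------------------------------------------
# regime comparison
# --------------------------------------------------------------------------


@dataclass
class RegimeComparison:
    observable: str
    times: np.ndarray
    curve_a: np.ndarray
    curve_b: np.ndarray
    end_a: float
    end_b: float
    delta: float                 # end_a - end_b
    fit_a: ClosureTrace | None = None
    fit_b: ClosureTrace | None = None


def compare_regimes(run_a, run_b, observable: str,
                    fit: bool = False, burn_in: float = 0.2) -> RegimeComparison:
    """Pair one observable across two runs sharing geometry and dt policy.

    Curves are interpolated onto the shorter common time range; the report
    carries the end-state delta and, optionally, the fitted closure laws.
    """
    ta, tb = run_a.trace.times, run_b.trace.times
    if observable not in run_a.trace.observables or \
            observable not in run_b.trace.observables:
        raise ValueError(f"observable {observable!r} missing from a run")
    if run_a.config.geometry != run_b.config.geometry or \
            run_a.config.dt != run_b.config.dt:
        raise ValueError("runs must share geometry and dt policy")
    t_end = min(ta[-1], tb[-1])
    t = np.linspace(0.0, t_end, 200)
    ya = np.interp(t, ta, run_a.trace.observables[observable])
    yb = np.interp(t, tb, run_b.trace.observables[observable])
    fa = fb = None
    if fit:
        fa = fit_closure_law(t[1:], ya[1:], burn_in)
        fb = fit_closure_law(t[1:], yb[1:], burn_in)
    return RegimeComparison(observable, t, ya, yb,
                            float(ya[-1]), float(yb[-1]),
                            float(ya[-1] - yb[-1]), fa, fb)
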
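"""Quasi-static viscous plane mechanics on a Lagrangian triangle mesh.

The tissue obeys a creeping-flow constitutive law sigma = H : strain_rate,
where H is built like a plane-stress Hooke matrix but its entries are
viscosities (stiffness-analog E*, Poisson-analog nu*).  At every instant the
velocity field v balances the applied boundary tractions exactly,

    div sigma = 0 in the bulk,     sigma . n = t on the boundary,

discretised with linear (P1) triangles and solved by direct sparse
factorisation.  The deformed configuration is then advanced explicitly,
x <- x + v dt, and becomes the reference configuration for the next solve;
boundary force terms are re-evaluated on the deformed contour each step, so
a contraction shrinks its own source and self-arrests.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Chain, TriMesh, remesh_if_needed


class SolverError(RuntimeError):
    pass


class StepRejectedError(RuntimeError):
    """Explicit move inverted an element; caller should halve dt or remesh."""


@dataclass
class MaterialModel:
    """Viscous Hooke-analog material.

    stiffness_analog : E*, the viscosity-scale analog of a Young modulus
        (model value 2 over a body dimension of 0.4 maps to the ~1000 Pa
        range of early embryonic tissue once redimensioned).
    poisson_analog : nu*, ratio of bulk to shear viscosity response;
        default 0.45, near-incompressible but non-singular.
    softness : per-region multiplier f in [0, 1] on E* (region tag -> f),
        used to soften or effectively remove placode tissue.
    """

    stiffness_analog: float = 2.0
    poisson_analog: float = 0.45
    softness: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.stiffness_analog <= 0:
            raise ValueError("stiffness_analog must be positive")
        if not -1.0 < self.poisson_analog < 0.5:
            raise ValueError("poisson_analog must lie in (-1, 0.5)")
        for tag, f in self.softness.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(
                    f"softness factor for tag {tag} must lie in (0, 1]; "
                    "use geometry (softness=0) to remove tissue entirely")

    def h_matrix(self) -> np.ndarray:
        """Plane-stress-analog viscosity matrix (Voigt order xx, yy, xy)."""
        e, nu = self.stiffness_analog, self.poisson_analog
        return e / (1 - nu**2) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2.0]])

    def factor(self, tags: np.ndarray) -> np.ndarray:
        f = np.ones(len(tags))
        for tag, val in self.softness.items():
            f[tags == tag] = val
        return f


@dataclass
class VelocityField:
    values: np.ndarray          # (n, 2) displacement rate per vertex
    residual: float             # relative residual of the solve

    def max_speed(self) -> float:
        return float(np.sqrt((self.values**2).sum(axis=1)).max())


@dataclass
class BoundaryTraction:
    """Traction (force per unit boundary length) sampled at the vertices of
    one chain; converted to nodal loads by edge-lumped integration."""

    chain: Chain
    values: np.ndarray          # (k, 2)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------


def _element_gradients(mesh: TriMesh):
    p = mesh.vertices[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    area2 = ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
             - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0],
                  y[:, 0] - y[:, 1]], axis=1) / area2[:, None]
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                  x[:, 1] - x[:, 0]], axis=1) / area2[:, None]
    return b, c, 0.5 * area2


def _stiffness(mesh: TriMesh, material: MaterialModel) -> sp.csr_matrix:
    b, c, area = _element_gradients(mesh)
    m = len(mesh.triangles)
    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    H = material.h_matrix()
    f = material.factor(mesh.tri_tags)
    ke = np.einsum("mia,ij,mjb->mab", B, H, B) * (f * area)[:, None, None]
    dof = np.empty((m, 6), dtype=int)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    n = 2 * len(mesh.vertices)
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def traction_loads(mesh: TriMesh,
                   tractions: list[BoundaryTraction]) -> np.ndarray:
    """Edge-lumped nodal forces: each chain edge contributes half its length
    times the traction sampled at each of its endpoints."""
    F = np.zeros_like(mesh.vertices)
    for bt in tractions:
        v = bt.chain.vertices
        vals = np.asarray(bt.values, float)
        if bt.chain.closed:
            a, b = v, np.roll(v, -1)
            va, vb = vals, np.roll(vals, -1, axis=0)
        else:
            a, b = v[:-1], v[1:]
            va, vb = vals[:-1], vals[1:]
        ell = np.linalg.norm(mesh.vertices[b] - mesh.vertices[a], axis=1)
        np.add.at(F, a, 0.5 * ell[:, None] * va)
        np.add.at(F, b, 0.5 * ell[:, None] * vb)
    return F


def stress_boundary_loads(mesh: TriMesh, sigma: np.ndarray) -> np.ndarray:
    """Consistent nodal loads of a uniform stress state applied as boundary
    traction sigma.n (per-edge normals, exact for the patch test)."""
    F = np.zeros_like(mesh.vertices)
    for a, b in mesh.boundary_edges():
        d = mesh.vertices[b] - mesh.vertices[a]
        ell = np.linalg.norm(d)
        n = np.array([d[1], -d[0]]) / ell
        t = sigma @ n
        F[a] += 0.5 * ell * t
        F[b] += 0.5 * ell * t
    return F


def _body_force_loads(mesh: TriMesh, body_force) -> np.ndarray:
    """Consistent P1 loads of a volumetric force density, integrated with
    the 3-edge-midpoint rule (exact for quadratics)."""
    p = mesh.vertices[mesh.triangles]
    _, _, area = _element_gradients(mesh)
    mids = 0.5 * (p + np.roll(p, -1, axis=1))      # midpoints opposite order
    F = np.zeros_like(mesh.vertices)
    # midpoint k lies opposite vertex (k+2)%3; shape function values at the
    # midpoints: phi_i = 1/2 at the two adjacent midpoints, 0 at the opposite
    fvals = np.stack([np.column_stack(body_force(mids[:, k, 0],
                                                 mids[:, k, 1]))
                      for k in range(3)], axis=1)          # (m, 3, 2)
    w = area[:, None] / 3.0
    for i in range(3):
        contrib = 0.5 * (fvals[:, i] + fvals[:, (i + 2) % 3]) * w
        np.add.at(F, mesh.triangles[:, i], contrib)
    return F


def _dirichlet_dofs(mesh: TriMesh, constraints) -> tuple[np.ndarray, np.ndarray]:
    """Constraints spec -> (dof indices, prescribed values).

    Accepted keys: "fixed_labels" (pin both components of every vertex of
    those chains to zero) and "fixed_vertices" (list of (vertex, component,
    value) triples).
    """
    dofs: list[int] = []
    vals: list[float] = []
    constraints = constraints or {}
    for label in constraints.get("fixed_labels", []):
        for c in mesh.chains_for(label):
            for v in c.vertices:
                dofs += [2 * int(v), 2 * int(v) + 1]
                vals += [0.0, 0.0]
    for (v, comp, val) in constraints.get("fixed_vertices", []):
        dofs.append(2 * int(v) + int(comp))
        vals.append(float(val))
    if not dofs:
        return np.empty(0, int), np.empty(0)
    dofs_a = np.asarray(dofs, int)
    vals_a = np.asarray(vals, float)
    uniq, first = np.unique(dofs_a, return_index=True)
    return uniq, vals_a[first]


def assemble_and_solve(mesh: TriMesh, material: MaterialModel,
                       tractions: list[BoundaryTraction] | None = None,
                       constraints: dict | None = None,
                       nodal_loads: np.ndarray | None = None,
                       body_force=None,
                       nullspace_filter: bool = False,
                       tol: float = 1e-10) -> VelocityField:
    """Solve the discrete quasi-static problem for the velocity field.

    Rigid-body modes (2 translations + 1 rotation) must be removed by the
    Dirichlet constraints; alternatively ``nullspace_filter=True`` augments
    the system with the three rigid modes as Lagrange constraints, valid
    when the tractions are self-equilibrated.
    """
    K = _stiffness(mesh, material)
    F = np.zeros_like(mesh.vertices)
    if tractions:
        F += traction_loads(mesh, tractions)
    if nodal_loads is not None:
        F += nodal_loads
    if body_force is not None:
        F += _body_force_loads(mesh, body_force)
    rhs = F.ravel()
    n = K.shape[0]

    fixed, fixed_vals = _dirichlet_dofs(mesh, constraints)
    if len(fixed) == 0 and not nullspace_filter:
        raise SolverError(
            "singular system: 3 unconstrained rigid-body modes "
            "(2 translations + 1 rotation); add constraints or request "
            "the null-space filter")

    if nullspace_filter and len(fixed) == 0:
        x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
        C = np.zeros((n, 3))
        C[0::2, 0] = 1.0
        C[1::2, 1] = 1.0
        C[0::2, 2] = -y
        C[1::2, 2] = x
        A = sp.bmat([[K, sp.csr_matrix(C)],
                     [sp.csr_matrix(C.T), None]], format="csc")
        sol = spla.spsolve(A, np.concatenate([rhs, np.zeros(3)]))
        u = sol[:n]
        res = np.linalg.norm(K @ u - rhs + C @ sol[n:])
    else:
        free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
        u = np.zeros(n)
        u[fixed] = fixed_vals
        rhs_red = rhs[free] - K[:, fixed][free] @ fixed_vals
        Kff = K[free][:, free].tocsc()
        u[free] = spla.spsolve(Kff, rhs_red)
        res = np.linalg.norm(Kff @ u[free] - rhs_red)
    scale = max(np.linalg.norm(rhs), 1.0)
    rel = float(res / scale)
    if not np.isfinite(u).all():
        raise SolverError("solver produced non-finite velocities")
    if rel > max(tol, 1e-8):
        raise SolverError(f"solver residual {rel:.2e} above tolerance")
    return VelocityField(u.reshape(-1, 2), rel)


# --------------------------------------------------------------------------
# Lagrangian update and time loop
# --------------------------------------------------------------------------


def step(mesh: TriMesh, velocity: VelocityField, dt: float) -> TriMesh:
    """Explicit Lagrangian move: every vertex displaced by v*dt.

    Raises :class:`StepRejectedError` if any element would invert; the
    caller should halve dt or remesh.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = mesh.copy()
    new.vertices = mesh.vertices + dt * velocity.values
    if (new.signed_areas() <= 0).any():
        raise StepRejectedError("element inversion after move")
    return new


@dataclass
class DtPolicy:
    """CFL-limited adaptive explicit time step: dt = min(dt_max,
    cfl * h_min / max|v|)."""

    cfl: float = 0.2
    dt_max: float = 0.05
    dt_min: float = 1e-8


@dataclass
class StopCriteria:
    max_steps: int | None = None
    max_time: float | None = None
    quiescence_tol: float | None = None
    observable: tuple[str, float, str] | None = None  # (name, thr, "below"/"above")

    def __post_init__(self):
        if (self.max_steps is None and self.max_time is None
                and self.quiescence_tol is None and self.observable is None):
            raise ValueError("at least one stop criterion required")


@dataclass
class SimulationTrace:
    times: np.ndarray
    observables: dict[str, np.ndarray]
    max_speed: np.ndarray
    final_mesh: TriMesh
    snapshots: list[tuple[float, TriMesh]]
    stop_reason: str
    remesh_steps: list[int]
    wall_time: float


def run(mesh: TriMesh, material: MaterialModel, actuators: list,
        constraints: dict | None, dt_policy: DtPolicy,
        stop: StopCriteria, observables: dict | None = None,
        remesh_quality: float = 0.12, snapshot_every: int = 0,
        nullspace_filter: bool = False) -> SimulationTrace:
    """Advance the coupled solve/move/remesh loop.

    ``actuators`` is a list of objects with ``evaluate(mesh) ->
    list[BoundaryTraction]`` (see :mod:`morphofem.actuators`); they are
    re-evaluated on the deformed boundary every step, so the force term is
    advected with the flow.  ``observables`` maps names to callables
    ``f(mesh) -> float`` recorded once per step (and at t=0).
    """
    observables = observables or {}
    t = 0.0
    times = [0.0]
    obs: dict[str, list[float]] = {k: [f(mesh)] for k, f in observables.items()}
    speeds: list[float] = []
    snaps: list[tuple[float, TriMesh]] = []
    remeshes: list[int] = []
    reason = "max_steps"
    eff_quality = remesh_quality
    t0 = time.perf_counter()
    max_steps = stop.max_steps if stop.max_steps is not None else 10**6

    for istep in range(1, max_steps + 1):
        try:
            tr = []
            for a in actuators:
                tr.extend(a.evaluate(mesh))
            vel = assemble_and_solve(mesh, material, tr, constraints,
                                     nullspace_filter=nullspace_filter)
        except (SolverError, ValueError) as exc:
            raise SolverError(f"step {istep}: {exc}") from exc
        vmax = vel.max_speed()
        speeds.append(vmax)
        if stop.quiescence_tol is not None and vmax < stop.quiescence_tol:
            reason = "quiescence"
            break
        dt = min(dt_policy.dt_max,
                 dt_policy.cfl * mesh.min_edge_length() / max(vmax, 1e-300))
        if stop.max_time is not None:
            dt = min(dt, stop.max_time - t)
        if dt < dt_policy.dt_min:
            reason = "dt_underflow"
            break
        for _ in range(6):
            try:
                mesh = step(mesh, vel, dt)
                break
            except StepRejectedError:
                dt *= 0.5
        else:
            raise StepRejectedError(f"step {istep}: inversion persists "
                                    "after 6 dt halvings")
        t += dt
        if mesh.min_quality() < eff_quality:
            mesh = remesh_if_needed(mesh, eff_quality)
            remeshes.append(istep)
            q = mesh.min_quality()
            # anti-thrash: if retriangulation cannot reach the requested
            # quality (boundary vertices force slivers), lower the bar until
            # quality actually degrades further
            eff_quality = remesh_quality if q >= remesh_quality else 0.9 * q
        times.append(t)
        for k, f in observables.items():
            obs[k].append(f(mesh))
        if snapshot_every and istep % snapshot_every == 0:
            snaps.append((t, mesh.copy()))
        if stop.max_time is not None and t >= stop.max_time - 1e-14:
            reason = "max_time"
            break
        if stop.observable is not None:
            name, thr, mode = stop.observable
            val = obs[name][-1]
            if (mode == "below" and val < thr) or \
               (mode == "above" and val > thr):
                reason = f"observable_{mode}"
                break

    return SimulationTrace(
        np.asarray(times), {k: np.asarray(v) for k, v in obs.items()},
        np.asarray(speeds), mesh, snaps, reason, remeshes,
        time.perf_counter() - t0)


# --------------------------------------------------------------------------
# unit conversion (documentation-level; never used inside the solver)
# --------------------------------------------------------------------------


@dataclass
class UnitSystem:
    """Maps dimensionless model units to physical units.

    The simulation uses E* = 2 over a body dimension of 0.4 model units;
    redimensioned with a real body size and tissue modulus (~500 um,
    ~1000 Pa) this places the model in the physiological range.
    """

    length_scale: float = 500e-6 / 0.4      # metres per model length
    stress_scale: float = 1000.0 / 2.0      # pascals per model stress
    time_scale: float = 1.0 / 1e-3          # seconds per model time

    def length(self, x: float) -> float:
        return x * self.length_scale

    def stress(self, s: float) -> float:
        return s * self.stress_scale

    def time(self, t: float) -> float:
        return t * self.time_scale
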
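"""Boundary force actuators.

Each actuator translates one of the model's force mechanisms into traction
vectors (force per unit boundary length) sampled at the vertices of its
target chain, evaluated on the *current* deformed boundary:

* ``line_tension`` — Laplace force of a constant contractile tension T along
  a curved contour, ``t = -T kappa n`` (inward on a convex rim; the total
  force on a shrinking circular hole stays constant).
* ``normal_pressure`` — curvature-independent inward normal traction P (the
  total force decays with the perimeter).
* ``shear_pair`` — antagonistic tangential pulls: constant line-force +-F on
  the two arclength halves of the target segment, oriented head-on
  (``contract``) or outward (``extend``); an asymmetry ratio scales the
  second half.
* ``tension_gradient`` — tangential traction signed to point toward a given
  direction (the dorsal/median axis), modeling a tension maximum at the
  neural tube.
* ``neg_surface_tension`` — outward growth stress gamma * kappa**m (m = 1
  or 2) on convex parts of the external contour, the ridge-growth negative
  surface tension; concave parts are clamped to zero by default.

Sign conventions: positive magnitudes are contractile/inward for tension,
pressure and shear pairs, and outward for negative surface tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Chain, CurvatureField, TriMesh, boundary_curvature
from .mechanics import BoundaryTraction

KINDS = ("line_tension", "normal_pressure", "shear_pair",
         "tension_gradient", "extensional_shear", "neg_surface_tension")


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# per-kind traction rules (operate on a CurvatureField)
# --------------------------------------------------------------------------


def line_tension_traction(curv: CurvatureField, T: float) -> np.ndarray:
    """Laplace traction -T*kappa*n of a constant tension T."""
    return -T * curv.kappa[:, None] * curv.normal


def normal_pressure_traction(curv: CurvatureField, P: float) -> np.ndarray:
    """Uniform normal traction of magnitude P, curvature-independent.

    Positive P is contractile: on a convex outer contour it points into the
    material (-n), while on a hole rim (a closed chain with total turning
    -2 pi) it points centripetally into the void (+n), so a wound closes.
    Corner vertices inherit the averaged vertex normal (half-angle
    bisector).
    """
    out = np.empty_like(curv.normal)
    for sl, closed in curv.per_chain():
        sign = 1.0
        if closed:
            s = curv.s[sl]
            seg = np.diff(np.append(s, s[-1] + (s[1] - s[0])))
            ds = 0.5 * (seg + np.roll(seg, 1))
            if float(np.sum(curv.kappa[sl] * ds)) < 0:
                sign = -1.0
        out[sl] = -P * sign * curv.normal[sl]
    return out


def shear_pair_traction(curv: CurvatureField, F: float,
                        asymmetry: float = 1.0,
                        sense: str = "contract") -> np.ndarray:
    """Antagonistic tangential tractions +-F*t on the two arclength halves.

    ``contract``: both halves point toward the arclength midpoint;
    ``extend``: both point away (negative shearing, oriented outwardly).
    ``asymmetry`` scales the second half (in chain order).
    """
    if sense not in ("contract", "extend"):
        raise ConfigurationError(f"unknown sense {sense!r}")
    out = np.zeros_like(curv.tangent)
    for sl, _closed in curv.per_chain():
        s = curv.s[sl]
        if len(s) < 4:
            raise ConfigurationError("shear_pair target needs >= 4 vertices")
        mid = 0.5 * (s[0] + s[-1])
        sign = np.where(s < mid, 1.0, -1.0)
        sign[np.isclose(s, mid)] = 0.0
        mag = np.where(s < mid, F, F * asymmetry)
        out[sl] = (sign * mag)[:, None] * curv.tangent[sl]
    if sense == "extend":
        out = -out
    return out


def extensional_shear_traction(curv: CurvatureField, F: float,
                               asymmetry: float = 1.0) -> np.ndarray:
    """Outward-oriented shear pair (neural-tube extension along an edge)."""
    return shear_pair_traction(curv, F, asymmetry, sense="extend")


def tension_gradient_traction(curv: CurvatureField, strength: float,
                              direction) -> np.ndarray:
    """Tangential traction of the given magnitude, signed so that it points
    toward ``direction`` (zero where the tangent is orthogonal to it)."""
    d = np.asarray(direction, float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ConfigurationError("direction must be a nonzero vector")
    d = d / n
    sgn = np.sign(curv.tangent @ d)
    return strength * sgn[:, None] * curv.tangent


def neg_surface_tension_traction(curv: CurvatureField, gamma: float,
                                 m: int = 1,
                                 clamp_concave: bool = True) -> np.ndarray:
    """Outward growth traction gamma*kappa**m*n on convex boundary."""
    if m not in (1, 2):
        raise ConfigurationError("growth exponent m must be 1 or 2")
    kap = curv.kappa
    if clamp_concave:
        kap = np.maximum(kap, 0.0)
    return gamma * (kap**m)[:, None] * curv.normal


# --------------------------------------------------------------------------
# declarative actuator
# --------------------------------------------------------------------------


@dataclass
class Actuator:
    """One boundary force term bound to a labeled chain.

    ``params`` holds the kind-specific scalars: T, P, F, asymmetry, sense,
    strength, direction, gamma, m, clamp_concave.  Referencing a label the
    mesh does not carry is a configuration error, never a silent no-op.
    """

    kind: str
    target: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown actuator kind {self.kind!r}")

    def tractions(self, curv: CurvatureField) -> np.ndarray:
        p = self.params
        if self.kind == "line_tension":
            return line_tension_traction(curv, p["T"])
        if self.kind == "normal_pressure":
            return normal_pressure_traction(curv, p["P"])
        if self.kind == "shear_pair":
            return shear_pair_traction(curv, p["F"],
                                       p.get("asymmetry", 1.0),
                                       p.get("sense", "contract"))
        if self.kind == "extensional_shear":
            return extensional_shear_traction(curv, p["F"],
                                              p.get("asymmetry", 1.0))
        if self.kind == "tension_gradient":
            return tension_gradient_traction(curv, p["strength"],
                                             p["direction"])
        if self.kind == "neg_surface_tension":
            return neg_surface_tension_traction(curv, p["gamma"],
                                                p.get("m", 1),
                                                p.get("clamp_concave", True))
        raise ConfigurationError(self.kind)

    def evaluate(self, mesh: TriMesh) -> list[BoundaryTraction]:
        """Tractions on the current deformed boundary, one BoundaryTraction
        per chain carrying the target label."""
        try:
            curv = boundary_curvature(mesh, self.target)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        vals = self.tractions(curv)
        if self.target == "all-external":
            chains = [Chain("all-external", mesh.external_loop(), closed=True)]
        else:
            chains = mesh.chains_for(self.target)
        out = []
        for (sl, _), ch in zip(curv.per_chain(), chains):
            out.append(BoundaryTraction(ch, vals[sl]))
        return out

    def to_dict(self) -> dict:
        p = dict(self.params)
        if "direction" in p:
            p["direction"] = [float(x) for x in p["direction"]]
        return {"kind": self.kind, "target": self.target, "params": p}

    @classmethod
    def from_dict(cls, d: dict) -> "Actuator":
        return cls(d["kind"], d["target"], dict(d.get("params", {})))
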
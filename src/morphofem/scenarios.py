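"""Config-driven scenario presets.

Each preset packages one of the model's numerical experiments — wound-ring
closure, crenel-to-ear contraction and its variants, mouth invagination,
neck flexure, curvature-driven nasal growth, free normal+tangential
morphing, and the placode-nucleated dorsal buckling — as a fully
serialisable :class:`ScenarioConfig`.  Absolute force magnitudes in living
embryos are not measurable at this level of description, so preset
magnitudes are order-unity defaults chosen to express each qualitative
regime; they are config values, not constants.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .actuators import Actuator
from .analysis import shape_metrics
from .geometry import PlacodeSpec, TriMesh, boundary_curvature, build_annulus, build_body
from .mechanics import (DtPolicy, MaterialModel, SimulationTrace, StopCriteria,
                        run)


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation run.

    Round-trips bit-exactly through YAML (sorted keys, plain scalars).
    ``seed`` is reserved for stochastic meshing; the built-in mesh
    generators are deterministic, so runs are reproducible bit-for-bit.
    """

    name: str
    geometry: dict
    material: dict = field(default_factory=lambda: {"stiffness_analog": 2.0,
                                                    "poisson_analog": 0.45})
    actuators: list = field(default_factory=list)
    constraints: dict = field(default_factory=dict)
    dt: dict = field(default_factory=lambda: {"cfl": 0.2, "dt_max": 0.02})
    stop: dict = field(default_factory=dict)
    remesh_quality: float = 0.12
    output: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "geometry": copy.deepcopy(self.geometry),
            "material": copy.deepcopy(self.material),
            "actuators": copy.deepcopy(self.actuators),
            "constraints": copy.deepcopy(self.constraints),
            "dt": copy.deepcopy(self.dt),
            "stop": copy.deepcopy(self.stop),
            "remesh_quality": self.remesh_quality,
            "output": self.output,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad scenario config: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True,
                              default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        return cls.from_yaml(Path(path).read_text())


# --------------------------------------------------------------------------
# geometry / material realisation
# --------------------------------------------------------------------------


def build_geometry(config: ScenarioConfig) -> TriMesh:
    g = dict(config.geometry)
    kind = g.pop("kind", None)
    if kind == "annulus":
        return build_annulus(**g)
    if kind == "body":
        placodes = [PlacodeSpec(**p) for p in g.pop("placodes", [])]
        return build_body(placodes=placodes, **g)
    raise ConfigError(f"unknown geometry kind {kind!r}")


def build_material(config: ScenarioConfig) -> MaterialModel:
    softness = {}
    for i, p in enumerate(config.geometry.get("placodes", [])):
        f = p.get("softness", 1.0)
        if 0.0 < f < 1.0:
            softness[i + 1] = f
    m = dict(config.material)
    m.setdefault("softness", softness)
    return MaterialModel(**m)


def _stop_from_dict(d: dict) -> StopCriteria:
    obs = d.get("observable")
    return StopCriteria(
        max_steps=d.get("max_steps"),
        max_time=d.get("max_time"),
        quiescence_tol=d.get("quiescence_tol"),
        observable=tuple(obs) if obs else None,
    )


# --------------------------------------------------------------------------
# observables
# --------------------------------------------------------------------------


def hole_radius(mesh: TriMesh) -> float:
    """Effective wound radius: hole-loop perimeter / 2 pi (robust to
    non-circularity)."""
    return mesh.perimeter("hole") / (2 * np.pi)


def _laplace_total_force(mesh: TriMesh, T: float) -> float:
    """Integral of |T kappa| along the hole rim (edge-lumped)."""
    curv = boundary_curvature(mesh, "hole")
    pts = mesh.vertices[curv.indices]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    ds = 0.5 * (seg + np.roll(seg, 1))
    return float(np.sum(np.abs(T * curv.kappa) * ds))


def _observables_for(config: ScenarioConfig, mesh: TriMesh) -> dict:
    obs: dict = {}
    labels = set(mesh.labels)
    if "hole" in labels:
        obs["hole_radius"] = hole_radius
        for a in config.actuators:
            if a["kind"] == "line_tension":
                T = a["params"]["T"]
                obs["total_force"] = lambda m, T=T: _laplace_total_force(m, T)
            elif a["kind"] == "normal_pressure":
                P = a["params"]["P"]
                obs["total_force"] = \
                    lambda m, P=P: abs(P) * m.perimeter("hole")
    if "ear_base" in labels:
        obs["ear_base_length"] = lambda m: m.chain_length("ear_base")
        if not all(c.internal for c in mesh.chains_for("ear_base")):
            # absent placode tissue: the contracting base is free boundary
            # and digs a slit; track its depth and depth/width aspect
            obs["slit_depth"] = \
                lambda m: shape_metrics(m, "ear_base")["deflection_in"]

            def slit_aspect(m):
                sm = shape_metrics(m, "ear_base")
                return sm["deflection_in"] / max(sm["chord_length"], 1e-12)

            obs["slit_aspect"] = slit_aspect
    if (mesh.tri_tags == 1).any():
        obs["ear_area"] = lambda m: shape_metrics(m, 1)["area"]
        obs["ear_centroid_y"] = lambda m: shape_metrics(m, 1)["centroid"][1]
        obs["ear_aspect_ratio"] = lambda m: shape_metrics(m, 1)["aspect_ratio"]
        obs["ear_isoperimetric"] = \
            lambda m: shape_metrics(m, 1)["isoperimetric_ratio"]
    if "mouth" in labels:
        obs["mouth_deflection"] = \
            lambda m: shape_metrics(m, "mouth")["deflection_in"]
        obs["mouth_extension"] = \
            lambda m: shape_metrics(m, "mouth")["deflection_out"]
    if "dorsal" in labels:
        obs["dorsal_bulge"] = \
            lambda m: shape_metrics(m, "dorsal")["deflection_out"]
        obs["dorsal_length"] = lambda m: m.chain_length("dorsal")
    obs["area"] = lambda m: m.area()
    return obs


# --------------------------------------------------------------------------
# runner
# --------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: ScenarioConfig
    initial_mesh: TriMesh
    trace: SimulationTrace
    metrics: dict

    @property
    def final_mesh(self) -> TriMesh:
        return self.trace.final_mesh


def run_preset(config: ScenarioConfig, snapshot_every: int = 0) -> SimulationResult:
    """Build the scenario's geometry, run the actuated quasi-static loop,
    and collect the scenario's observables and final-state metrics."""
    mesh = build_geometry(config)
    material = build_material(config)
    acts = [Actuator.from_dict(a) for a in config.actuators]
    observables = _observables_for(config, mesh)
    trace = run(mesh.copy(), material, acts, config.constraints,
                DtPolicy(**config.dt), _stop_from_dict(config.stop),
                observables, remesh_quality=config.remesh_quality,
                snapshot_every=snapshot_every)
    metrics = {name: float(series[-1])
               for name, series in trace.observables.items()}
    result = SimulationResult(config, mesh, trace, metrics)
    if config.output:
        _write_outputs(result)
    return result


def _write_outputs(result: SimulationResult) -> None:
    out = Path(result.config.output)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_trace_csv(result.trace, out / "observables.csv")
    mio.write_boundary_csv(result.final_mesh, out / "boundary.csv")
    mio.write_vtk(result.final_mesh, out / "final.vtk")
    mio.write_ply(result.final_mesh, out / "final.ply")
    mio.write_run_metadata(result.config, result.trace, out / "run.json")
    for i, (t, snap) in enumerate(result.trace.snapshots):
        mio.write_vtk(snap, out / f"snapshot_{i:04d}.vtk")


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------


_BODY_GEOM = {"kind": "body", "length": 2.0, "height": 1.0,
              "corner_smoothing_radius": 0.0, "target_edge_length": 0.06,
              "placodes": []}
_CRENEL = {"position": 1.0, "width": 0.3, "depth": 0.3,
           "shape": "crenel", "softness": 1.0}
_HEAD_RADIUS = 0.15           # corner smoothing for growth scenarios
_NASAL_GAMMA = 0.15           # gamma * (1/rc) ~ 1: order-unity tip traction


def _body(placodes=(), smoothing=0.0, h=0.06) -> dict:
    g = copy.deepcopy(_BODY_GEOM)
    g["placodes"] = [copy.deepcopy(p) for p in placodes]
    g["corner_smoothing_radius"] = smoothing
    g["target_edge_length"] = h
    return g


def _cfg(name, geometry, actuators, stop, constraints=None, **kw):
    return ScenarioConfig(
        name=name, geometry=geometry, actuators=actuators,
        constraints=constraints or {"fixed_labels": ["neck"]},
        stop=stop, **kw)


def _wound(name: str, actuator: dict) -> ScenarioConfig:
    return _cfg(
        name,
        {"kind": "annulus", "outer_radius": 1.0, "hole_radius": 0.3,
         "target_edge_length": 0.07},
        [actuator],
        {"max_steps": 2000, "max_time": 10.0,
         "observable": ["hole_radius", 0.1, "below"]},
        constraints={"fixed_labels": ["outer"]},
        dt={"cfl": 0.2, "dt_max": 0.01},
    )


def preset_wound_ring_tension() -> ScenarioConfig:
    return _wound("wound_ring_tension",
                  {"kind": "line_tension", "target": "hole",
                   "params": {"T": 1.0}})


def preset_wound_ring_pressure() -> ScenarioConfig:
    # pressure matched to the tension preset's initial total force:
    # 2*pi*T = 2*pi*r0*P  =>  P = T / r0
    return _wound("wound_ring_pressure",
                  {"kind": "normal_pressure", "target": "hole",
                   "params": {"P": 1.0 / 0.3}})


_EAR_PULL = {"kind": "shear_pair", "target": "ear_base",
             "params": {"F": 2.0, "asymmetry": 1.0, "sense": "contract"}}
_MOUTH_PULL = {"kind": "shear_pair", "target": "mouth",
               "params": {"F": 1.0, "asymmetry": 1.0, "sense": "contract"}}


def preset_crenel_ear() -> ScenarioConfig:
    return _cfg("crenel_ear", _body([_CRENEL]),
                [copy.deepcopy(_EAR_PULL)],
                {"max_steps": 1500, "max_time": 3.0})


def preset_crenel_ear_gradient() -> ScenarioConfig:
    c = preset_crenel_ear()
    c.name = "crenel_ear_gradient"
    c.actuators.append({"kind": "tension_gradient", "target": "ear_crenel",
                        "params": {"strength": 0.15, "direction": [0.0, 1.0]}})
    return c


def preset_crenel_ear_asym() -> ScenarioConfig:
    c = preset_crenel_ear()
    c.name = "crenel_ear_asym"
    # 2:1 antero-posterior asymmetry of the dorso-ventral pull
    c.actuators[0]["params"]["asymmetry"] = 0.5
    return c


def preset_slit_ear() -> ScenarioConfig:
    c = preset_crenel_ear()
    c.name = "slit_ear"
    c.geometry["placodes"][0]["softness"] = 0.0    # absent tissue
    # the contracting base digs a narrow invagination; halt once it has
    # contracted to half its length, before the slit flanks touch
    c.stop["observable"] = ["ear_base_length", 0.15, "below"]
    return c


def preset_mouth() -> ScenarioConfig:
    return _cfg("mouth", _body(),
                [copy.deepcopy(_MOUTH_PULL)],
                {"max_steps": 1200, "max_time": 1.2})


def preset_mouth_plus_ear() -> ScenarioConfig:
    return _cfg("mouth_plus_ear", _body([_CRENEL]),
                [copy.deepcopy(_MOUTH_PULL), copy.deepcopy(_EAR_PULL)],
                {"max_steps": 1200, "max_time": 1.2})


def preset_neck_ventral() -> ScenarioConfig:
    return _cfg("neck_ventral", _body(),
                [copy.deepcopy(_MOUTH_PULL),
                 {"kind": "shear_pair", "target": "ventral",
                  "params": {"F": 1.0, "sense": "contract"}}],
                {"max_steps": 1200, "max_time": 1.2})


def preset_neck_dorsal() -> ScenarioConfig:
    c = preset_neck_ventral()
    c.name = "neck_dorsal"
    c.actuators.append({"kind": "shear_pair", "target": "dorsal",
                        "params": {"F": 0.5, "sense": "contract"}})
    return c


def preset_dorsal_extension() -> ScenarioConfig:
    return _cfg("dorsal_extension", _body(),
                [copy.deepcopy(_MOUTH_PULL),
                 {"kind": "extensional_shear", "target": "dorsal",
                  "params": {"F": 0.5}}],
                {"max_steps": 1200, "max_time": 1.2})


def preset_nasal_process_linear() -> ScenarioConfig:
    return _cfg("nasal_process_linear", _body(smoothing=_HEAD_RADIUS),
                [{"kind": "neg_surface_tension", "target": "mouth",
                  "params": {"gamma": _NASAL_GAMMA, "m": 1}}],
                {"max_steps": 800, "max_time": 0.8})


def preset_nasal_process_quadratic() -> ScenarioConfig:
    c = preset_nasal_process_linear()
    c.name = "nasal_process_quadratic"
    # matched initial tip traction: gamma2 * k0^2 = gamma1 * k0,
    # k0 = 1/smoothing radius
    c.actuators[0]["params"] = {"gamma": _NASAL_GAMMA * _HEAD_RADIUS, "m": 2}
    return c


def preset_free_morph() -> ScenarioConfig:
    return _cfg("free_morph", _body(smoothing=_HEAD_RADIUS),
                [{"kind": "normal_pressure", "target": "mouth",
                  "params": {"P": -0.8}},        # negative = outward growth
                 {"kind": "tension_gradient", "target": "mouth",
                  "params": {"strength": 0.4, "direction": [0.0, 1.0]}}],
                {"max_steps": 800, "max_time": 0.8})


def preset_buckling_bulge() -> ScenarioConfig:
    return _cfg("buckling_bulge", _body([_CRENEL]),
                [{"kind": "neg_surface_tension", "target": "dorsal",
                  "params": {"gamma": 0.3, "m": 1}},
                 {"kind": "shear_pair", "target": "ear_base",
                  "params": {"F": 0.3, "sense": "contract"}}],
                {"max_steps": 1000, "max_time": 1.0})


PRESETS = {
    "wound_ring_tension": preset_wound_ring_tension,
    "wound_ring_pressure": preset_wound_ring_pressure,
    "crenel_ear": preset_crenel_ear,
    "crenel_ear_gradient": preset_crenel_ear_gradient,
    "crenel_ear_asym": preset_crenel_ear_asym,
    "slit_ear": preset_slit_ear,
    "mouth": preset_mouth,
    "mouth_plus_ear": preset_mouth_plus_ear,
    "neck_ventral": preset_neck_ventral,
    "neck_dorsal": preset_neck_dorsal,
    "dorsal_extension": preset_dorsal_extension,
    "nasal_process_linear": preset_nasal_process_linear,
    "nasal_process_quadratic": preset_nasal_process_quadratic,
    "free_morph": preset_free_morph,
    "buckling_bulge": preset_buckling_bulge,
}


def get_preset(name: str, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown scenario {name!r}; available: "
                          f"{sorted(PRESETS)}")
    c = PRESETS[name]()
    for k, v in overrides.items():
        if not hasattr(c, k):
            raise ConfigError(f"unknown config field {k!r}")
        setattr(c, k, v)
    return c
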
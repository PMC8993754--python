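"""Shared fixtures: scenario runs are expensive, so each preset is run once
per session and shared between the scenario tests and the acceptance suite."""

from __future__ import annotations

import pytest

import morphofem as mf


def _run(name, **overrides):
    cfg = mf.get_preset(name)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return mf.run_preset(cfg)


@pytest.fixture(scope="session")
def wound_tension_run():
    return _run("wound_ring_tension")


@pytest.fixture(scope="session")
def wound_pressure_run():
    return _run("wound_ring_pressure")


@pytest.fixture(scope="session")
def crenel_runs():
    """crenel_ear at two mesh resolutions, keyed by target edge length."""
    out = {}
    for h in (0.06, 0.05):
        cfg = mf.get_preset("crenel_ear")
        cfg.geometry["target_edge_length"] = h
        out[h] = mf.run_preset(cfg)
    return out


@pytest.fixture(scope="session")
def slit_run():
    return _run("slit_ear")


@pytest.fixture(scope="session")
def gradient_run():
    return _run("crenel_ear_gradient")


@pytest.fixture(scope="session")
def mouth_run():
    return _run("mouth")


@pytest.fixture(scope="session")
def neck_ventral_run():
    return _run("neck_ventral")


@pytest.fixture(scope="session")
def nasal_runs():
    return {"linear": _run("nasal_process_linear"),
            "quadratic": _run("nasal_process_quadratic")}


@pytest.fixture(scope="session")
def buckling_runs():
    """Placode-winding run and its no-winding control."""
    with_winding = _run("buckling_bulge")
    cfg = mf.get_preset("buckling_bulge")
    cfg.actuators = [a for a in cfg.actuators if a["kind"] != "shear_pair"]
    control = mf.run_preset(cfg)
    return {"winding": with_winding, "control": control}
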
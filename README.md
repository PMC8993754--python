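# morphofem

A 2D quasi-static viscous finite-element simulator of early vertebrate
morphogenesis driven by a *biaxial* pattern of boundary tensions.

Early embryonic tissue behaves, on developmental time scales, as a creeping
viscous sheet.  Morphogenesis of the body outline — wound-like ring closure,
formation of ears and eyes from crenel-shaped placodes, mouth invagination,
neck flexure, and the outgrowth of nasal processes — can be reproduced at a
qualitative level by a small set of contractile and extensile force
actuators acting along two orthogonal families of lines (rings and rays)
inherited from the first cleavages.  `morphofem` implements that model for
researchers in tissue biomechanics and developmental biophysics who want a
small, fully scriptable sandbox for boundary-force-driven morphogenesis.

## Model

The tissue obeys a viscous Hooke-analog constitutive law

    sigma = H : (d eps / dt),        div sigma = 0,

where `H` is a plane-stress-style matrix built from a stiffness-analog `E*`
(default 2 over a body dimension of 0.4 model units, matching the ~1000 Pa
range of embryonic tissue once redimensioned) and a Poisson-analog `nu*`
(default 0.45).  At each instant the velocity field balances the boundary
forces exactly (no inertia); the Lagrangian mesh is then advected,
`x <- x + v dt`, and the force terms are re-evaluated on the deformed
boundary, so every contraction shrinks its own source — the model's
signature *self-arrest*.

Boundary force actuators (all per unit boundary length, evaluated on the
current contour):

| actuator              | traction                       | regime it drives |
|-----------------------|--------------------------------|------------------|
| `line_tension`        | `-T kappa n` (Laplace force)   | linear ring closure (total force constant) |
| `normal_pressure`     | `-P n` (centripetal)           | exponential ring closure (total force ~ perimeter) |
| `shear_pair`          | `+-F t` on two arclength halves| crenel-to-ear winding, mouth invagination, neck flexure; `dL/dt ~ -L`, `L ~ exp(-t/tau)` |
| `tension_gradient`    | tangential, toward a direction | dorsal-ward advection of the ear territory |
| `extensional_shear`   | outward shear pair             | dorsal/neural extension |
| `neg_surface_tension` | `+gamma kappa^m n`, `m` = 1, 2 | curvature-driven ridge growth; `m = 2` elongates (trunk-like feedback) |

A standalone closed-form module provides the quadrupolar stream function of
two head-on pulling source lines,

    Psi(x,y) = alpha ln((x-a)^2+(y-b)^2) - alpha ln((x-a)^2+(y+b)^2)
             - beta  ln((x-c)^2+(y-b)^2) + beta  ln((x-c)^2+(y+b)^2),

with `(u, v) = (dPsi/dy, -dPsi/dx)` — the non-self-consistent potential-flow
picture of ear winding, used as an independent cross-check.

## Worked example

```sh
python examples/wound_closure.py
```

prints

```
wound_ring_tension:
  hole radius 0.300 -> 0.099 over t = 0.340 (54 steps)
  selected closure law: linear (speed = 0.610)
  total inward force 6.280 -> 6.275
wound_ring_pressure:
  hole radius 0.300 -> 0.100 over t = 0.556 (58 steps)
  selected closure law: exponential (tau = 0.489)
  total inward force 6.280 -> 2.087
```

Both runs start from the same total centripetal force (2 pi T with T = 1).
Under constant tension the Laplace pressure `T kappa` grows exactly as the
perimeter shrinks, the total force stays constant (6.280 -> 6.275, i.e.
within 0.1%), and the hole heals linearly at speed 0.61 model units per
unit time.  Under constant pressure the total force decays with the
perimeter and the same closure takes the exponential form
`R ~ exp(-t/0.49)` — the dichotomy that AIC-based model selection in
`fit_closure_law` detects.  The other examples
(`ear_from_crenel.py`, `quadrupole_flow.py`, `nasal_growth.py`) walk
through the self-arresting ear contraction, the passive winding flow and
the curvature-growth regimes the same way.

Scenario presets are also runnable from the shell:

```sh
morphofem run --scenario crenel_ear --out out/
morphofem fit-closure out/observables.csv --value-col ear_base_length
morphofem flow --alpha 1 --beta 0.6
```

## Layout

- `src/morphofem/geometry.py` — meshes, labeled boundary chains, discrete
  curvature, quality-triggered remeshing
- `src/morphofem/mechanics.py` — P1 assembly/solve of `div sigma = 0`,
  Lagrangian stepping, the run loop
- `src/morphofem/actuators.py` — the boundary force mechanisms
- `src/morphofem/quadflow.py` — the closed-form quadrupole flow
- `src/morphofem/analysis.py` — closure-law fits (AIC), shape metrics,
  regime comparison
- `src/morphofem/scenarios.py` — declarative, YAML-round-trippable presets
- `docs/methods.md` — modeling assumptions, parameter defaults, numerics
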
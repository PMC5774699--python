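# seadrift

Individual-based Lagrangian modelling of marine organisms: offline particle
tracking in gridded or analytic flow fields, larval behavior models,
hydrographic backtracking, habitat-connectivity estimation, ocean-parameter
extraction, and a posterior Eulerian advection–diffusion–reaction solver.

`seadrift` is aimed at fisheries and marine ecologists who ask transport
questions about early life stages — where do eggs spawned *here* end up,
where did larvae observed *there* come from, how strongly are two habitats
connected by drift — using stored output of an ocean circulation model (or
closed-form test flows) as the physical forcing.

## The model

Each particle *i* carries a position **x**ᵢ and an internal state **s**ᵢ
(age, stage, length, survival weight, …) updated per time step *dt* as

```
dxᵢ = (uᵢ + wᵢ) dt + ∇Kᵢ dt + ρ √(2 K(xᵢ + ½∇Kᵢ dt) dt)
dsᵢ = Gᵢ dt
```

where **u**ᵢ and *K*ᵢ are the local current and eddy diffusivity served by a
*physics provider*, **w**ᵢ and *G*ᵢ are the active swimming velocity and
state increment rate of a *biology model*, and ρ is a unit-variance random
deviate drawn per axis.  The ∇*K* drift plus midpoint evaluation of *K* is
the diffusivity-gradient (Visser) correction: without it, a spatially
varying *K* artificially aggregates passive tracers at diffusivity minima
(the "well-mixed condition" diagnostic).

On top of this kinematic core the package provides four task drivers:

* **simulate / backtrack** — forward ensemble propagation, or adjoint
  backtracking by reversing (**u**ᵢ, *G*ᵢ) while keeping diffusion
  forward-diffusive (anti-diffusion is ill-posed);
* **connectivity** — release *R*ᵢ propagules in each source habitat *i*,
  tally survival-weighted settlements *N*ⱼᵢ at first entry into sink *j*
  while competent, and estimate the transport probability matrix
  *T*ⱼᵢ = *N*ⱼᵢ / *R*ᵢ;
* **extract** — region/period statistics (mean/min/max/count) of any scalar
  field the provider registers;
* **eulerian** — a conservative finite-volume solver for
  ∂C/∂t = −∇·(uC − K∇C) + Ĝ(C) in a box, with logistic and
  logistic-plus-grazing reaction operators.

Reference biology models: a passive particle (the null model), a diel
vertical migrator (10 m at night and dusk, 40 m by day), and a staged larva
with a ~two-week non-feeding egg phase, hatching at 3 mm, linear growth
with age, DVM from two weeks post-hatch, a settlement-competency window and
optional constant mortality.

## Worked example: a two-sink connectivity matrix

Release 500 staged larvae (immediately competent, mortality 0.1 d⁻¹) in a
spawning box and let a 0.5 m s⁻¹ eastward current with 50 m² s⁻¹ horizontal
eddy diffusivity carry them toward two downstream nursery boxes:

```python
from datetime import datetime
import seadrift as sd
from seadrift.tasks import Habitat, HabitatSet, compute_connectivity

prov = sd.UniformFlow(u=0.5, Kh=50.0, bounds=(-1, 1, -1, 1), water_depth=100.0)
habitats = HabitatSet([
    Habitat.from_box("banks",     0.0, 0.1, -0.1, 0.1, role="source"),
    Habitat.from_box("nursery_s", 0.5, 0.7, -0.2, 0.0, role="sink"),
    Habitat.from_box("nursery_n", 0.5, 0.7,  0.0, 0.2, role="sink"),
])
bio = sd.StagedLarva(egg_duration=0.0, yolk_duration=0.0, competency_age=0.0,
                     dvm_onset=1e9, mortality=0.1)
cfg = sd.StepConfig(dt=600.0, scheme="rk2", seed=42)
M = compute_connectivity(habitats, prov, bio, cfg, datetime(2004, 1, 1),
                         n_steps=250, releases_per_source=500)
print(M.T.round(4))
print(M.accounting)
```

prints

```
            banks
nursery_s  0.4232
nursery_n  0.4664

       released  settled  active  deactivated_other
banks       500      500       0                  0
```

Every propagule settled (accounting conserves particles); the split between
the two nurseries reflects the diffusive spreading across the dividing
latitude, and the entries sum to less than 1 because each settlement is
weighted by the larva's survival weight e^(−m·t) at arrival
(m = 0.1 d⁻¹ over ≈1.7 days of drift).

The same run is available from the shell: write a single TOML configuration
and call `seadrift connectivity -c run.toml` (subcommands: `simulate`,
`backtrack`, `connectivity`, `extract`, `eulerian`, `make-fixture`; any key
can be overridden with `--set step.dt=60`).  Identical configuration + seed
reproduces every output byte for byte, and each output file carries the
package version and a JSON echo of the configuration that produced it.

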
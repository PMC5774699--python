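# Methods

This note documents the models, numerical choices and validation design of
`seadrift`: what is computed, under which assumptions, and what the test
suite does and does not demonstrate.

## Particle kinematics

Particles are updated by the explicit per-step increment

    dx = (u + w) dt + ∇K dt + ρ √(2 K(x + ½∇K dt) dt)        (per axis)
    ds = G dt

with positions in geographic coordinates (longitude East on the
[−180, 180) branch, latitude North, depth in metres positive down) and all
lengths converted through a local spherical metric with R = 6 371 000 m
(metres per degree longitude = (2πR/360)·cos φ).  A sphere rather than an
ellipsoid is ample at the sub-basin scales of the test problems.

**Deterministic part.**  The advective + active velocity is integrated as
an ODE in (lon, lat, z) with Euler, RK2 (midpoint) or RK4; the metric
conversion is applied at each evaluation latitude.  The default is RK2 with
dt = 300 s, a standard configuration for shelf-sea larval tracking; dt must
not exceed the forcing frame spacing.  If an RK substep position leaves the
wet domain the step falls back to the Euler rate for that particle and the
event is counted (`rk_fallback`).  Active velocity **w** is evaluated once
per step at the start-of-step position; only the currents are re-evaluated
at substeps.  The RK2 order is verified on a solid-body-rotation orbit
(closure error after one period falls by ≈4× when dt halves).

**Stochastic part.**  The random walk uses Euler–Maruyama with the
diffusivity-gradient correction applied independently per axis: the drift
term (∂K/∂a)·dt plus evaluation of K at the half-gradient-offset point
a + ½(∂K/∂a)dt.  ρ is standard normal by default; a uniform deviate on
[−√3, √3] (unit variance) is available — both satisfy the diffusion limit.
Horizontal displacements are computed in metric metres, then converted to
degrees at the particle latitude.  The deterministic and stochastic
displacements are both computed from the start-of-step position, summed,
and boundaries are enforced once on the combined candidate, matching the
single-increment form of the update rule.  A diagnostic switch
(`StepConfig(gradient_correction=False)`) reproduces the naive walk for
well-mixed-condition comparisons; it is never the default.

**Backtracking** reverses the current and the biology (u → −u, w → −w,
G → −G) while applying the random walk with positive K: turbulence spreads
an ensemble in backward time exactly as in forward time, and reversing it
(anti-diffusion) would be ill-posed.  With K = 0 and a steady flow the
forward-then-backward composition error is O(dt²) per the RK2 scheme; the
staged-larva state reverses through the same thresholds, restoring the
discrete state (stage) exactly and the continuous state (age, length) to
floating-point roundoff (the additions are not exactly associative, so
"exact" recovery of a float accumulator is guaranteed only to ~1e−12 d).

**Boundaries.**  The vertical coordinate is mirrored into [0, wdepth] by
the closed form of repeated reflection (a triangle-wave fold — identical to
"reflect, re-check, clamp" for any displacement size).  Horizontal
violations are resolved against the rasterized coastline: the segment from
the old to the candidate position is walked cell by cell; the first
wet→land face yields the intersection, and the candidate is mirrored
specularly across that face.  Up to 5 mirrors are attempted (stair-step
corners can cascade); an unresolved cascade cancels the sub-step, leaving
the particle at its wet start position — never on land.  A segment exiting
exactly through a cell corner reflects across the face with the larger
penetration depth; an exact tie (measure zero) cancels the sub-step.
Policies `absorb` (deactivate as left_domain) and `sticky` (freeze) are
available per axis.  The coastline is the land mask of the provider's own
grid — a stair-step coast at forcing resolution, which makes the
face-crossing test exact; no vector shoreline is used.

## Physics providers

A provider serves currents, diffusivity (+gradient), named scalars,
bathymetry, the land mask and wet tests behind one interface; callers never
see grid indices or frame times.  Analytic providers (uniform flow, linear
shear, solid-body rotation, parabolic Kv profile, stair-coast basin) return
closed forms and analytic gradients, and double as trajectory oracles.

The gridded provider reads a regular lon–lat–z NetCDF file (cell-centred
coordinates, layer-centre depths, time frames; variables u, v and
optionally w, Kh, Kv plus any named scalars; integer/boolean land mask;
bathymetry).  On each clock update the two bracketing frames are blended
linearly and held, so every spatial query between updates sees one frozen
time.  Space interpolation is trilinear on the blended arrays; values at
grid nodes therefore reproduce file values to round-off, which the fixture
generator exploits: `generate_synthetic_hydrography` samples an analytic
field onto a grid, and the round trip through the file is checked to
≤1e−12.  Outside the outermost cell centres the interpolant clamps to the
edge value (no vertical extrapolation of surface gradients).  Diffusivity
gradients for gridded data are central finite differences of the
interpolant with a half-cell stencil; for a parabolic Kv profile this is
exact, which the tests use.  Vertical current w is positive down, matching
the depth axis.  Fill values (NaN) are treated as zero for interpolation;
the land mask, not the fill pattern, governs wet tests.

## Biology models

All models implement the same contract: state initialization, active
velocity **w**, and the state increment *G* (sign-reversed in backward
runs).  The passive particle is the null model; a run with it attached is
bit-identical to a run with no biology at all.

The day/night flag for vertical migration comes from a low-precision solar
ephemeris (declination from a day-of-year cosine, hour angle from UTC +
longitude; ~1° accuracy, ample for a flag).  The threshold is the geometric
horizon (elevation 0°) by default so that dusk groups with night — a
migrating larva holds its shallow night-time depth through dusk; a civil
twilight convention (−6°) is available via `twilight_deg`.

`DVMLarva` swims vertically toward 10 m when the sun is below the threshold
and 40 m in daylight, at `swim_speed` (default 5 mm s⁻¹ — the target depths
are the observable; the speed only sets how fast the target is reached and
is clamped so a larva can arrive within one step without overshoot).

`StagedLarva` (cod-like defaults):

| parameter        | default | units | meaning                                   |
|------------------|---------|-------|-------------------------------------------|
| `egg_duration`   | 14      | d     | non-feeding, passively dispersing egg phase |
| `hatch_length`   | 3       | mm    | length assigned at hatch                   |
| `growth`         | 0.2     | mm/d  | linear growth slope after hatch            |
| `yolk_duration`  | 5       | d     | yolk-sac phase after hatch                 |
| `dvm_onset`      | 14      | d post-hatch | age at which DVM behavior starts    |
| `competency_age` | 40      | d     | total age at which settlement opens        |
| `mortality`      | 0       | 1/d   | constant rate decaying the survival weight |
| `q10`            | off     | –     | optional Q10 scaling of development rate   |

Egg duration, hatch length and the DVM depths/onset are the
literature-anchored values for North Sea cod early life stages; the growth
slope, competency age and mortality are configurable placeholders — field
estimates vary and no single value is canonical, so they are parameters,
not hard-coded science.  Stages are a pure function of (developmental) age,
which makes the stage sequence monotone forward and exactly reversible
backward.  With Q10 scaling on, development accumulates at rate
Q10^((T−Tref)/10) using the provider's temperature field; the
configuration parser rejects the combination at parse time if the provider
lacks that field.

## Connectivity estimation

T[j, i] = N[j, i] / R[i], with R[i] propagules released uniformly over
source polygon i (rejection sampling against the polygon and the wet mask,
capped at 1000 rounds) and N[j, i] the sum of survival weights of
propagules whose *first* entry into sink j occurred while
settlement-eligible.  There is no re-suspension: a settled propagule is
deactivated at its settlement position.  Sink suitability thins first
entries by a seeded Bernoulli draw; a failed draw at sink j is not retried
at j, but the propagule keeps drifting and may settle elsewhere.  Because
habitats differ in size, the per-area matrix T/area(sink) is reported
alongside raw T.  Accounting (settled + active + otherwise deactivated =
released, per source) is asserted in the tests.  The estimator is binomial:
over repeated stochastic runs the standard deviation of T̂ scales as 1/√R,
which the suite checks by comparing replicate spreads at R = 50 and 200.

## Eulerian solver

∂C/∂t = −∇·(uC − K∇C) + Ĝ(C) on a uniform 1–3-D box grid in conservative
flux form: first-order upwind advective flux plus centred diffusive flux on
cell faces, zero-flux (closed) boundaries by default, explicit time
stepping under the checked CFL conditions max|u|·dt/Δx ≤ 1 and
2K·dt/Δx² ≤ 0.5 per axis.  The local reaction term is integrated with
Heun's explicit trapezoidal rule — still a local, explicit update, but it
tracks the logistic closed form to ~1e−8 where plain Euler leaves ~3e−4 at
the same step size.  Mass is conserved to round-off by construction;
the centred-diffusion second moment grows exactly as 2K·t while a plume is
unresolved by neither boundary, which the Gaussian-plume test uses.

Two boundary/velocity subtleties are worth stating plainly.  (1) In a
closed box, a velocity field with nonzero wall-normal component *must*
accumulate mass at the downstream wall — for any conservative scheme; the
"constants are preserved" property of upwind advection therefore holds for
wall-tangent, discretely divergence-free velocities, which the solver
supports directly through staggered face velocities (e.g. derived from a
streamfunction).  The constant-preservation and maximum-principle tests
use such a field.  (2) A steady grazing-depletion balance ("C recovers to
carrying capacity upstream") needs an upstream source; a closed advective
box simply flushes.  An optional Dirichlet advective-inflow boundary
(`inflow={axis: (value, value)}`) feeds the domain for that configuration;
the default remains fully closed.  The grazing steady state is validated
against an independent ODE integration of the steady balance
u·dC/dx = rC(1−C/Ccap) − g·m(x)·C (agreement ≤0.05·Ccap, limited by the
first-order upwind truncation at the chosen Δx).

Reaction rates (`r`, `grazing`) are configured in 1/day and converted to
1/s internally.

## Synthetic data and what the tests show

All validation forcing is generated in-process: analytic providers, and
NetCDF files written by `generate_synthetic_hydrography` whose node values
equal the generating field exactly.  These fields are steady or two-frame,
single-signed, and geometrically simple; they emulate the *interfaces and
invariants* of real hydrography (grids, masks, frames, units), not its
variability.  Passing tests therefore demonstrate correctness of the
numerics and bookkeeping — exact advection, diffusion limits, the
well-mixed condition, conservation and reversibility — but say nothing
about skill against observed drift, which depends entirely on the quality
of the operational forcing a user supplies.

Validation problem sizes (chosen to make Monte-Carlo error bars decisively
smaller than the tested effects): diffusion limit 1e5 particles × 1 h at
dt = 10 s (sample variance vs 2Kt within 3 standard errors of the χ²
sampling law); well-mixed condition 1e4 particles × 48 h at dt = 60 s under
the parabolic profile Kv = 1e−4 + 4e−6·z(50−z) m² s⁻¹, with the stationary
vertical distribution estimated from snapshots pooled hourly over the final
12 h — pooling is a variance reduction of the estimator (a single 1e4
snapshot has E[KS] ≈ 0.009 under perfect uniformity, leaving no margin to
the 0.01 criterion on pure sampling noise); the corrected walk stays below
0.01 while ablating the correction drives KS above 0.15 (density piling up
at the low-K walls); boundary stress 2000 particles × 520 steps
(1.04e6 particle-steps) of onshore flow + 100 m² s⁻¹ horizontal diffusion
against a diagonal stair coast, asserting zero dry rests and zero
unresolved reflection cascades.

## Reproducibility

Each run is fully determined by (configuration, seed): one RNG is seeded
per StepConfig, release sampling and settlement thinning derive their own
seeds from it, and identical configurations produce byte-identical
trajectory files (asserted through the CLI).  Outputs embed the package
version string and a compact JSON echo of the configuration.

## Known limitations

* Regular lon–lat–z grids only; no curvilinear, nested or unstructured
  meshes, and no online coupling to a running circulation model.
* The coastline is the forcing-grid land mask (stair-step), not a vector
  shoreline; reflection geometry is exact for that raster but resolution
  follows the forcing.
* One global dt per run; no per-particle adaptive stepping, and the
  stochastic term is Euler–Maruyama regardless of the deterministic scheme.
* Organisms respond only to ambient conditions — no schooling,
  gradient-following or other particle–particle interactions.
* The Eulerian solver is first-order in space and time by design;
  sharp-front accuracy is limited by upwind diffusion.
* The growth, competency and mortality defaults of the staged larva are
  placeholders to be calibrated per species and region.
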
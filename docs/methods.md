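# Methods

This note documents the models, numerical choices and limitations of
hemoflow in enough detail to reproduce or audit any number the package
computes.

## Scope and design

The package reimplements, at desk scale, the analysis chain used in
patient-specific CFD studies of aortic aneurysm/dissection: pulsatile
non-Newtonian flow driven by inlet-velocity and outlet-pressure
waveforms, wall-shear-stress (WSS) extraction, and the endothelial risk
indices TAWSS, OSI, RRT and ECAP. Patient CT geometry is out of scope;
synthetic 2-D domains replace it so that every stage can be verified
against analytic solutions or exactly invertible generators. Full 3-D
patient solves and turbulence-transport modelling are deliberately not
attempted: the verification value of the package comes from running in
regimes where exact references exist.

## Blood rheology

Carreau–Yasuda apparent viscosity
`mu(γ̇) = mu_inf + (mu_0 − mu_inf)·[1 + (λγ̇)²]^((n−1)/2)` with defaults
ρ = 1060 kg/m³, μ∞ = 0.0035 Pa·s, μ₀ = 0.056 Pa·s, λ = 3.313 s,
n = 0.3568. The exponent sign (n−1)/2 is the one for which μ → μ∞ as
γ̇ → ∞, i.e. μ∞ genuinely is the infinite-shear plateau. The shear-rate
magnitude is the standard generalized-Newtonian invariant
γ̇ = √(2 D:D) of the rate-of-deformation tensor D, which vanishes for
rigid rotation. A Newtonian fluid is the special case μ₀ = μ∞.

The k–ω SST closure quantities that appear in turbulent formulations —
`arg2 = max(2√k/(β*ωd), 500ν/(ωd²))`, `F2 = tanh(arg2²)`,
`μt = a1ρk / max(a1ω, S·F2)`, and the Boussinesq stress tensor
`τij = μt(∂ui/∂xj + ∂uj/∂xi − ⅔(∇·u)δij) − ⅔ρk δij` — are exposed as
pure functions with the standard constants a1 = 0.31, β* = 0.09. The k
and ω transport equations are not solved anywhere: the desk-scale cases
run at laminar Reynolds numbers, and the closure algebra is provided so
it can be evaluated and unit-tested in isolation.

## Geometry and meshing

Three synthetic vessel kinds, specified in millimetres and meshed as
structured quadrilateral grids in metres:

* **straight** — axisymmetric tube over 0 ≤ r ≤ R(z), with optional
  linear taper between the inlet and outlet diameters. Presets carry
  the measured pre-dissection aorta diameters (52.79 mm ascending,
  28.44 mm descending).
* **arch** — planar curved channel (annular sector) whose centreline
  length and bend angle set the curvature; a stand-in for the aortic
  arch used for meshing/export tooling.
* **dissected** — planar channel split by an intimal septum into a true
  lumen (fed by the inlet) and a false lumen (sealed at the inlet end,
  open at the outlet), connected through one or more tear openings in
  the septum. The preset carries the measured post-dissection lumen
  diameters (true 23.17→20.18 mm, false 44.55→19.11 mm). Septum
  thickness (default 2.5 mm) and tear geometry (default one tear at
  40 mm arc length, 15 mm opening) are package choices; the source
  measurements do not constrain them.

`resolution` counts cells across the inlet diameter; dissected lumen and
septum widths are snapped to whole cells (within one cell width), and a
septum thinner than one cell is rejected rather than silently lost.
Refinement splits each cell `factor`× per direction with bilinear node
insertion, so refining twice by 2 equals refining once by 4 to
round-off, and boundary tags cover the same curves. The default vessel
length (400 mm) is the order of an adult thoracic aortic centreline.

Meshes carry per-face tags (inlet / outlet / wall / septum / axis) and a
validity audit (positive cell Jacobians, tag coverage). Near-wall
resolution guidance: for the laminar 2-D grids here the relevant
criterion is cells across the Stokes layer δ = √(2ν/ω) rather than a
turbulent wall-unit (y⁺) target; the `wall_y_plus` diagnostic is
provided for comparability with wall-resolved turbulent practice.

## Flow solver

Staggered (MAC) finite volumes: axial velocity u on x-normal faces,
cross velocity v on y-normal faces, pressure in cell centres;
axisymmetric metric terms for tubes, planar otherwise. Time advance is
an incremental pressure-correction projection: explicit advection
(first-order upwind by default, central optional) and explicit
diffusion in the form ∇·(μ(γ̇)∇u), followed by a pressure-increment
Poisson solve (prefactorized sparse LU) and a divergence-free
correction. Because the projection is solved directly, the discrete
divergence — and hence the net boundary flux — of every state is at
round-off level; the mass-conservation checks assert < 1e-8 relative
and observe ~1e-16.

Boundary conditions: prescribed inlet velocity profile (parabolic for
tubes, flat for channels, or a user callable — the Womersley tests drive
the solver with the exact analytic profile); no-slip rigid walls; axis
symmetry; prescribed-pressure outlet with zero tangential stress.
Tangential no-slip at walls uses a one-sided quadratic ghost
(ghost = −2u₁ + u₂/3), making the wall viscous flux exact for parabolic
profiles and consistent with the WSS extraction below; this makes wall
shear second-order accurate (observed Poiseuille WSS errors 3.0 % →
0.78 % → 0.19 % over a 8/16/32 resolution ladder).

Pressure is solved as a gauge relative to the outlet value. For rigid
incompressible flow a spatially uniform, time-varying pressure offset
does not alter the velocity field, so the outlet waveform is applied
exactly by adding it back when probing — the probe pressures are
absolute mmHg.

Viscosity is lagged one Picard iteration within each step (recomputed
from the provisional field and iterated up to `max_inner_iterations`
until the scaled change falls below `residual_tolerance`, default
1e-5); for Newtonian runs a single pass is exact. Time step: explicit
stability limits for diffusion (with the 1.5× wall-ghost diagonal
accounted for) and advection are enforced every step; `time_step=None`
picks 40 % of the limit, and a user step that violates the limit raises
with a suggested value. Transient runs integrate `cycles` cardiac
cycles (default 3) and record the last on a uniform grid
(`n_record` samples, default 100); the cycle-to-cycle drift of the
cycle-mean velocity between the final two cycles is reported as a
diagnostic (< 1 % in the shipped verification runs). Steady solves
pseudo-time-march with the residual scaled by the cross-section's
viscous relaxation time.

Only rectilinear meshes (untapered tube, dissected channel) are
solvable; tapered and arch meshes are built, refined, audited and
exported but rejected by the solver. A conformal curvilinear solve adds
substantial machinery without adding verification value — no analytic
oracle exists for the arch, and the index pipeline is
geometry-agnostic — so the solver's scope was kept to the cases that
can be checked exactly.

## Wall shear stress and y⁺

Per wall face, the tangential velocity gradient normal to the wall is
the one-sided quadratic fit through the first two interior cell values
(distances Δ/2 and 3Δ/2): a = (9u₁ − u₂)/(3Δ), exact for parabolic
profiles. The WSS vector is μ(|a|)·a along the wall tangent; its sign
encodes instantaneous flow direction, so reversing (Womersley) flow
produces sign flips within the cycle. Wall y⁺ = (Δ/2)·u_τ/ν with
u_τ = √(|τw|/ρ); for non-Newtonian runs the wall viscosity uses a
two-step fixed-point estimate of the wall shear rate.

## Indices

Quadrature is the trapezoid rule on the uniform periodic grid, which on
an open grid (samples t_k = kT/n) equals the sample mean — exact for
piecewise-constant reversing series and second-order for smooth ones.
The OSI numerator integrates the WSS *vector*, the denominator its
magnitude; the two 1/T factors cancel. This is the standard
normalization that guarantees OSI ∈ [0, 0.5] (a printed formula that
divides by "TAWSS" leaves the 1/T ambiguous; only this reading yields
the documented endpoint values 0 and 0.5). Zero-TAWSS points take
OSI = 0 by definition; RRT is capped at a configurable ceiling
(default 10³ 1/Pa) with a boolean degeneracy flag wherever
(1 − 2·OSI)·TAWSS underflows it, and ECAP flags zero-TAWSS points —
degenerate points are flagged, never invented. Snapshot extraction
linearly interpolates |WSS| at the report times (default 0.01, 0.14,
0.35, 0.59 s of the 1 s cycle).

## Waveforms

Physiological pulse shapes are not available in closed form, so the
generator uses a von Mises bump exp(κ(cos θ − 1)) about the systolic
peak, truncated to `harmonic_count` Fourier harmonics (default 8,
sharpness κ = 8 giving a ≈0.3 s systolic upstroke). All cosine
coefficients are positive, so the truncated series peaks exactly at
`peak_time`; the sampled waveform is affinely normalized so the peak
equals the systolic level and the sampled minimum equals the diastolic
level. Seeded jitter perturbs harmonic amplitudes (keeping them
positive) for families of realistic variants; `seed=None` is the
canonical shape. Defaults: 1 s period, peak at 0.14 s, 140/80 mmHg
pressure levels (the diastolic level is a standard clinical default,
not a measured value).

Comparison metrics: the waveform percent difference is the relative L2
norm 100·‖a − b‖₂/‖b‖₂ against the reference on a common periodic grid
(chosen because the quantity it reproduces is reported without a
printed definition; a symmetric variant is available). Systolic
metrics: amplification = 100·(max test − max ref)/max ref and peak lead
= t_peak(ref) − t_peak(test), with peaks refined by a parabolic
sub-sample fit and the lead wrapped into (−T/2, T/2].

Analytic oracles: Poiseuille WSS 4μQ/(πR³) and the classical Womersley
series (steady paraboloid plus Bessel-function harmonics of the
pressure-gradient spectrum), Newtonian only; their frozen test values
come from an independent 40-digit arbitrary-precision evaluation.

## Synthetic ground truth

`make_wss_series` builds, per wall point, a steady component plus an
equal-dwell reversing square wave in a seeded random direction. With
square amplitude m = TAWSS* and steady part c = (1 − 2·OSI*)·m, the
continuous-time TAWSS and OSI equal the targets exactly — and because
the periodic trapezoid rule integrates piecewise-constant signals
exactly, recovery on any even sample grid is exact too (the square wave
was chosen over a sinusoid precisely because this inversion is closed
form). `make_pressure_pair` scales the base waveform about its
diastolic floor to hit a prescribed systolic amplification and advances
it by the prescribed lead (integer-sample leads use an exact circular
shift; fractional leads use the spectral shift, exact for the
band-limited pulses). Noise injection is additive Gaussian scaled by
the signal RMS — the simplest model that exercises robustness; it makes
no claim of physiological realism.

What the generators do *not* emulate: spatial WSS contour patterns,
wave propagation/reflection, lumen compliance, or measurement artifacts
of imaging-derived data. Passing the round-trip tests therefore
demonstrates correctness of the index computations and metric
definitions, not fidelity to any patient.

## Verification problem sizes

Chosen as the package's own verification conditions: the Poiseuille
ladder runs a 4 mm × 16 mm tube at resolutions 8/16/32 with mean inlet
velocity 0.05 m/s; the Womersley run uses the same tube at resolution
32 (Womersley number α ≈ 2.8 for the first harmonic), driven by
pressure-gradient harmonics (−100, −200) Pa/m with Δt = 0.4 ms over 3
cycles, and matches the analytic profiles to ≈0.01 % relative L2 — far
inside the 3 % acceptance band. The dissected verification channel is
8 mm lumens with a 1 mm septum and a single 8 mm tear, 3 cycles.

## Known limitations

* 2-D (axisymmetric/planar) only; no secondary flows or branch trees.
* First-order upwind advection smears sharp features at coarse
  resolution; the verification flows are diffusion-dominated.
* Rigid walls; no Windkessel or impedance outlets — the outlet pressure
  waveform is imposed, not computed from downstream physiology.
* The Picard viscosity lag is first-order in time for strongly
  shear-thinning transients.
* The arch geometry has no flow solve (see above).
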
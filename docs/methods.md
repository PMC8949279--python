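# Methods

## Problem and model

`softimpact` simulates the first milliseconds of a blunt, direct impact of a
soft, nearly incompressible body — brain-like tissue inside a simplified
cranium — against a rigid flat obstacle, and identifies material parameters
from a reference acceleration trace.

The tissue is modelled as a generalised Norton–Hoff viscoplastic fluid.
With the strain-rate tensor `ε̇ = (grad v + grad vᵀ)/2` and the effective
rate `D = sqrt(2/3 · dev ε̇ : dev ε̇)`, the deviatoric Cauchy stress is

    τ' = s · K · (√3 · D)^(m−1) · dev ε̇ ,

so the apparent shear viscosity is `μ(D) = s·K·(√3 D)^(m−1)`.  `m = 1` is a
Newtonian fluid of viscosity `s·K`; `m = 0` a perfectly plastic solid whose
flow-stress magnitude is rate independent; `m < 0` is the non-standard
regime of interest: *strain-rate softening*, where viscosity falls faster
than the rate grows.  A note on the exponent: the two limit statements
(`m = 0` perfectly plastic, `m = 1` Newtonian) force the exponent `m − 1`
on the rate-magnitude factor; an exponent `1 − m` would make a nominally
"softening" material shear-thicken.  The law is applied to the deviatoric
part of `ε̇` (and `D` is computed from it), so the stress is exactly
trace-free and the volumetric response is governed solely by the penalty
term below.

Incompressibility `div v = 0` is imposed weakly by a penalty: a Voigt-space
operator `Λ` with `λ` in the upper-left 3×3 block of ones adds the stress
`λ·(div v)` to each normal component, i.e. the quadratic form `λ (div v)²`,
which vanishes on isochoric motions.

The conventional comparator is a Kelvin–Voigt solid, `σ = C(E, ν) ε + c ε̇`
(spring and dashpot in parallel).  It doubles as the material of the
elastic skull layer (with `c = 0` and a nonzero Poisson ratio).  Its
hallmark deficiency — the acceleration at a remote point builds up only
after a wave-travel delay, with the delay shaped by damping — is what the
softening law removes.

## Space–time discretisation

Unknowns are nodal velocities on P1 tetrahedra, interpolated linearly in
time across a slab `[t, t+h]`; the space–time interpolation matrices have
twice the columns of a spatial interpolation (values at both slab ends).
Testing the virtual-work balance with the time shape function of the
unknown end values and integrating exactly in time gives one sparse system
`(K + M + Z) v_new = F` per slab:

* `M` — inertia, `ρ Nᵀ ∂N/∂t`, which integrates to half the consistent
  mass matrix;
* `Z` — external damping `c Nᵀ N` acting on absolute velocity (only the
  viscoplastic material's `c` enters here; the comparator's dashpot is a
  strain-rate damping and is part of `K`);
* `K` — the constitutive block: `(h/3)` times the viscous operator
  (apparent viscosity at the element's current `D`, plus the penalty) and
  the elastic displacement coupling.

Displacements are the exact time integral of the linear-in-time velocity,
`u ← u + h (v_old + v_new)/2`; elastic elements accumulate Voigt strain the
same way.  One deliberate deviation from the pure Galerkin weights: the
time weights of the elastic displacement integral are `(1/12, 1/4)` instead
of `(5/24, 1/8)`.  Both sum to `1/3` (first-order consistency); the pure
weights are only conditionally stable (amplification > 1 for `ωh > 3.46`,
which a GPa-stiff skull layer exceeds at practical slab sizes), while the
shifted weights are unconditionally stable with spectral radius ≤ 0.82 in
the stiff limit.  The scheme is globally first-order accurate in velocity,
and on a linear-elastic bar it converges to a classical backward-Euler
solution (the `classical` module, an independent implementation kept solely
as an oracle).

The nonlinearity — viscosity depending on the mid-slab rate field, and the
contact force depending on the predicted end position — is resolved by
Picard iteration with three safeguards, all of which leave fixed points
unchanged:

* element viscosities are updated in log space, damped by 0.7 and capped at
  one decade per iteration (near the regularisation plateau the viscosity
  can jump ~1e12 between rigid and yielded states, and an uncapped update
  cycles);
* the velocity iterate is adaptively under-relaxed when the residual grows
  (a pure two-state limit cycle, e.g. a contact node flickering on/off the
  plane, becomes a contraction under averaging);
* the slab is solved in increment form `A Δv = r(v_old)` with internal
  forces evaluated on translation-removed element velocities, so rigid
  motion is an *exact* fixed point — otherwise the enormous floor viscosity
  amplifies cancellation noise and momentum drifts at ~1e-8 per hundred
  slabs.

The impact driver adds one more safety net: a slab whose Picard iteration
stagnates is deterministically re-run as two half slabs (bounded recursion).

### Geometry treatment

Node positions always track the motion (contact needs them), but the
assembly geometry follows the displacement only in the optional
updated-Lagrangian mode (`update_geometry=True`).  The default is the
small-strain treatment: under strongly softening flow the deformation
localises at the contact rim and linear tetrahedra invert within ~0.5 ms of
a 12 ms window; remeshing/ALE is out of scope.  The updated mode is
implemented and tested and is appropriate for moderate deformations.

## Regularisation and parameter scales

The power law is singular at `D = 0` for `m < 1`; rates below a floor
`D_floor` use the floor viscosity.  The regularised law is therefore
Bingham-like, with stress rising to a plateau `τ_f ≈ 0.54·s·K/√D_floor` at
the floor and *decreasing* beyond it (for `m = −0.5`).  This makes the
floor a physically meaningful scale, not just a numerical guard: with the
default `D_floor = 1e-8 1/s` and `K = 20 Pa·s`, the plateau (~1e5 Pa)
straddles the inertial stress scale `ρ v Δv ≈ 6e4 Pa` of a 7.5 m/s impact,
so the shape coefficient `s` and viscosity `K` genuinely shape the peak
acceleration.  A much larger floor (e.g. 1e-6) drops the plateau below the
driving stress; every element then yields immediately, the flowing material
is water-thin, and peak accelerations become *independent* of `s` and
nearly independent of `K` — the softening law degenerates.  This is also
why the headline constant-vs-softening contrast does not reproduce at these
SI parameter scales: a constant-sensitivity material (`m = +0.5`,
`K = 30 Pa·s`) carries stresses `τ ≈ 0.93·K·√D` of only ~1 kPa at impact
rates, so its peak sits at the near-inviscid limit, below softening runs
whose plateau is the thing producing their `s`-ordering.  The two published
orderings would only coexist here if `K` were roughly three orders of
magnitude larger than its nominal SI value; the package reports what the
stated parameters actually produce.

The damping coefficient `c` is quoted in the dashpot unit N·s/m yet enters
a volume integral; it is applied as a distributed coefficient (per unit
volume) with the quoted numeric values.  At those values its dynamical
effect is small (velocity decay rate `c/ρ ≈ 0.01/s`), which is faithfully
reflected in the identification landscape: the mismatch functional varies
orders of magnitude more along `K` than along `c`.

Other defaults, chosen once and configurable: penalty `λ = 1e6 Pa·s`
(large enough that the div-v residual is contact-limited, small enough for
well-conditioned float64 solves; the acceptance sweep varies it over three
decades); contact penalty stiffness `1e9 N/m³` (penetration ~1 mm on the
head fixture, response rise contact-limited to well under 10% of the
record); brain density `1040 kg/m³`; skull layer `E = 6.5 GPa`, `ν = 0.3`,
`ρ = 1900 kg/m³`; slab size `h = 3e-5…6e-5 s` at desk scale, a few hundred
slabs per run.

## Fixtures (synthetic geometry)

No external data is needed.  Two generators provide the study geometry:

* a structured bar (hexahedral cells split into six Kuhn tetrahedra with
  consistent orientation) for oracle tests and wave benchmarks;
* an ellipsoid approximating an adult cranium, default semi-axes
  0.09/0.07/0.08 m, built by smoothly mapping a structured cube mesh onto
  the unit ball and scaling.  An impact-facing surface shell of
  configurable thickness can be tagged as the elastic skull layer; the
  measurement point is the surface node nearest the pole opposite the
  impact (the occipital point).  The published head model has ~21k elements
  and ~15k dof; the generator reaches that class (`target_element_count`),
  while routine runs use 160–1300 elements.

Both are deterministic for fixed arguments.  What they do *not* emulate:
anatomical geometry, cerebrospinal fluid, skull–brain interface mechanics,
tissue heterogeneity or anisotropy.  Passing tests therefore demonstrate
properties of the *method* (orderings, conservation, convergence,
recoverability), not clinical accelerations; absolute peak values on these
fixtures are mesh- and contact-parameter-dependent.

The softening sweeps are run without the skull layer: on a ~1300-element
ellipsoid a GPa shell dominates the coarse-mesh dynamics and masks the
brain law entirely (peaks become s-insensitive).  The layer is kept for
geometric fidelity tests and mixed-material solver coverage.

## Identification

Given a reference trace `a_d(t)` at the measurement node, the mismatch
`J(K, c) = ∫₀ᵀ (a − a_d)² dt` is evaluated by trapezoidal quadrature after
linear resampling to the finer of the two time grids, and minimised over a
box by a coarse grid scan (default 8×8; the grid doubles as the sensitivity
landscape) followed by Nelder–Mead refinement from the best grid point,
never returning worse than the grid best.  Ties keep the first grid point
in K-major order.  Acceleration is recovered from the velocity history by
central differencing (the space–time unknown is velocity), with no
smoothing by default.

Because the literature reference curves behind the original calibration are
not available in reusable form, recovery is validated self-consistently:
the forward model generates the reference at known `(K†, c†) = (20, 12)`
and the search recovers both to ~0.1% on a 162-element ellipsoid.  This is
the standard inverse-crime check; it validates the machinery, not the
biological parameter values.  The reported literature optima are shipped as named
presets (`identify.PRESET_OPTIMA`), not asserted.

## Delay metrics

The comparator's lag is summarised by the time for |a| at the measurement
node to first reach 50% of its peak (`delay_to_threshold`).  On desk-scale
fixtures this build-up delay decreases monotonically with damping —
higher damping transports the disturbance diffusively and earlier — while
the literal time of the global maximum is tie-or-slightly-*increasing* in
damping (Kelvin–Voigt smearing retards the rounded maximum), so the
build-up delay is the operational "response delay" throughout.  The
softening viscoplastic run reaches half its peak within ~2.5% of a 12 ms
record: the immediate-rise behaviour the model was designed for.

## Known limitations

* First-order accuracy in time; no adaptive slab sizing beyond the
  bisection fallback.
* Equal-order P1 velocities with a penalty are prone to volumetric locking;
  the incompressibility residual is contact-limited below ~0.13 s⁻¹ on the
  coarse bar regardless of `λ`.
* No friction, no rotation, no skull fracture, no fluid layers; the
  obstacle is an infinite rigid plane.
* Serial execution only; element operations are vectorised across elements
  but there is no multi-worker assembly.
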
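# softimpact

Space–time finite element simulation of soft-tissue impact with a
strain-rate-softening viscoplastic law, and inverse identification of its
parameters from acceleration traces.

## What problem this solves

When a head hits a hard, flat surface, the dangerous part of the response is
over within a few milliseconds: a rapid acceleration peak followed by a
smooth decay.  Linear viscoelastic brain models get this qualitatively
wrong — the acceleration at a remote point (e.g. the occipital pole) builds
up only after a wave-travel delay shaped by stiffness and damping, and the
response rings.  `softimpact` implements the alternative: treat the tissue
as a dense, nearly incompressible viscoplastic fluid whose viscosity *falls*
as the strain rate grows.

The constitutive core is a generalised Norton–Hoff law for the deviatoric
Cauchy stress,

    τ' = s · K · (√3 D)^(m−1) · dev ε̇ ,      D = √(2/3 · dev ε̇ : dev ε̇) ,

with viscosity `K` (Pa·s), rate sensitivity `m ∈ [−1, 1]` (`m = 1`
Newtonian, `m = 0` perfectly plastic, `m < 0` rate softening) and a shape
coefficient `s` tuning the viscosity–rate hyperbola.  Incompressibility is
enforced by a penalty on `div v`; a Kelvin–Voigt solid `σ = C(E, ν) ε + c ε̇`
serves as the conventional comparator and as the elastic skull layer.

Everything is discretised with a velocity-based space–time finite element
method: P1 tetrahedra in space × linear interpolation in time over slabs,
one sparse system `(K + M + Z) v = F` per slab, with Picard iteration
resolving the rate-dependent viscosity and the rigid-wall penalty contact.
Parameter identification minimises `J(K, c) = ∫ (a − a_d)² dt` against a
reference trace by a grid scan plus Nelder–Mead refinement.

Intended users: researchers in tissue biomechanics and impact modelling who
want a transparent, dependency-light reference implementation of the
softening-law + space–time-FEM approach, not a clinical head-injury tool.
See `docs/methods.md` for model details, numerical choices and limitations.

## Worked example

Impact of an ellipsoidal head fixture (semi-axes 9/7/8 cm, ~750 tetrahedra)
at the speed of a 2.87 m fall, sweeping the shape coefficient of the
softening material (`m = −0.5`, `K = 20 Pa·s`, `c = 12`):

```python
import softimpact as si

mesh = si.generate_ellipsoid_mesh((0.09, 0.07, 0.08), 750, 0.0)
v0 = si.impact_velocity_from_drop(2.87)
print(f"impact speed: {v0:.2f} m/s")

scen = si.ImpactScenario.head_on(mesh, initial_speed=v0, duration=3e-3, h=3e-5)
brain = si.ViscoplasticMaterial(K_viscosity=20.0, m_sensitivity=-0.5, c_damping=12.0)
table = si.sweep_softening(mesh, brain, [0.5, 1.0, 2.0], scen)
print(table[["s", "peak_acceleration", "time_of_peak"]].to_string(index=False))
```

prints

```
impact speed: 7.50 m/s
  s  peak_acceleration  time_of_peak
0.5        4843.954060       0.00039
1.0        4987.925689       0.00039
2.0        5256.381244       0.00039
```

i.e. the peak acceleration at the occipital measurement node (m/s²) rises
monotonically with `s`, and the peak arrives ~0.4 ms after contact — the
immediate, no-delay rise that distinguishes the softening material from a
viscoelastic comparator, whose build-up at the same node lags by several
milliseconds of wave travel.  Absolute peak values depend on mesh
resolution and contact stiffness; orderings and timings are the meaningful
output at this scale.

A CLI wraps the same library (`softimpact mesh / simulate / sweep /
identify / summarise / export`); each run writes a manifest with a
configuration fingerprint for reproducibility.

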
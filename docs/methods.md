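# Methods

## Physical picture and model reduction

The seed scale is modelled as a cantilevered beam whose proximal bending
zone is a two-layer laminate: an abaxial sclereid layer that contracts
longitudinally on drying (active), bonded to an adaxial layer of
sclerenchyma fiber strands (passive).  The brown tissue between the strands
is mechanically minor in the bending zone and is absorbed into the
homogeneous passive layer; epidermes are ignored.  The distal remainder of
the scale is treated as a rigid lever: it contributes no compliance and is
carried only to convert the zone-end rotation into a tip position.

The original analysis of this system used a 3D hexahedral finite-element
model with a temperature-load analogy for the hygroscopic contraction.
This package reduces that model to 1D layered-beam (laminate) theory:

* plane sections remain plane; axial strain `eps(z) = eps0 + kappa z`;
* each layer is linear elastic with a humidity-dependent Young's modulus;
  stress is uniaxial (an optional plane-strain switch replaces `E` by
  `E/(1-nu^2)`, `nu = 0.3`, to bound the effect of lateral constraint —
  applied to both layers it cancels from the curvature exactly, so the
  uniaxial default is not a restriction in practice);
* the hygroscopic contraction enters as a stress-free eigenstrain in the
  active layer only, longitudinal, uniform across the layer thickness;
* the section being load-free, `(eps0, kappa)` solve the 2x2 equilibrium
  system with exact rectangle integrals per layer.

Because eigenstrain bending carries no external load, curvature is a state
function of each cross-section.  The "geometrically nonlinear" aspect of
the problem therefore reduces exactly to finite-rotation integration of
`kappa(s)`: `theta(s) = ∫ kappa ds` and the centerline from
`(cos theta, sin theta)`.  The tests verify this against an ODE elastica
integration and the bimetal closed form.

The cross-section is a rectangular stack with the measured widths, although
the real section is oval — this is the minimal shape that honours the four
printed thickness values and two widths.  For a two-layer rectangle the
width cancels from the curvature, so the width taper affects only stiffness
resultants, not the angle; the thickness taper is what matters.

## Geometry

Dry-state dimensions at the two ends of the bending zone (start = clamped
proximal end): active layer 0.80 → 0.65 mm, passive layer 0.60 → 0.43 mm,
width 1.8 → 3.5 mm, all linearly interpolated.  Geometry is held fixed
across humidity states (the layer-thickness swelling seen in tomography is
not fed back into the section stiffness), mirroring the fixed-mesh
temperature-load approach of the original analysis.

**Bending-zone length.** The zone length is not printed anywhere; only the
two end cross-sections are.  It is a first-class configuration parameter,
echoed into every output.  The default, `L = 3.0 mm`, was chosen by the
same inverse logic the study itself used for the passive modulus: it is the
length (consistent with the few-millimetre scanned fragments) at which the
dry-state calibration of the 1D model lands at the reported passive-modulus
value (≈ 1230 vs 1170 MPa).  At `L = 4 mm` the 1D model would calibrate to
≈ 2000 MPa; the difference is absorbed entirely by this unprinted length,
to which the calibrated modulus is roughly proportional.

**Stations.** Curvature is integrated by composite trapezoid on a uniform
grid of 201 stations (default).  The integrand is smooth, so the error is
O(h²); at 201 stations the angle changes by < 5e-7 relative when the
station count is doubled.  51 stations would already give four significant
digits but falls short of the 1e-6 reproducibility the tests demand.

## Materials

Tissue moduli are piecewise-linear in relative humidity between measured
knots and clamped to the endpoint values outside the measured range
(extrapolating the steep sclerenchyma slope would produce negative moduli
below ≈ 17 % rh).  Shipped presets (CSV resource, overridable by file):

| preset | knots (rh %, MPa) | use |
|---|---|---|
| `sclerenchyma_sim` | (30, 800), (80, 180) | passive layer, simulation endpoints |
| `sclerenchyma_afm` | (30, 800), (75, 200) | passive layer, indentation values |
| `sclereid_regression` | (30, 37), (80, 21) | active layer (default) |
| `sclereid_afm` | (40, 35), (50, 35), (60, 25), (80, 25) | active layer, step-like measured course |
| `brown_tissue` | (30, 52), (70, 52), (80, 43) | documentation/synthetic tables |

The sclereid regression is oriented 37 MPa dry → 21 MPa wet, consistent
with the measured step from 35 MPa (50 % rh) down to 25 MPa (60 % rh).
The two sclerenchyma presets differ at the wet end because the simulation
used slightly different endpoint values than the indentation averages; the
simulation preset is the default for all calibration work.

## Drying path

A scalar drying coordinate `xi` (0 = fully wet, 1 = fully dry) couples the
two humidity effects linearly and in lockstep:

* active-layer strain `eps_a(xi) = -eps_max * xi`, `eps_max = 0.22` (the
  tomographically observed 22 % longitudinal shortening of the sclereid
  layer in the bending zone);
* passive modulus `E_p(xi) = 70 + (E_dry - 70) * xi` MPa.  70 MPa is the
  fully wet endpoint; `E_dry` is the calibrated dry value (default 1170,
  replaced by the fitted value after calibration).  This ordering — soft
  wet, stiff dry — is the only one consistent with the observation that the
  fibers stiffen while drying; the source text's attachment of "70 MPa" to
  the dried state is treated as a transposition.

A humidity maps into the path through the passive-modulus curve:
`xi(rh) = (E_SF(rh) - 70) / (E_dry - 70)`, clipped to [0, 1].  This mapping
is a modelling convenience (the study never defines an explicit rh ↔ state
map); it reproduces the intended anchor states E = 180 MPa at 80 % rh and
E = 800 MPa at 30 % rh exactly.  Along a sweep, the active-layer modulus is
read from its own humidity curve at the rh equivalent of the current
passive modulus, clamped at the curve ends (in particular the fully dry
state uses the dry sclereid value of 37 MPa).

## Calibration

Both inverse problems are scalar and solved by bracketed bisection:

* the forward map is first probed on a 9-point grid over the bracket and
  must be strictly monotone, otherwise the solve is refused with
  diagnostics (no silent wrong roots);
* the bracket is bisected until it is relatively tiny (1e-13), so fitted
  values round-trip through the forward model to ≈ 1e-8 relative;
  convergence is declared when the angle residual is ≤ 1e-4 degrees
  (configurable), with a 200-iteration cap;
* default brackets: passive modulus [100, 5000] MPa; contraction increment
  [0, 0.22].

`fit_passive_modulus` solves the dry-state problem (target 24.4°, active
modulus 37 MPa, contraction 22 %).  On the stiff branch
(`E_p / E_a ≳ 4`) the angle is strictly decreasing in `E_p`, so the root is
unique.  `fit_contraction` solves for the contraction increment over a
humidity interval with the endpoint moduli held at their curve values; the
default target is the 12° measured over 80 → 30 % rh (the per-scale
measured mean 12.2° is available in configuration).

With the default geometry the calibrated model gives: passive modulus
≈ 1226 MPa (reported 1170), interval angle ≈ 15.1° (measured 12 ± 4),
interval contraction ≈ 9.5 % (reported ≈ 11 %), passive stiffening 620 MPa
(exact by construction of the curve).  The interval quantities inherit the
1D reduction and the invented `xi(rh)` mapping; their deviations sit within
the between-scale measurement spread.

## Synthetic studies and recovery

The generator emulates the *reported scatter structure* of the study, not
its raw data (none are deposited):

* **angle sweeps**: forward-model angles on the 30–80 % rh grid in 10 %
  steps, plus i.i.d. Gaussian noise (default sd 4.2°, the reported
  between-scale spread) and one lognormal size factor per scale multiplying
  the bending-zone length (median 1, cv default 0.15) — a stand-in for the
  wide range of scale sizes, to which the angle is exactly proportional;
* **modulus tables**: lognormal multiplicative noise (mean 1, cv default
  0.3) around the curve value, 64 locations per (tissue, rh) sample,
  guaranteeing positive moduli.

Everything is deterministic per seed (numpy `default_rng`).

Recovery refits `e_passive_dry` per synthetic scale by bounded least
squares of predicted vs. observed angles over the rh grid; fits ending on
the bracket boundary are flagged non-convergent and excluded.  The
study-level estimator is the mean of converged per-scale fits.  Monte-Carlo
over 200 seeds at 1° noise shows a median relative bias of ≈ 1–2 % (the
small positive bias is the Jensen effect of the size factor entering the
estimate reciprocally) and an estimator RMSE that falls with the number of
scales as expected.

What passing these tests shows — and what it does not: the inverse
machinery is consistent and well-conditioned *under the model's own noise
assumptions* (additive Gaussian angles, multiplicative size variation).
Real scales add systematic effects the generator does not emulate:
humidity-history dependence, biaxial "two-phase" motion, tissue
heterogeneity along the zone, and non-proportional geometric variation.

## Numerical and degenerate-input policy

* Moduli, thicknesses, widths must be positive; violations raise typed
  errors (`GeometryError`, `DomainError`) rather than returning NaN.
* Geometry constructors are permissive; `validate_geometry` reports all
  violated invariants and the mechanics layer refuses invalid models.
* Layer stacks must be contiguous in z (gap/overlap tolerance 1e-9 relative
  to the thickest layer).
* Curves with a single knot are constant; evaluation at a knot returns the
  knot value exactly.
* The drying path requires `E_dry > E_wet`; equal endpoints are rejected as
  degenerate rather than yielding 0/0.
* Angles are degrees at every public surface and radians internally.
* Sign convention: z from the layer interface toward the passive (adaxial)
  side; drying (active contraction below) gives positive curvature and a
  positive, opening angular change.

## Known limitations

* 1D beam reduction: no transverse curvature, no oval section, no discrete
  fiber strands, no contact between scales, no inertia.
* No time dependence: sorption kinetics, creep and the wet/dry hysteresis
  of real scales are out of scope; states are equilibrium states.
* The bending-zone length is not identifiable from the published geometry
  alone; all calibrated moduli should be read conditional on it.
* The rh ↔ drying-coordinate mapping is linear in the passive modulus by
  construction; any nonlinearity of real moisture uptake between the anchor
  states is not represented.
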
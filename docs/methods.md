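# Methods

`cortexfold` models the folding of a growing stiff elastic layer on a
soft elastic substrate — the mechanical caricature of the developing
cerebral cortex on white matter — and measures the thickness asymmetry
that folding creates between gyri (outward crests) and sulci (inward
valleys).  This note records the models, the numerical choices, and what
the synthetic data do and do not establish.

## Morphoelastic model

Deformation is decomposed multiplicatively, `F = Fe · Fg`, with isotropic
morphogenetic growth `Fg = ϑI` in the layer (`ϑ = 1`, `G = 0` in the
substrate) and only the elastic part `Fe` generating stress.  Growth is
quasi-static with linear kinetics `ϑ̇ = G`; time is dimensionless and
absorbed into `G`.  Units are mm and kPa throughout.

Two constitutive branches:

* **Incompressible neo-Hookean** (analytical work):
  `σ = µ FeᵀFe − pI`, `det Fe = 1` (tolerance 1e-8).
* **Compressible neo-Hookean** (finite elements):
  `σ = [λ ln Je − µ] I + µ FeᵀFe`.

The compressible expression is implemented verbatim as the package
default.  Read literally it is a Kirchhoff-type stress: a frame-correct
Cauchy stress requires a `1/Je` prefactor and the left Cauchy–Green
tensor `Fe Feᵀ`.  Both variants are provided
(`SimConfig(frame_correct=True)` selects the energy-consistent one); for
the symmetric elastic states that dominate this problem the tensor
choice coincides, and the `1/Je` factor changes stresses by under ~15%
at the growth levels reached here.  The default follows the printed
form so that simulated quantities refer to the same law the constants
were published with.

## Analytical stability (linear + weakly nonlinear readout)

The layer occupies `Y ∈ [0, 1]`, the substrate `Y ≤ 0`, both
incompressible with stiffness ratio `β = µ_l/µ_s`.  Laterally
constrained growth leaves the layer with elastic stretches
`(1/ϑ, ϑ)` (flat solution `y = ϑ²Y`) and the substrate unstressed.
Incremental equilibrium is solved with the classical exponential
(Stroh-type) ansatz: stream-function solutions `exp(±ky)`,
`exp(±ky/ϑ²)` in the layer and the degenerate pair
`(D₁ + D₂ky)e^{ky}` in the unstrained substrate, joined by displacement
and traction continuity at the interface, a traction-free top and decay
at depth.  The vanishing 6×6 boundary-condition determinant defines
`ϑ(k)`; its minimum over `k` is the critical growth `ϑ^crit` and
wavenumber `k_c`.  Exponential columns are rescaled to keep the
determinant well conditioned at large `k·ϑ²`.

Two classical limits validate the formulation end to end:

* stiff-film asymptote: for `β = 100`,
  `k_c·t → (3/β)^{1/3}` and the critical strain matches the classical
  quarter-power law;
* Biot limit: as `k → ∞` the dispersion approaches the surface
  instability of a growth-compressed half-space at stretch 0.5437
  (`ϑ_B = 1.8393`), reproduced to six digits.

The fold mode is `y(x, Y) = ϑ²Y + A k F₁(Y) cos(kx)`; `F₁` is the null
vector of the boundary-condition matrix, normalised to `max|F₁| = 1`
over the layer with `F₁(1) < 0` so the gyral crest sits at `x = π/k_c`.
The thickness-asymmetry coefficient follows directly from the mode:
`t_g = 1 + aA`, `t_s = 1 − aA` with
`a = (k_c/ϑ²)(F₁(0) − F₁(1))`, so `t_g + t_s = 2` identically and
`κ = aA`.  Computed behaviour: `a > 0` on the whole finite-wavelength
branch (gyri thicken, sulci thin) and decreases with `β`
(a ≈ 0.0086 at β = 3).

**Folding threshold.** As `β` decreases, the finite-`k` minimum of
`ϑ(k)` rises and merges into the Biot plateau; below the merge point
the minimising wavenumber diverges (zero-wavelength regime) and the
asymmetry coefficient ceases to exist.  `folding_threshold()` computes
this endpoint as the root in `β` of the signed gap between the Biot
growth and `ϑ(k_probe)` at large `k_probe`; `biot_limit()` reaches the
same phenomenon by bisecting on whether the minimiser over a wide
wavenumber window is interior.  In this formulation both give
β* ≈ 0.525.  This is the package's computed value for the single
threshold the linear analysis possesses; the creasing window reported
in the experimental literature (stiffness ratios ~0.35–0.86) involves a
nonlinear surface instability deliberately outside this package's
scope.

## Finite-element simulator

Plane strain, bilinear quadrilaterals, total-Lagrangian residual
`P = Jg·Je·τ·F⁻ᵀ` for the printed law (`Jg·τ·F⁻ᵀ` for the
frame-correct variant) with `τ = µ(b_e − I) + λ ln Je I` and exact
analytic tangent (verified against central finite differences to 1e-6
relative).  Selective reduced integration — deviatoric part at 2×2
Gauss points, volumetric `λ` part at the centre point — mitigates
volumetric locking at the Poisson ratio 0.4515 implied by the default
constants (µ_l = 0.30, λ_l = 2.79, µ_s = 0.10, λ_s = 0.93 kPa,
stiffness ratio 3).

Default geometry: 110 × 25 mm with a 1.25 mm layer; the printed
discretisation 240 × (20 + 4) elements gives 5760 elements and 12 050
displacement unknowns.  Rollers (zero normal displacement, free
tangential slip) on the left, right and bottom edges; free top.

**Continuation.** Growth is stepped by `Δϑ = 2e-3` (halved adaptively on
Newton failure, floor 1e-5; Newton: residual < 1e-9 of the first
iterate, max 25 iterations, with backtracking line search).  Symmetry
is broken once at the start by a deterministic perturbation of the
reference node heights: a fixed-seed sum of the first 30 lateral cosine
modes, ramped quadratically from the fixed bottom edge and normalised
to a maximum offset of 1e-3 of the layer thickness.

The folding bifurcation of this bilayer is weakly subcritical: with a
small imperfection, plain Newton continuation can follow the metastable
flat branch far past the instability.  The solver therefore monitors
the lowest eigenvalue of the free-DOF tangent (every `eig_every` steps
once `ϑ > 1.15`, deterministic ARPACK start vector).  When an
eigenvalue crossing is detected, the crossing is first localised by
bisection between the last stable check and the current state, and the
eigenvector *at the crossing* is used as the kick direction — without
this, several nearly-critical modes can cross within a few growth steps
(the dispersion minimum is flat) and the kick would select an arbitrary
member of that band.  The kick escalates in amplitude (0.05–1.0 layer
thicknesses, deterministic sign convention) until Newton lands on a
stable folded equilibrium.

Secondary snap-throughs (the period-doubling transition and later fold
coalescence) manifest as continuation stalls at limit points, where the
lowest eigenvalue is only marginally positive.  Stalls are rescued by,
in order: a larger eigenvector jump (0.3–2.0 layer thicknesses with a
generous Newton budget), then an explicit diagonally-preconditioned
pseudo-time relaxation (`u' = −D⁻¹R`, displacement increments capped at
2% of the layer thickness, Newton polishing every 50 flow steps) that
can traverse regions where the residual must rise before falling.  This
branch-following is part of the model definition here: detected
bifurcation growth factors refer to the *stable* branch, reached as
soon as the previous branch loses stability.

**Self-contact** is detection-only: node and segment-midpoint samples of
the deformed top surface closer than the detection gap (the configured
`contact_gap`, floored at a quarter element width — the surface
polyline cannot resolve finer separations) whose reference stations are
more than three element widths apart.  A continuation stall with fold
walls within 1.5 of that gap is also classified as first contact: in a
detection-only model, equilibrium loss driven by approaching walls *is*
the contact event at that mesh resolution.  The run stops at first
contact.

## Fold metrics

* Thickness is measured along deformed material columns (top node to
  interface node at the same reference station) — well defined under
  shear and consistent with the analytical definition
  `t = y(·, 1) − y(·, 0)` evaluated on material columns.
* Crests/fundi: prominence-filtered local extrema of the top-surface
  height (prominence 5% of the current fold amplitude, suppressing
  mesh-scale ripples); extrema within half a crest spacing of a lateral
  boundary (half-folds distorted by the rollers) are excluded from
  averages.
* First bifurcation: earliest growth at which
  `κ = (t_g − t_s)/(t_g + t_s)` exceeds 0.005 for three consecutive
  snapshots.  Second bifurcation: the alternate-fundus depth asymmetry
  (|mean even-indexed − mean odd-indexed| / mean fundus depth, depths
  from the mean surface height) exceeds 0.05 for three snapshots; the
  indicator is gated on a fold amplitude of at least 5% of the layer
  thickness so pre-buckling mesh noise cannot trigger it.
* Wavelength: peak of the magnitude spectrum of the top-surface height
  over the uniform reference stations with parabolic peak
  interpolation, cross-checked against mean crest spacing.

## Surface statistics

The HMRF segmentation uses two Gaussian emission classes on the
per-vertex maximum principal curvature with a Potts smoothness prior on
mesh edges, fit by EM with mean-field updates; initialisation is a
deterministic quantile split, the class with higher mean convexity maps
to "gyral", and `smoothness=0` reduces exactly to pointwise
maximum-likelihood thresholding.  Thickness statistics are area-weighted
with barycentric vertex areas (one third of each incident triangle, an
O(h²) Voronoi-area surrogate that sums exactly to the mesh area);
parcel-level weighting is available via the per-region table.  Class
comparison is Welch's unequal-variance two-sample t test on
region-level values, two-sided — the package's explicit choice where a
test is needed.  The folding scaling law is evaluated as
`k = A_t √t_c / A_e^{5/4}` in cm units; exposed area `A_e` is an input,
never computed.

## Contour thickness

Outer contours are arclength-resampled to 512 stations and smoothed
with a periodic 5%-arclength moving average before curvature is taken
(digitised outlines are noisy and curvature is second order).  Local
thickness is the inward-normal ray length to the first inner-contour
intersection, with nearest-point fallback (flagged) where a sharp fold
makes the ray miss.  The curvature dead band separating gyral/sulcal
from neutral flank stations defaults to 10% of the curvature
interquartile range.

## Synthetic data — what it does and does not show

The generators produce folded-sheet surfaces (class-conditional
Gaussian thickness and curvature, truncated at 3 SD; contiguous lobe
bands; optional anterior–posterior thickness gradient), organoid-like
contour pairs (sinusoidally folded outer circle, inner offset by a
crest-to-trough interpolated thickness field), and the FE perturbation
fields.  All randomness flows from one explicit seed; identical specs
give bit-identical files.  Passing measurements on these inputs shows
the estimators recover *known* truth under clean, unimodal, spatially
coherent conditions; it does not establish robustness to the features
of real data these generators deliberately omit — MRI segmentation
error, topological defects, partial-volume thickness bias, regionally
correlated noise, or the irregular meshing of reconstructed cortices.

## Problem sizes and reproduction

The default-resolution simulation (240 × 24 elements, `Δϑ = 2e-3`) is
the reference configuration; the test suite exercises the cascade at
reduced lateral resolution (60–96 elements) and the acceptance script
at 120 × (20 + 4) elements with `Δϑ = 2e-3` (default geometry) and
96 × (14 + 4) with `Δϑ = 6e-3` (thickness variants), sizes chosen to
keep ~10 elements per fold wavelength.  At these resolutions the
cascade is qualitatively identical (folding → asymmetry growth →
period doubling → contact); the default-geometry wavelength is stable
to within a spectral bin across 96–240 elements.

Wavelength selection across the thickness variants carries an intrinsic
spread: the dispersion minimum is flat, so nearly-critical modes
compete, and for the thicker layers (2–3.3 mm, wavelengths 19–32 mm)
the 22–24 mm substrate depth is no longer deep compared with the
wavelength, which biases the selected mode short of the half-space
prediction.  The measured thickness-to-wavelength ratios therefore
scatter around ~0.10–0.15 rather than collapsing onto a single
constant.

## Known limitations

* The simulated bifurcation growth factors are properties of the
  *stable-branch* continuation defined above.  Published values for
  this system obtained with other solvers (in particular ones that ride
  the metastable flat branch before snapping) can sit substantially
  higher; comparisons of absolute bifurcation growth factors across
  codes are therefore solver-sensitive, while ratios, wavelengths and
  the qualitative cascade are robust.
* Detection-only contact: the simulation cannot continue past first
  self-contact (a frictionless penalty continuation exists behind a
  flag but is not exercised by any reported quantity).
* 2D plane strain only; isotropic morphogenetic growth only; no
  cerebrospinal-fluid pressure, no stress-modulated growth, no
  trilayer effects, no creasing analysis.
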
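# cortexfold

Growth-driven folding of a soft elastic bilayer — the mechanical model
behind cortical gyrification — and the thickness asymmetry folding
creates between gyri and sulci.

## The problem

The cerebral cortex (a stiff, growing gray-matter layer) rests on a
softer white-matter substrate.  As the layer grows it is laterally
constrained, builds up compressive stress, and buckles: first into a
sinusoidal folding pattern, then through a period-doubling bifurcation
in which alternate sulci deepen and flatten, until neighbouring folds
touch.  Along the way an initially homogeneous layer spontaneously
develops *thicker gyri and thinner sulci* — a symmetry breaking that
mirrors the gyral/sulcal thickness difference measured in human brains.
`cortexfold` is for researchers in brain biomechanics and morphogenesis
who want a self-contained, tested implementation of this system: the
simulation, the analytics, and the measurement pipelines, all runnable
on synthetic data.

## What is inside

* **Morphoelastic core** — multiplicative growth decomposition
  `F = Fe·Fg`, `Fg = ϑI`, with incompressible
  (`σ = µFeᵀFe − pI`) and compressible
  (`σ = [λ ln Je − µ]I + µFeᵀFe`) neo-Hookean laws.
* **Analytical stability** (`cortexfold.stability`) — incremental
  (Stroh-type) analysis of the growing incompressible bilayer: critical
  growth `ϑ^crit(β)` and wavenumber `k_c(β)` for stiffness ratio
  `β = µ_l/µ_s`, the fold mode
  `y(x,Y) = ϑ²Y + AkF₁(Y)cos(kx)`, and the thickness-asymmetry
  coefficient `a` with `t_g = 1 + aA`, `t_s = 1 − aA`.
* **Finite-element simulator** (`cortexfold.fem`) — plane-strain Q4
  elements with selective reduced integration, exact consistent
  tangents, growth stepping with line-searched Newton, deterministic
  symmetry-breaking imperfection, eigenvector branch switching through
  the folding and period-doubling bifurcations, and self-contact
  detection.
* **Fold metrics** (`cortexfold.metrics`) — material-column gyral and
  sulcal thickness, the relative difference
  `κ = (t_g − t_s)/(t_g + t_s)`, dominant wavelength, and detection of
  the two bifurcation points.
* **Surface statistics** (`cortexfold.surfaces`) — HMRF-EM gyral/sulcal
  labeling of per-vertex curvature on triangulated surfaces,
  area-weighted thickness statistics per class and per lobe, Welch
  class comparison, and the cortical scaling law
  `k = A_t √t_c / A_e^{5/4}`.
* **Contour thickness** (`cortexfold.contours`) — organoid-style 2D
  readout: inward-normal ray thickness between outer and inner contours
  with curvature-based gyrus/sulcus classification.
* **Synthetic data** (`cortexfold.synthetic`) — seeded generators for
  labeled cortical-like surfaces, organoid-like contour pairs and FE
  perturbation fields, each with embedded ground truth.

## Worked example

```python
import cortexfold as cf

# analytical onset for a brain-like stiffness ratio
res = cf.analyze(3.0)
print(f"theta_crit = {res.theta_crit:.4f}, k_c = {res.k_crit:.4f}, "
      f"a = {res.a:.4f}")
# theta_crit = 1.2779, k_c = 0.7073, a = 0.0086

# growth simulation of the default bilayer (half lateral resolution)
cfg = cf.SimConfig(nx=120, ny_substrate=20, ny_layer=4)
traj = cf.run_growth(cfg)
m = cf.trajectory_metrics(traj)
print(m["theta_first"], m["theta_second"])
# 1.3309 1.4355   (first thickness divergence; period doubling)
tab = m["table"]
print(tab[tab.kappa > 0.005].wavelength.iloc[0])
# 12.22            (dominant fold wavelength, mm)

# scaling law from mean human cortical measurements (cm units)
print(cf.scaling_k(cf.ScalingInput(A_e=594.0, A_t=1791.0, t_c=0.258)))
# 0.31022
```

The analytical onset says a layer three times stiffer than its
substrate folds at ~28% growth with a wavelength of ~9 layer
thicknesses, and `a > 0` means the crests (gyri) carry the thicker
columns from the very onset.  In the simulation the gyral/sulcal
thickness difference becomes detectable (κ > 0.005) at ϑ ≈ 1.33, the
alternating-sulcus asymmetry at ϑ ≈ 1.44, and the fold wavelength for
the 1.25 mm layer is ≈ 12.2 mm — about 9.8 initial thicknesses, i.e. a
thickness-to-wavelength ratio of ≈ 0.10.

A CLI mirrors the library:

```bash
cortexfold stability --beta 3 --out stab
cortexfold simulate --config cfg.json --out traj
cortexfold measure --traj traj --out metrics.csv
cortexfold synth surface --out surf && cortexfold surfstats --surface surf
```

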
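# Methods

## The bilayer model

`BilayerModel` represents the transverse structure of a fluid bilayer as a
sum of analytic components, all even in z (the bilayer normal, z = 0 at the
bilayer center):

* **Mirrored Gaussian component groups** — phosphatidylcholine (PC) and
  phosphatidylethanolamine (PE) headgroups, carbonyl–glycerol (CG), the
  terminal-methyl (CH3) trough, and optionally a peptide.  Each contributes
  identical Gaussians at ±center with integrated *excess* electron density
  `areal_excess` (e/Å²) per mirror copy.  Negative areal excess describes
  electron-poor groups (the CH3 trough).
* **A hydrocarbon slab** — a plateau of density ρ_HC over |z| < D_C whose
  edges are smoothed by an error function of interfacial width w
  (convolution of the indicator with a Gaussian of width w).
* **Complementary water fill** — bulk water at ρ_W occupies the volume the
  slab does not: ρ_water(z) = ρ_W·(1 − s(z)), where s is the smoothed slab
  indicator.  Gaussian components are *excess* densities and do not displace
  water in this accounting.  This convention makes the far field equal ρ_W
  exactly and — the reason it was chosen over alternatives such as
  subtracting every component from the water density — makes the model's
  density profile and its closed-form form factor exactly consistent:

```
F(q) = Σ_g 2 A_g exp(−σ_g² q²/2) cos(q c_g)
     + 2 (ρ_HC − ρ_W) D_C sinc(q D_C/π) exp(−w² q²/2)
```

  which is the analytic cosine transform of ρ(z) − ρ_W.  F(0) is the total
  areal electron excess.  The closed form is the oracle against which the
  numerical density → form-factor path is tested (maximum relative
  deviation < 10⁻⁶ over random models; in practice ~10⁻¹²).

### The (z, A_L) condition family

`condition_model(area_per_lipid, peptide_depth, n_peptides)` maps one cell
of the scan grid to a concrete model of a DOPC:DOPE (1:1) bilayer:

| parameter | value | rationale |
|---|---|---|
| D_C | V_C / A_L, V_C = 973.5 Å³ | volume conservation; anchored so A_L = 66 Å² gives 2D_C = 29.5 Å (the neat-bilayer control) |
| PC-head | center D_C + 4.9 Å, σ 3.0 Å, areal 0.35 e/Å² | with PE, places the control's head-to-head spacing near 36.7 Å at A_L = 66 Å² |
| PE-head | center D_C + 2.9 Å, σ 3.0 Å, areal 0.35 e/Å² | PC peak sits 2 Å further from the bilayer center than PE, as in mixed PC/PE profiles |
| CG | center D_C + 1.0 Å, σ 2.5 Å, areal 0.15 e/Å² | carbonyl–glycerol layer just above the chains |
| CH3 | center 0, σ 2.5 Å, areal −0.15 e/Å² | terminal-methyl density dip at the bilayer midplane |
| ρ_HC | 0.30 e/Å³ | methylene liquid density, slightly below water |
| w | 2.5 Å | typical fluid-phase interfacial roughness |
| ρ_W | 0.333 e/Å³ | bulk water at ~37 °C |
| peptide | center \|z\|, σ 3.5 Å, areal (n_pep/2)·208 e / leaflet area | 208 e is the excess of one Tat 47–57 peptide over displaced water: ~838 electrons, partial specific volume 0.73 cm³/g → ~1890 Å³ displacing ~630 water electrons |

Coupling D_C to A_L means lateral expansion thins the bilayer, so the scan's
A_L axis doubles as a thickness axis, and reducing D_C shifts form-factor
minima to higher q_z (the thinning signature).

## Synthetic experiments

`synthesize_experiment` turns a model into an "experimental" curve:
Gaussian noise with standard deviation Δ(q_z) — 0.05 below 0.6 Å⁻¹, 0.1
above, *in lobe-2-normalized units* (i.e. absolute magnitude Δ·max|F| over
lobe 2) — is added to the model amplitude, clipped at zero, and everything
is multiplied by an arbitrary positive scale.  The recorded per-point Δ is
expressed in the same output units, so χ² downstream is invariant to the
arbitrary scale; with the noise turned off the output is the model form
factor times the scale, exactly.  Noise is applied in normalized units
because the Δ values are specified for curves whose lobe-2 maximum is one.

Experimental-style q_z grids default to 0.1–0.8 Å⁻¹ in steps of 0.005 Å⁻¹.
The lower cutoff plays the role of the beamstop: the model |F| has a
genuine low-q zero (near 0.045 Å⁻¹ for these models) that diffuse data
never show, and starting above it makes the leading truncated interval
lobe 1, matching the experimental numbering.  Simulation-side grids span
0–0.8 Å⁻¹ (step 0.005 Å⁻¹) and are linearly interpolated onto the
experimental points before fitting.

## Toy trajectories

`generate_trajectory` emulates the output of a restrained NpAT simulation:

* The transverse box is fixed by the prescribed area per lipid
  (Lx·Ly = n_lipids/2 · A_L); the default system is 128 lipids with 0, 2 or
  4 peptides (mole fractions 0, 0.015, 0.030) and eight chloride
  counterions per peptide.
* Bead z positions are redrawn each frame from the condition model's
  component densities; bead weights carry the component's integrated
  (excess) electrons, so histogramming converges to the model density.
  Because beads cannot carry negative electrons, chain beads are sampled
  from the combined non-negative chain density (slab + CH3 trough) and
  labeled CH2/CH3 probabilistically; only the combined chain density enters
  any measured quantity.
* Each peptide is a bead cluster whose center of mass jitters by σ = 1 Å
  per frame around ±z, emulating a stiff harmonic depth restraint with
  ~1 Å average displacement; the cluster's internal spread is chosen so the
  time-averaged peptide density matches the model's peptide Gaussian.
* Undulations are a single sinusoidal mode u(x) = A·sin(2πx/Lx) added to
  every bead — the simplest field that reproduces the artifact in which
  bending satisfies a global depth restraint while smearing the projected
  density (over uniform x the smearing kernel is the arcsine distribution
  on [−A, A]).  Increasing A monotonically lowers the peak density and
  raises χ² against the flat-bilayer reference.
* All randomness flows through one explicit integer seed; identical
  (config, seed) pairs give bit-identical trajectories, and the JSON-lines
  serialization round-trips exactly (shortest-exact float representation,
  gzip-transparent).

What the toy does **not** emulate: lipid chain conformations and order
parameters, force-field energetics, peptide conformational dynamics and
aggregation, water defects or pores accompanying deep insertion, ion–peptide
coupling (ions are simply dissolved in the water region, so core ion
occupancy is ~0 unless configured otherwise), and frame-to-frame
correlation (frames are independent redraws, so equilibration discard is a
bookkeeping convention here, not a physical relaxation).  Passing tests
therefore validate the *analysis machinery* — binning, centering,
transforms, scaling, ranking, metrics — on data whose ground truth is
known, not the realism of any particular bilayer.

## Analysis pipeline: numerical choices

* **Recentering**: each frame is centered on the hydrocarbon (CH2+CH3)
  center of mass, located with a circular mean along the periodic z
  dimension so bilayers wrapped across the boundary are handled exactly;
  this reference is robust to peptide/water asymmetry.
* **Binning**: default bin width 0.25 Å — fine enough to resolve ~0.3 Å
  shifts in D_HH, coarse enough for toy statistics.  By default the first
  half of the frames is discarded as equilibration.  Symmetrization
  ((ρ(z) + ρ(−z))/2) provides the even profile the cosine transform
  assumes; raw profiles remain available for diagnostics.
* **Transform**: trapezoid quadrature over the box.  Integrands decay to
  zero at the box edges, where trapezoid quadrature is spectrally accurate,
  hence the 10⁻¹²-level agreement with the closed form.
* **Lobe finding**: interior local minima below 0.2 of the global maximum
  (diffuse data never reach exact zeros); at least two qualifying minima
  are required.
* **χ²**: implemented exactly as the reduced sum of squared weighted
  residuals (no square root); because the printed form of such definitions
  is occasionally ambiguous, `chi_squared(..., root=True)` exposes the
  square-root variant for sensitivity checks.  The acceptance comparison is
  inclusive (χ² ≤ 3.4).
* **Ranking**: replicates are aggregated by mean χ² per (z, A_L) cell;
  ties break toward smaller z, then smaller A_L, so reporting is
  deterministic.
* **D_HH**: distance between the two highest local maxima on opposite
  sides of z = 0 of the symmetrized total electron density; unimodal
  profiles are an error, and ties in `peak_density` break toward smaller
  |z|.
* **2D_C**: width of the chain profile at half its plateau, with the
  plateau defined as the mean density over the central 50% of the region
  between the crossings and solved self-consistently (converges in a few
  iterations).  For an error-function slab the crossings sit exactly at
  ±D_C.  On a *combined* CH2+CH3 profile the central trough lowers the
  self-consistent plateau and biases the estimate outward by ~0.4 Å with
  the default trough — an intrinsic property of the estimator, which is why
  parameter-recovery tests measure the slab profile, and trajectory-level
  checks use correspondingly looser tolerances.
* **Core occupancy**: strictly |z| < threshold (default 5 Å), counted per
  frame after recentering, plus the fraction of frames with at least one
  bead inside.

## Problem sizes

The test suite and the acceptance script run on one CPU in well under a
minute each.  Representative sizes, chosen as a balance between statistical
resolution and quick iteration: 100 random models for the transform oracle;
100 seeded replicates of the 8 × 8 grid recovery (each scan scores 64
analytic candidates on a 141-point experimental grid); 10 seeds × 5
undulation amplitudes × 40 frames of ~4,700-bead trajectories for the
artifact diagnostic; 50 random models for structural-estimator recovery at
0.25 Å bins.  The grid-recovery rate is ~97% in the long run; the residual
misses land almost entirely on (z = 16 Å, A_L = 68 Å²), the nearly
degenerate neighbor of the generating cell — the same near-tie between
adjacent depths that motivates scanning with repeats in the first place.

## Known limitations

* The Gaussian+slab family cannot represent asymmetric bilayers or
  peptide-induced local deformations; peptide insertion affects the form
  factor only through its own Gaussian and the A_L–D_C coupling.
* Δ is a two-level step model, not a propagated experimental uncertainty.
* Toy-trajectory χ² values against noiseless references include a
  histogram-noise floor that depends on bead counts and frames; comparisons
  across conditions are meaningful, absolute values are not calibrated to
  any instrument.
* `measure_DHH` on coarse noisy profiles inherits argmax jitter from the
  flat top of the headgroup peak; averaging more frames is the remedy.
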
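# Methods

This note documents the models, conventions and numerical choices behind
`hdlamyloid`, and what the synthetic-data generators do and do not emulate.

## Synthetic data: what is emulated

The generators reproduce the *geometry and sampling structure* of the
experimental readouts, with ground truth known exactly:

- **Sphere fields.** Spherical HDL particles imaged by AFM are modelled as
  the upper surface of a sphere tangent to the substrate: height at lateral
  offset r from the center is R + √(R² − r²) for r ≤ R (R = diameter/2), so
  the apex reads the full diameter. Defaults target a 12.7 nm population.
  Tip convolution is deliberately ignored: the zero-width-tip geometry is
  the reference model, and the height *distribution* it induces —
  P(h) ∝ (h − R) on [R, 2R], from the uniform sampling of the footprint —
  is the quantity the morphometry fits. (A real 8–10 nm tip broadens
  lateral footprints but barely biases heights, which is what the analysis
  uses.)
- **Disc fields.** Discoidal HDL are flat plateaus of constant height
  (default 12.9 nm) over circular footprints: a δ-peak in height, broadened
  only by pixel noise.
- **Fibril fields.** Fibrils are discretized worm-like chains: the tangent
  angle performs a Gaussian walk with per-step variance
  step/persistence_length (step = one pixel), rasterized at constant height
  (3 nm by default, twice the 1.5 nm analysis threshold). Paths reflect at
  the field boundary. Non-overlap of particles is enforced by dart-throwing
  placement with centers at least one diameter apart; a bounded retry count
  turns impossible packings into an explicit `PlacementError`.
- **Ideal cross-β stacks.** A fibril model is n chains (default 5) of
  residues 17–42 (the amyloid core of Aβ1-42, 26 residues). Chain k is a
  straight extended Cα template (0.35 nm spacing, centred on the z axis)
  translated by (k−1)·0.48 nm along z — the canonical cross-β inter-strand
  rise — and rotated by an optional per-chain twist. Structural disorder is
  injected as isotropic per-atom Gaussian noise (`distortion_sd`, nm). Only
  inter-chain geometry matters for the order parameter, so the straight
  template is sufficient; it is *not* a physical peptide backbone.
- **Transwell series.** Two-compartment linear exchange
  dQ_r/dt = P·A·(C_d − C_r) with mass conservation, integrated in closed
  form: C_r(t) = C_eq(1 − e^{−kt}) with k = PA(1/V_d + 1/V_r). Defaults:
  1.12 cm² membrane, 0.5 mL apical, 1.0 mL basolateral. Sampling noise is
  multiplicative Gaussian with a given CV, truncated at zero — the simplest
  model consistent with concentration readouts.
- **ThT traces.** Constant, exponential (baseline·(p + (1−p)e^{−kt})) or
  logistic decays toward a plateau fraction p; the sigmoidal midpoint is
  fixed at 1/decay_rate since only monotone decays are analysed.

Features of real data that are **not** emulated: AFM tip convolution and
scanner artefacts (bow, line noise), polydisperse particle sizes, fibril
bundling and branching, cellular uptake or active transport in the
transwell (passive exchange only), and ThT photobleaching. Passing tests
therefore demonstrate correctness of the estimators under the stated
geometric/kinetic models, not robustness to every instrumental artefact.

All generators accept a seed and are bit-reproducible.

## AFM threshold index

The aggregation index is the percentage of pixels strictly above a fixed
height threshold (default 1.5 nm — roughly half a fibril diameter, well
above substrate noise). Strict inequality makes the all-pixels-at-threshold
case count zero. Replicates at one time point are combined as arithmetic
mean ± sample SD with no outlier rejection. Background levelling (order-0
mean or order-1 least-squares plane; default plane) is provided because raw
AFM data carry tilt; levelling is linear, so adding any plane to a map
leaves the downstream index unchanged. Disaggregation timecourses are
normalized to the t = 0 value; a zero starting value raises an explicit
error rather than propagating infinities.

## Particle morphometry

Heights are histogrammed per pixel over a 4–25 nm analysis range (84 bins,
0.25 nm width); the 4 nm floor excludes the substrate. Per-pixel statistics
(rather than per-particle maxima) are used: they need no segmentation and
carry shape information in the distribution's form.

- *Sphere model:* P(h) ∝ (h − R) on [R, 2R] convolved analytically with a
  Gaussian of sd σ (closed form via erf/exp), with free diameter, σ and an
  amplitude that absorbs range truncation; fitted by bounded least squares.
  The model is validated by self-consistency (recovery of the simulated
  diameter) and by a Kolmogorov distance < 0.05 between generated fields
  and the analytic law at ≥ 10⁴ pixels.
- *Disc model:* mode of the distribution (ties broken toward the lowest
  bin) refined by a Gaussian fit; an input occupying ≤ 2 bins is treated as
  a pure δ (the mode bin is the answer, broadening 0). A straight line is
  regressed over the upper 25% of occupied bins above the mode; with fewer
  than 2 tail bins the slope is undefined and flagged rather than invented.
- *Classification:* both models are fitted to the same histogram; the lower
  residual sum of squares wins, and the RSS ratio is reported as a margin.
  Margins below 2 are flagged uncertain.

Lipidation stoichiometry is molar_ratio = weight_ratio · M_protein/M_lipid,
exactly linear in the weight ratio; reported ratios are conventionally
rounded to the nearest integer.

## Fibril structural metrics

- **Order parameter.** ordP = (1/N_r) Σ_r cos α_r with
  cos α_r = ⟨v_r, z⟩/(|v_r||z|), v_r the vector from residue r's Cα in the
  first chain to the same residue in the last chain. The cosine is signed
  (no absolute value), so anti-aligned stacks give negative values; ordP is
  invariant under joint rotation of coordinates and axis and under
  translation. Coincident Cα pairs (|v_r| = 0) are an error. The default
  chain pair is the first and last chains in stacking order; the fibril
  axis defaults to the recorded construction axis or, for file-read models,
  to the normalized mean displacement between consecutive chain centroids.
- **Equilibrium window.** Trajectory observables are averaged over the
  trailing 20% of the simulated time span by default (a standard
  "last fifth" equilibrium convention). The SEM treats window frames as
  independent; frame autocorrelation is ignored — a documented limitation.
- **Superposition/RMSD.** Kabsch via SVD with reflection correction;
  collinear point sets (rotation not unique) raise an error. RMSD aligns by
  default.
- **PCA.** Covariance of the 3N Cartesian Cα coordinates over frames
  (population normalization, equal frame weights, no mass weighting),
  diagonalized with a symmetric eigensolver; eigenvalues are clipped at
  zero against roundoff. Frames are superposed onto their mean structure
  (two fixed-point passes) unless `align=False`, which is the right setting
  when frames are already in a common frame or when an exact hand oracle is
  wanted.
- **β-sheet content.** A Cα-geometry rule, since models may be Cα-only:
  a residue is *helix* when a Cα(i)–Cα(i±3) distance falls in 0.42–0.60 nm
  (the α-helical i,i+3 range); *β* when its local backbone is extended
  (bend angle ≥ 120°) *and* the same residue in another chain lies within
  0.6 nm (cross-β pairing; ideal spacing 0.48 nm); otherwise coil. Terminal
  residues lack the bend stencil and are excluded from the assignable
  count; chains shorter than 5 residues are rejected. The rule is validated
  by construction (ideal stacks are fully β; ideal helical traces contain
  no β) — no numeric agreement with any hydrogen-bond-based assignment is
  claimed.
- **Interface area.** Shrake–Rupley SASA (probe 0.14 nm, 960 sphere points
  per atom by default, via biotite) with a uniform 0.17 nm Cα pseudo-atom
  radius for Cα-only models; interface = (SASA_A + SASA_B − SASA_AB)/2.
  Sampling makes the zero of well-separated groups exact only to ~10⁻³ nm².
  Note the degenerate case of an exactly superimposed duplicate partner:
  geometrically the complex surface equals one copy's surface, so the
  interface evaluates to SASA_A/2, and point-on-surface coincidences make
  the numerical result sensitive to strict-vs-inclusive occlusion tests;
  tests probe this case with an ε-offset copy.

Coordinates are held in nm; PDB I/O (via biotite) converts to/from Å. PDB's
fixed %8.3f precision limits round-trips to 10⁻⁴ nm.

## Transwell and ThT

EP = slope(Q_r(t))/(A·C_d0) with Q_r = C_r·V_r, regressed over samples
where the receiver holds < 10% of the initial donor amount (sink
condition); if fewer than two samples qualify, the earliest two are used.
A negative slope is flagged, and EP reported as 0, rather than silently
clipped. Aliquot sampling is assumed volume-replaced (no receiver-volume
depletion correction). Time units are minutes for EP (conventionally
printed in cm/min) and hours for ThT. Percent passage is the amount ratio
100·Q_r(t)/Q_0, invariant to concentration units. ThT metrics operate on
the trace normalized to its zero-time intensity and are therefore invariant
to multiplicative rescaling; "time to fraction" returns the earliest
*sampled* time at or below the fraction (NaN = not reached), with no
interpolation between samples.

The noise-free EP recovery check uses a 0–60 min sampling grid: the
regression's curvature bias grows as k·T/2 with the window length T, and
the 60 min window keeps it under 1% at P = 9 × 10⁻⁵ cm/min, matching the
assumption that permeability is estimated from the early linear regime.

## Statistics

One-way fixed-effects ANOVA from between/within sums of squares; the F
p-value from the F(k−1, N−k) distribution; zero within-group variance is an
error. Tukey HSD uses the pooled within mean square with the Tukey–Kramer
SE for unbalanced groups and the studentized-range distribution for
adjusted p-values. The t-test is the classical pooled-variance Student test
(not Welch), one-tailed in a stated direction; α = 0.05 throughout.
Implementations are written from the formulas and cross-checked in the test
suite against independent library routines.

## Problem sizes in the test and acceptance runs

Synthetic fields are 1600–2000 nm at 1–2 nm pixels (≈ 1–4 megapixels) with
120–200 particles, recovery statistics use 20–24 seeded replicates, and
trajectories use 5–40 frames of 5 × 26 Cα atoms — sizes chosen so every
estimator's recovery error is measured well away from small-sample noise
while the whole suite runs in well under a minute per module.

## Known limitations

- The AFM model omits tip convolution; fitted lateral sizes from real
  images would be tip-broadened even though heights are not.
- The β-sheet rule is geometric and Cα-based; it is not comparable
  number-for-number with DSSP-class assignments.
- SEM over trajectory frames ignores autocorrelation and will understate
  uncertainty for strongly correlated frames.
- The EP estimator assumes passive two-compartment exchange; active
  transport or membrane binding would bias it.
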
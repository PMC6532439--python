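# hdlamyloid

Quantitative analytics for studies of how the lipidation state of
apolipoprotein A-I (apoA-I) — lipid-poor, discoidal (nascent) HDL, or mature
spherical HDL — affects β-amyloid (Aβ) fibrils and their transport across an
in vitro blood-brain-barrier (BBB) model. The package bundles the complete
numerical machinery such a study needs, exercisable end-to-end on synthetic
data with known ground truth:

- **AFM quantification** — fibril growth/disassembly as the percentage of
  image pixels above a fixed height threshold (default 1.5 nm), with
  replicate averaging and normalization to the t = 0 value.
- **Particle morphometry** — sphere-vs-disc discrimination of HDL from
  per-pixel height distributions: a tangent-sphere height model
  P(h) ∝ (h − R) on [R, 2R] for spherical HDL, a Gaussian-broadened δ-peak
  plus upper-tail regression for discoidal HDL, and lipid:protein
  stoichiometry from weight ratios and molecular masses.
- **Fibril structural order** — for cross-β Cα coordinate models and
  trajectories: the fibril order parameter

  ordP = (1/N_r) Σ_r ⟨v_r, z⟩ / (|v_r|·|z|),

  where v_r joins the Cα of residue r in the first chain to the same
  residue in the last chain and z is the fibril axis (ordP = 1 for a
  perfect amyloid stack); Kabsch superposition and RMSD;
  essential-dynamics PCA of the Cα covariance; a Cα-geometry β-sheet
  assignment; and buried solvent-accessible surface between binding
  partners.
- **Transwell / ThT kinetics** — apparent endothelial permeability
  EP = (dQ/dt)/(A·C_d0) from sink-condition regression, percent passage,
  and thioflavin-T disaggregation metrics (percent reduction, time to a
  fraction of the starting signal).
- **Statistics** — one-way ANOVA with Tukey HSD post hoc and the one-tailed
  pooled-variance Student t-test.
- **Synthetic data** — generators for all of the above (AFM particle and
  worm-like-chain fibril fields, ideal cross-β stacks with controllable
  distortion, two-compartment permeation series, ThT decays), seeded and
  bit-reproducible.

## Worked example

```python
import numpy as np
from hdlamyloid import synth, morphometry, structure, transwell

# Classify a synthetic discoidal-HDL AFM field and fit its height
spec = synth.DiscFieldSpec(n_particles=200, disc_height=12.9, disc_diameter=13.0,
                           field_size=2000.0, pixel_size=2.0, noise_sd=0.2, seed=0)
dist = morphometry.height_distribution(synth.gen_disc_field(spec))
cls = morphometry.classify_population(dist)
print(f"shape: {cls.model}  h_D = {cls.disc_fit.height_hD:.2f} nm")

# Order parameter of an ideal vs distorted cross-β pentamer
fib = synth.gen_ideal_fibril(synth.IdealFibrilSpec())
print(f"ordP (ideal stack) = {structure.order_parameter(fib):.3f}")
dis = synth.gen_ideal_fibril(synth.IdealFibrilSpec(distortion_sd=0.3, seed=1))
print(f"ordP (distorted 0.3 nm) = {structure.order_parameter(dis):.3f}")

# Recover a known permeability from a simulated transwell series
ts = synth.TranswellSimSpec(true_permeability=9e-5, donor_conc0=500.0,
                            sample_times=np.arange(0, 61, 10.0))
ep = transwell.endothelial_permeability(synth.gen_transwell_series(ts))
print(f"EP = {ep.EP:.2e} cm/min")

# Lipidation stoichiometry of a discoidal preparation
print(f"molar ratio = {morphometry.lipidation_molar_ratio(2.5, 760.1, 28000.0):.1f}")
```

prints

```
shape: disc  h_D = 12.90 nm
ordP (ideal stack) = 1.000
ordP (distorted 0.3 nm) = 0.954
EP = 8.92e-05 cm/min
molar ratio = 92.1
```

The disc fit recovers the simulated 12.9 nm disc height; the ideal stack is
perfectly ordered (ordP = 1) and per-atom distortion lowers ordP below 1;
the permeability regression recovers the simulated 9 × 10⁻⁵ cm/min within
the curvature of the early-time window; and a 2.5:1 POPC:apoA-I weight
ratio corresponds to 92 lipids per apoA-I (POPC 760.1 g/mol, apoA-I 28 kDa).

A command-line interface mirrors the library (`hdlamyloid --help`):
subcommands `simulate`, `afm-quant`, `particle-fit`, `fibril-ordp`,
`transwell-ep`, `tht` and `stats` read/write plain-text formats (TSV height
maps with JSON sidecars, PDB coordinate models, CSV time series).

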
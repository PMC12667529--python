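# aggrefinger

Single-particle fingerprinting of protein aggregates from single-molecule
pulldown (SiMPull) experiments: diffraction-limited puncta counting, dSTORM
morphometrics, subpopulation classification, cohort statistics, a linear
discriminant disease signature, and total-proteome-corrected
aggregate-fraction proteomics.

## Who this is for

Labs using surface-capture single-molecule assays to characterize soluble
nanoscopic protein aggregates (for example TDP-43 assemblies from brain
extracts in motor neuron disease). A SiMPull experiment captures multimeric
assemblies on a functionalized coverslip with the same antibody for capture
and detection, so monomers are excluded; TIRF imaging then reads each
captured particle out as one diffraction-limited punctum, and dSTORM on the
same surface resolves each particle's nanoscale shape. This package takes
the resulting image stacks and localization tables to donor-level statistics
and a cohort signature, with a fully ground-truthed synthetic-data generator
standing in for tissue data.

## What it computes

- **Puncta counting** — mean projection over the trailing 40 frames, local
  maxima above median + k·MAD (k = 5), sub-pixel centroids, per-spot
  intensities, and count scaling by tissue weight × protein concentration.
  A field of view spans 512 px × 107 nm/px = 54.784 µm.
- **Colocalization** — nearest-neighbour matching within 4 px, one-to-one,
  with a chance-match estimate from mirroring the second channel's
  x-coordinates: P(chance) ≈ 1 − exp(−ρπr²) for spot density ρ.
- **Morphometrics** — per aggregate, after a strict <30 nm precision filter,
  first-300-frame discard, cross-correlation drift correction and DBSCAN
  (ε = 0.5 px, minPts = 5): area A, perimeter, eccentricity e of the
  second-moment ellipse, axis lengths, skeleton length L (summed branch
  distance of the topological skeleton), and localization density
  n/A (loc/nm²).
- **Subpopulations** — inclusive thresholds: *long* L ≥ 100 nm, *fibrillar*
  e ≥ 0.9, *dense* n/A ≥ 0.01 loc/nm² (else *sparse*), *bright* scaled
  intensity ≥ 0.9 A.U.; 2³ Sankey tabulation and per-donor radar profiles.
- **Cohort statistics** — cumulative distributions interpolated at 101
  proportion points (0, 0.01, …, 1) by the nearest method; two-sample
  Kolmogorov–Smirnov tests on matched-n subsamples (n = 1000, drawn without
  replacement, median-summarized over bootstrap repeats); Welch's t; one-
  sample t against a relative proportion of 1; Holm–Bonferroni or Bonferroni
  families.
- **Disease signature** — LDA over 15 standardized donor-profile features
  with combined region-cohort classes, solving S_b v = λ S_w v; explained
  variance per discriminant and pseudo-eigenvector feature rankings.
- **Proteomics** — contaminant removal, the ≥2 peptides / ≥1 unique rule,
  reference-sum normalization, per-case ratios against mean control
  abundance, corrected ratio = (aggregate ratio)/(total ratio), one-sample
  t on log₂ ratios, and volcano calls at |log₂| > 1, −log₁₀ p > 1.3.

## Worked example

```python
import numpy as np
from aggrefinger import synthetic as syn, detect, morphology as morph, subpopulations as subpop

# a synthetic field of view with 12 known puncta at SNR ~ 10
rng = np.random.default_rng(0)
spots = syn.random_spot_layout(12, 512, 512, amplitude=100.0, rng=rng)
stack, truth = syn.simulate_tirf_stack(syn.TirfSimSpec(n_frames=50, spots=spots, seed=0))
det = detect.detect_puncta(detect.mean_projection(stack, last_n=40))
print(f"detected {len(det)} puncta; first centroid ({det.x_px[0]:.2f}, {det.y_px[0]:.2f})")

# a 180 nm rod imaged by dSTORM at 12 nm localization precision
agg = syn.GroundTruthAggregate(length_nm=180.0, n_localizations=360,
                               orientation_rad=0.6, center_nm=(5000.0, 5000.0))
table, _ = syn.simulate_localization_table([agg], n_frames=5000, seed=1)
records = morph.measure_all(morph.filter_localizations(table))
r = records.iloc[0]
print(f"aggregate: skeleton length {r.skeleton_length_nm:.0f} nm, "
      f"eccentricity {r.eccentricity:.3f}, density {r.density_loc_per_nm2:.4f} loc/nm^2")
```

prints

```
detected 12 puncta; first centroid (308.91, 369.86)
aggregate: skeleton length 164 nm, eccentricity 0.970, density 0.0459 loc/nm^2
```

All 12 simulated puncta are found (sub-pixel centroids are within ~0.2 px of
truth), and the 180 nm rod measures 164 nm with eccentricity well above the
0.9 fibrillar cut — so this aggregate classifies as long ∧ fibrillar ∧ dense.

The same stages are available from the shell:

```bash
aggrefinger simulate --kind stack --out fov.tif --seed 3
aggrefinger detect --stack fov.tif --k 5 --out spots.csv
aggrefinger morpho --locs locs.hdf5 --eps 0.5 --min 5 --out aggregates.csv
aggrefinger run --seed 2 --out results/   # synthetic end-to-end run
```

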
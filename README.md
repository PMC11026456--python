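# mechanophen

Mechanical phenotyping toolkit for cells and multicellular clusters on
soft substrates, plus a synthetic-microscopy generator so every pipeline
stage is testable with known ground truth and no external data.

What it computes:

- **Traction force microscopy** — multi-pass PIV (normalized
  cross-correlation, square 32-px interrogation windows with 0.5 overlap,
  Gaussian sub-pixel peak fit, median validation) and regularized
  Fourier-transform traction cytometry on the Boussinesq half-space
  Green's function, with mean-traction summaries.
- **Force-dipole analysis** — first moment of the masked traction field,
  symmetrized and diagonalized; anisotropy ratio Mδ = |λ_major|/|λ_minor|.
- **Shape / deformability metrics** — ImageJ-style roundness
  (4A/π·major²), RT-DC deformation (1 − 2√(πA)/P), porosity
  (hull area / area), and the quality gate (porosity ≤ 1.05,
  area ∈ [150, 350] µm²).
- **Cluster wetting geometry** — spherical-cap contact angles from
  (R, H) via R_sphere = (R² + H²)/(2H), wet θ = asin(R/R_sphere),
  dewet α = 180° − asin(R/R_sphere); (R, H) extraction from z-stacks.
- **Segmentation & intensities** — threshold/morphology segmentation,
  cytoplasm masks, background-subtracted means, nuclear/cytoplasmic
  ratios, multi-plane intensity profiles.
- **Tracking** — proximity-based centroid linking and accumulated-
  distance / total-time migration velocity.
- **Expression scoring** — per-cell stemness signature score (mean of
  BCL11B, AXIN2, LGR5, ASCL2, LRIG1), 75th-percentile LGR5+
  classification, kNN-graph diffusion smoothing, and ERM-gene
  (EZR/RDX/MSN) group contrasts.
- **Synthetic data** — bead image pairs deformed by known elastic
  fields (with an independent real-space direct-summation oracle),
  multi-channel cell scenes, spherical-cap stacks, contour populations,
  trajectories, and count matrices with planted subpopulations.

## CLI

All functionality is exposed through the `mechanophen` command:

```sh
# generate synthetic inputs (any of: tfm scene cluster contours tracks expression)
mechanophen simulate tfm --config tfm.yaml --seed 1 --out sim/

# TFM chain
mechanophen piv --reference sim/reference.tif --deformed sim/deformed.tif \
    --pixel-size 0.5 --out disp.csv
mechanophen tractions --displacement disp.csv --youngs-modulus-kpa 3 \
    --poisson 0.5 --out tractions.csv --summary summary.json
mechanophen dipole --traction tractions.csv --mask mask.tif \
    --pixel-size 0.5 --out dipole.json

# shape metrics and the deformability-cytometry gate
mechanophen shape --metric deformation --contours contours.csv --out metrics.csv
mechanophen rtdc-gate --contours contours.csv --porosity-max 1.05 \
    --area-min 150 --area-max 350 --out gated/

# wetting geometry, tracking, signature scoring
mechanophen wetting --stack cluster.tif --pixel-size 0.5 --z-step 0.25 --out wetting.csv
mechanophen track --centroids centroids.csv --frame-interval-min 20 \
    --max-link-um 30 --out velocities.csv
mechanophen signature --expression expr --percentile 75 --out scores/
```

## Conventions

- Rasters are row-major with the origin at the top-left pixel centre;
  x runs along columns, y along rows; physical units are µm via
  `pixel_size`.
- Substrate default Poisson ratio is 0.5 (incompressible polyacrylamide).
- Traction sign: the stress exerted by the cell on the gel; the
  zero-frequency (net force) mode of the inversion is set to zero.
- FTTC regularization is zeroth-order Tikhonov, default λ = 1e-9·E.
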
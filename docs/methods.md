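# Methods

This note describes the model and procedures implemented by `centrofind`,
the parameter choices and their defaults, and the limits of the synthetic
validation studies shipped with the package.

## Problem

Detect the centres of cell bodies (typically nuclei or cell-type-specific
marker signal) in 3D fluorescence time series, with enough reliability to
track individual cells over hours and read off division events — in tissue
where cells are densely packed, anisotropically sampled in z, and imaged at
low signal-to-noise to limit phototoxicity.

## Proximity-map regression

Rather than segmenting cell boundaries, the model regresses a **proximity
map**: a per-voxel score in [0, 1] that peaks at annotated cell centres.

- **Training target.** For an annotated 2D plane with clicked centres
  `p_1..p_n`, the target at pixel `q` is
  `max_i exp(-||q - p_i||^2 / (2 sigma^2))`, truncated to 0 beyond `3 sigma`.
  `sigma` is set to about half the cell radius. Max semantics (not sum)
  keeps the target bounded in dense clusters.
- **Features.** A 2D multiscale filter bank per plane and channel: the raw
  intensity plus, at scales (1, 2, 4, 8, 16) pixels, the Gaussian
  smoothing, gradient magnitude, Laplacian of Gaussian, and the two
  eigenvalues of the 2D Hessian. Boundaries use reflect padding. With one
  channel this is 26 features per pixel.
- **Regressor.** A random forest (30 trees, maximum depth 10, minimum 20
  samples to split, `ceil(n_features / 3)` features per node). Training
  pixels are sampled at a rate of 1/5, stratified per annotated region. One
  forest is trained per annotated cell class, so e.g. "cell" and
  "dividing" classes give independent maps.
- **Annotation economy.** Because the regressor is trained per pixel,
  a handful of annotated planes (single clicks on centres, plus at least
  one cell-free plane for background) is enough; the training-level study
  below quantifies this.

## 3D centre detection

The per-plane proximity predictions are stacked into a 3D map and centres
are extracted by a determinant-of-Hessian blob filter:

- The map is smoothed with an anisotropic Gaussian of `sigma = h / 2` per
  axis, where `h = (hz, hy, hx)` are the expected object radii in voxels
  (this is how z-anisotropy is handled: pass a smaller `hz`).
- The response is `det(-H)` of the smoothed map, positive at bright blobs.
- Detections are strict local maxima of the response within an ellipsoidal
  footprint of radii `h`, above a threshold expressed as a fraction
  (default 0.1) of the per-timepoint maximum response. Plateaus are reduced
  to their centroid. Detections whose footprint touches the volume border
  are flagged.

The threshold is the one user-facing sensitivity knob; in the validation
studies it is tuned on data independent of the evaluation set.

## Evaluation

Predicted and true centres are matched one-to-one by maximum-cardinality,
minimum-cost bipartite assignment, with matches only allowed within a
tolerance radius (anisotropic tolerances are supported by scaling each
axis). Precision, recall and F1 follow; both-empty scores 1, empty
prediction against non-empty truth scores 0.

## Synthetic phantoms

The generator renders what the method must survive, not realistic tissue:

- Spheres of radius `r` (default 8 voxels, 10% jitter), amplitude 1.0 on
  background 0.2, blurred with `sigma = r / 4`, plus Gaussian noise with
  standard deviation `amplitude / SNR` (default SNR 5).
- A `clustering` fraction of cells (default 75%) is placed touching a
  neighbour at about 2 r spacing, to stress the dense-packing case.
- Division series add, at scheduled frames, a 2-frame spindle-like
  ellipsoid (1.6 r by 0.7 r) replacing the mother, followed by two
  daughters (0.45 r radius, 0.7 amplitude) that drift apart at 0.25
  voxels/frame. Mothers are kept at least 1.6 r from the in-plane border
  because border-clipped spheres under reflect padding mimic elongated
  spindle figures.

Not emulated: uneven illumination, depth-dependent attenuation, true point
spread function anisotropy, touching non-spherical cells, photobleaching,
or drift of the whole tissue. Scores on phantoms are an upper bound on real
data.

## Tracking and division analysis

- **Linking.** Frame-to-frame optimal assignment of detections, gated at a
  maximum displacement; tracks can bridge up to `max_gap` missed frames
  using linear extrapolation of position.
- **Division signal.** The "dividing"-class proximity map is sampled along
  each track (max within 3x3x3 voxels of the tracked position). A centered
  moving average (default 21 frames, truncated at the series edges) is
  subtracted to remove slow background, and the residual is smoothed over
  3 frames because genuine spindle figures persist for 2 or more frames
  while single-frame spikes are regression noise.
- **Event rule.** Peaks of the smoothed residual above
  `max(3 x MAD, 0.1)` (MAD of the residual, plus an absolute floor on the
  [0, 1] proximity scale), separated by at least half the moving-average
  window. Both parts of the threshold matter: the MAD term adapts to the
  track's noise, the floor rejects tracks whose signal never leaves the
  noise floor (e.g. non-dividing cells whose MAD is near zero).
- **Cycle statistics.** Inter-event intervals times the frame interval are
  cycle lengths; cells with fewer than two events are excluded; divisions
  per hour is `60 / mean cycle length`.

## Segmentation refinement

Detected centres can be promoted to instance labels: stamp ellipsoids of
the expected radii around each centre (overlaps split by nearest centre in
radius-scaled distance), evolve the union a few iterations (sensible range
2–6) of a morphological Chan–Vese active contour against the intensity
image, then re-partition by marker-controlled watershed from the centres so
the label count always equals the detection count. The morphological
curvature operator's internal alternation is pinned before each call so the
result is deterministic.

## Validation studies and problem sizes

The studies in `centrofind.benchmark` (used by the acceptance tests and
`scripts/acceptance.py`) run at desk scale, chosen so the full suite
completes in minutes on one core while keeping the statistics meaningful:

- **Detection benchmark.** 128x128x40 phantoms with 30 cells of radius 8
  at SNR 5, 75% clustered. Train on 1 phantom, tune the threshold on 5,
  evaluate precision/recall/F1 on 25, at a strict 4-voxel tolerance and at
  the generous half-cell-size (one radius) tolerance.
- **Division study.** Five independently seeded 78-frame series
  (64x64x16, 3 cells, 4 min/frame) with staggered division schedules whose
  mean cycle is about 90 minutes (alternating 22/23-frame intervals).
  Recovered mean cycle and divisions/hour are compared to the schedule.
- **Training-level study.** Held-out F1 as the number of annotated planes
  grows 1 -> 3 -> 6, five replicates, threshold tuned per level on the
  training phantom.

## Numerical choices

- All randomness flows from explicit integer seeds; derived seeds are drawn
  below 2^31. Outputs (detection CSVs) are byte-identical across runs for
  fixed seeds.
- Plateau maxima round their centroid toward the lower index so detection
  coordinates are deterministic integers.
- Volume normalization is per timepoint and channel to the 0.1/99.9
  intensity percentiles, so the proximity model sees a stable input range.

## Limitations

- The forest is trained per plane in 2D; strongly anisotropic structures
  that only make sense in 3D context are handled only through the 3D blob
  step.
- The event rule's absolute floor (0.1) assumes the dividing-class map is
  meaningfully calibrated to [0, 1]; a poorly trained class model can push
  real events under the floor.
- Phantom results do not transfer quantitatively to real microscopy; they
  validate the algorithmic chain, not biological performance.
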
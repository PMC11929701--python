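# Methods

This note records the models, conventions, and numerical choices behind
`usnav`, and what the synthetic phantom does and does not establish about
real intraoperative data.  Units are millimetres and degrees throughout; the
world frame is right-handed.

## Problem setting and coordinate model

A robot-held 2D ultrasound probe sweeps the liver during a breath-hold.
Every frame carries a known rigid pose `T_pose` mapping image-plane
millimetre coordinates `(u·s_x, v·s_y, 0)` to the world; pixels are 0-based
`(u, v) = (column, row)` with pixel (0,0) centred at the probe-frame origin.
Preoperative planning supplies a vessel point cloud and tumor targets in CT
coordinates.  The registration unknown is the rigid map `T : CT → world`;
once recovered, targets are localized as `T · x_ct` and CT slices are
resampled on the live image plane through `T⁻¹`.

Rigid transforms are validated strictly at construction (`RᵀR = I` and
`det R = 1` within 1e-9, last row exact); long products are re-orthonormalized
via SVD so the invariant survives composition.

## Segmentation filters

The recognizer contract is a per-pixel vessel confidence in [0, 1].  The
decision rule is *strictly* above 0.5 (confidence exactly 0.5 is background),
and connected regions with fewer than 40 or more than 50,000 pixels are
removed; both bounds are read literally, so 40- and 50,000-pixel regions
survive.  "Continuous region" is interpreted as 8-connectivity, the common
imaging convention.  The classical intensity segmenter used on synthetic
frames maps intensity `I` to confidence `clip(0.5 + c_dark − I, 0, 1)` with
`c_dark = 0.5`: monotone decreasing in intensity (vessels are hypoechoic) and
crossing the 0.5 decision level exactly at the dark cutoff.  It is a
pluggable stand-in with the same interface a trained network would have, not
a claim about clinical image segmentation.

## Reconstruction

`reconstruct_cloud` keeps the contract "one point per retained mask pixel"
(with a stride subsampler).  The *pipeline*, however, feeds it mask
boundaries (pixels with a background 8-neighbour) rather than filled masks.
This is a deliberate design choice: the CT operand is a surface sampling,
and the bifurcation feature score consumes surface normals; PCA normals
estimated on a solid, volume-filled cloud are direction-noise and score
spuriously high everywhere, while boundary pixels sample the tube surface as
stacked cross-section rings whose k-NN neighbourhoods (default k = 30) span
adjacent rings and yield stable radial normals.  Clouds are voxel-downsampled
(default 0.5 mm, centroid per voxel, lexicographic voxel order for
determinism) before normal estimation.  Normal signs point away from the
local neighbourhood centroid — outward for tubes — but every consumer is
sign-insensitive, so orientation failures are harmless.

## Bifurcation features

The feature score of a point is `1 − ‖mean of sign-aligned neighbour normals
within radius r‖` (default r = 3 mm, roughly the calibre of the vessels of
interest).  On a straight tube of radius comparable to r the azimuthal spread
of radial normals gives a baseline score well below the 0.2 selection
threshold; at bifurcations, normals from two or three merging tubes mix and
the score rises sharply.  Thin, strongly curved branches also score above
threshold — acceptable, since such points are geometrically informative for
registration even if they are not junctions.  Sign-alignment to the centre
point's normal makes the statistic invariant to flipping any subset of
normals.

Selection is greedy non-maximum suppression in descending score order (ties
broken by index, for determinism).  The suppression radius is a separate
parameter, default 1 mm rather than the 3 mm scoring radius: with 3 mm
suppression a depth-3 tree yields only a few tens of features, too few for
the rigid fit to average out per-feature localization noise; at 1 mm the cap
of 500 features is reached and the recovered transform improves by roughly
an order of magnitude.  Feature *positions* are sample points of the parent
cloud (the set stores indices), so feature localization is limited by the
sampling density — this matters for interpreting RMS-A between independently
sampled clouds (see "What the phantom shows" below).

## Registration

Each ICP iteration: nearest-neighbour correspondence from transformed source
features to target features; rejection of pairs farther than 3× the median
pair distance (at least 3 pairs are always kept); closed-form weighted
Kabsch refit on the survivors; and *monotone acceptance* — if the refit does
not decrease the RMS-A over the accepted pairs, the previous transform is
kept and iteration stops.  Convergence is declared when the improvement
falls below 1e-4 mm (or immediately at RMS-A = 0); the per-iteration RMS-A
trace is recorded and is non-increasing by construction.  Degenerate fits
(collinear correspondences, second singular value ≤ 1e-9 of scale) raise
rather than returning a reflection; the proper-rotation branch is enforced
by sign-flipping the smallest singular direction.

Initialization aligns centroids and principal axes; the four proper sign
combinations of the axes are scored by nearest-neighbour RMS and the best is
kept.  Principal axes are unreliable when the two minor eigenvalues of a
feature cloud are close (nearly tubular second moments), which does occur
for some vessel-tree geometries, so `register_clouds` is multi-start: ICP
runs from the principal-axes initializer *and* from the identity, and the
lower final RMS-A wins.  For this application's moderate misalignments
(≤ 15°, ≤ 30 mm against clouds ~100 mm across) the identity start stays in
the correct basin when the axes initializer does not.  The identity-start
result is preferred only when strictly better (by > 1e-9 mm), so the
equivariant principal-axes branch decides ties and registration remains
exactly equivariant under rigid motion of the inputs in the generic case.

RMS-A is computed over the final accepted feature pairs only — "paired
feature points", not all points.

## Target localization, plan validation, fusion

Target localization is the homogeneous product `T · x_ct`; its error metric
(TLE) is the Euclidean distance to the ground-truth world position.  The
needle angle is measured between the needle axis and the skin (probe-face)
plane — 90° is perpendicular entry — so the mechanism envelope 10–50°
excludes both grazing and near-perpendicular paths; depth is the
entry-to-target distance, envelope 0–100 mm.  Fusion resamples the CT volume
once per ultrasound pixel by trilinear interpolation; pixels that leave the
voxel grid receive the fill value exactly (interpolation is never blended
with fill, so in-volume values obey the volume's min/max by convexity).  The
overlay is a linear alpha blend (α = 0.5), display-only.

## The synthetic phantom

* **Vessel tree** — a full binary tree of straight cylinders: root radius
  3 mm and length 30 mm along +z, per-generation radius decay 0.75 and
  length decay 0.72, branch angles uniform in 20–45° at roughly opposite
  azimuths, default depth 3 (15 segments, 7 bifurcations, ~2,500 mm² of
  surface).  Cylinders make cross-section and surface-area oracles exact.
* **Surface sampling** — Poisson counts at a given density (default
  2 pts/mm² ≈ 5,000 points per tree) with per-segment seed substreams, so a
  segment's sample is independent of the rest of the tree.
* **Sweep** — ~60 transverse planes covering the tree at 0.2 mm/px.  A pixel
  is vessel iff its world-mapped centre lies inside a tube, with the signed
  distance jittered by Gaussian boundary noise (σ = 0.2 mm at study
  conditions).  Vessels render at intensity 0.15 and background at 0.8 under
  multiplicative uniform speckle (0.75–1.25) — separable by the 0.5
  confidence rule even at the speckle extremes, by design: appearance realism
  is not the point, the mask and its noise model are.
* **Deformation** — breathing residual at breath-hold, modelled as three
  mutually orthogonal sinusoidal displacement components (wavelength 80 mm,
  random directions and phases) whose amplitudes sum in quadrature to the
  nominal amplitude, so the bound `‖d(x)‖ ≤ amplitude` holds pointwise and
  amplitude 0 is exactly the identity.  No quantitative breath-hold statistics
  were available; the default 1 mm amplitude is a deliberately mild nuisance
  term consistent with a rigid-registration regime.
* **CT cloud** — the (deformed) surface sampling under a hidden rigid
  transform (rotation ≤ 15°, translation ≤ 30 mm, uniform over axis/ball),
  plus Gaussian jitter *along the surface normal* (surface-localization
  error; the same model as the sweep's boundary noise).
* **Targets** — four per case, placed 2 mm-past-lumen to 24 mm off a random
  segment, always within the 30 mm vessel-proximity bound under which
  puncture is recommended; CT-space targets are the deformed, transformed
  world targets.

Everything is a pure function of its seed.

## What the phantom shows — and does not

With shared base samplings (a cloud and its transformed copy), registration
recovers the hidden transform to ~1e-13, confirming the optimizer itself is
exact.  With independent jitter on a shared base sampling (σ = 0.05 mm), the
mean RMS-A over 20 seeds is ≈ 0.073 mm — the √2·σ regime expected when
matched features are the same physical sample points.  With fully
*independent* samplings (CT surface vs reconstructed boundary rings), matched
features are different physical points and RMS-A floors at the sampling
spacing (~0.9 mm at study densities) no matter how good the transform is;
transform quality is then visible only through TLE.  At the full study
conditions (deformation 1 mm, boundary noise 0.2 mm) the mean TLE over 20
seeds is ≈ 0.6–1.9 mm depending on the seed block; noiseless undeformed
pipeline runs land at ~0.1–0.4 mm, limited by the independent-sampling floor,
not by noise.  None of this certifies clinical accuracy: the phantom has no
acoustic artefacts, no segmentation failure modes, no probe-calibration
error, and its deformation is smoother and smaller than real respiratory
residuals.  What it does establish is that the navigation computation —
filters, reconstruction geometry, feature detector, ICP, target mapping —
is correct, deterministic, and meets the 3 mm design target under its own
stated noise model.

## Problem sizes

Default experiment sizes were chosen so a full study is minutes, not hours,
on one CPU: 20-case studies, ~5,000-point clouds, 60 frames of ~400×200 px.
All are configuration, not constants.

## Known limitations

* Rigid registration only; the deformation term is a nuisance, not a model
  to be estimated.
* Feature positions are not sub-sample refined; RMS-A between independently
  sampled clouds is sampling-limited (see above).
* The fusion path supports axis-aligned NIfTI volumes only.
* No real-time/streaming reconstruction; the package processes a completed
  sweep.
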
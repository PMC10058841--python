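# Methods

## Problem and data model

A hyperspectral LiDAR (HSL) scanner returns, per scan point, 3D
coordinates and a spectrum of laser-echo peak intensities on a fixed
101-channel axis (550–1050 nm, 5 nm steps). `treeclass` classifies each
point of a fruit-tree scan into one of four components — unripe fruit,
ripe fruit, wood, leaf (codes 1–4, in that order) — and renders the
result as a colored point cloud.

The pipeline has five stages:

1. **Reflectance calibration.** Echo intensities are converted to
   reflectance against a scan of a diffuse reference panel of known
   reflectivity ρ_b (default 0.99) placed at the sample distance:
   ρ_t(λ_i) = V_t(λ_i)/V_b(λ_i) · ρ_b(λ_i), per channel. Intensity
   units cancel in the ratio, so V may be volts or digitizer counts.
   Negative intensities (noise) pass through as negative reflectance by
   default; an optional clamp floors them at zero. Background removal is
   a single coordinate threshold on the range axis (default y), because
   the backdrop sits a fixed distance behind the sample.
2. **Feature extraction.** Nine features per point: R700, R730, R780,
   R850, R900; the mean reflectance over 760–930 nm (inclusive at both
   ends, 35 channels); CI_red_edge = R780/R710 − 1;
   NDVI = (R800 − R670)/(R800 + R670);
   NDRE = (R790 − R720)/(R790 + R720). Band lookups are exact-match on
   the grid; zero denominators produce NaN rather than a clipped value,
   and classifiers refuse rows with missing features.
3. **Preliminary classification.** Random forest (8 trees), RBF-SVM
   (γ = 0.1, C = 10) or a one-hidden-layer sigmoid network (9–5–4).
   Labeled data are split 7:3 (unstratified uniform random; round() of
   n·0.7) into training and validation. Standardization is fitted on the
   training split only and applied for SVM and the network; forests use
   raw features. Zero-variance features get a unit scale instead of a
   division by zero. The network is trained with Adam
   (learning-rate 0.01, ≤500 epochs, tolerance-based stopping): with
   only five hidden units, quasi-Newton optimization occasionally lands
   in a non-separating local minimum, while Adam at this rate converged
   on every configuration we exercised.
4. **Spatial reprogramming.** Each point is reassigned the plurality
   class of its N spatially nearest neighbors (Euclidean distance,
   self excluded, default N = 12, exposed as a parameter). The default
   pass is *sequential*: labels are rewritten in place in input order,
   so later votes see earlier corrections; a *frozen* mode votes with
   the input labels only and is therefore permutation-equivariant. Ties
   keep the current label when it is among the tied classes, otherwise
   the tied class of the nearest neighbor wins. One pass is the default;
   repeated passes are available. Neighbor lists come from a dense
   distance computation with a stable (distance, index) sort for up to
   4,000 points and from a k-d tree beyond that; both paths return
   identical lists, with exact ties broken toward the lower index.
5. **Evaluation and reconstruction.** Predicted and truth label sets
   are paired at identical coordinates (tolerance 1e-9 m; ambiguous
   pairings are an error; matching by index is used when both label
   sets live on one cloud object — the two paths agree by construction).
   Per class j, T_j correct of H_j truth points give K_j = T_j/H_j and
   K_Overall = ΣT_j / ΣH_j, which is identically the H_j-weighted mean
   of the K_j. Reconstruction writes a standard colored PLY (per-vertex
   uint8 RGB, one fixed color per class) plus a two-color PLY of the
   points whose label the reprogramming pass changed.

## Synthetic scenes

No instrument scans ship with the package, so a generator produces
labeled scenes with the structure the pipeline exploits; its defaults
are the package's reference study conditions.

**Geometry.** A vertical trunk cylinder (radius 5 cm, height 1.4 m) with
five tilted branch cylinders (radius 2 cm, length 45 cm); fruit spheres
(radius 5 cm) dangle below branch points on stems of varying length;
leaf discs (radius 6 cm) float around the branches with random
orientation. Points are sampled uniformly on each surface, and the
number of spheres and discs follows from one shared areal density (set
by the wood count), because a scanner samples every surface at roughly
the same angular rate. Placement keeps a ~5 cm gap between components —
comparable to the radius a 12-point neighborhood spans at the default
density — so neighborhoods away from silhouettes stay class-pure.
Default counts: 1,500 wood, 2,000 leaf, 750 + 750 fruit (a
leaf-dominated canopy with minority fruit classes), 5,000 points total.

**Spectra.** Analytic base curves encode the class signatures: wood
rises linearly 0.15→0.40 across the grid; leaf and unripe fruit have a
sigmoidal chlorophyll red edge centered at 715 nm (NIR plateaus 0.45 and
0.38); ripe fruit is a flat ~20% plateau over 600–900 nm. The curves are
stand-ins constrained by those qualitative properties, not digitized
instrument spectra; i.i.d. Gaussian channel noise (sd 0.02 reflectance)
is added and results are clipped at zero.

**Edges.** Per class, the 15% of points geometrically closest to their
primitive's silhouette as seen from the scanner (+y view direction;
sphere/cylinder points with near-tangent normals, disc points near the
rim) are flagged as edges. The rim width is derived from the requested
fraction (quantile thresholding of the silhouette-proximity score)
rather than fixed, so the configured fraction is honored exactly while
edges remain spatially coherent rings and bands. Edge spectra are the
base curve scaled by 1/(1 + a) — so the non-edge class mean exceeds the
edge mean by exactly the configured relative margin a (defaults 10.36%
unripe fruit, 17.81% ripe fruit, 18.18% leaf, 11.06% wood) — then mixed
with weight 0.9 toward a slowly increasing linear ramp of identical
channel mean, which washes out the class's spectral shape without
perturbing the margin. Attenuation is relative, not absolute percentage
points; the flattening weight is high enough that edge spectra of the
three brighter classes overlap heavily under the default noise, which
is the failure mode the reprogramming stage exists to repair.

**What the generator does not emulate:** footprint-level mixed-pixel
physics, multi-return waveforms, incidence-angle and distance falloff,
occlusion, scanner zigzag timing, and natural within-class spectral
variation (moisture, pigment gradients). Passing tests therefore show
that the pipeline recovers edge-driven misclassification when geometry
is informative and non-edge spectra are separable; they do not certify
accuracy on real orchard scans.

## Numerical and design choices

- The 760–930 nm averaging window includes both endpoints (35 channels).
- The 7:3 split is unstratified; a class missing from the training half
  raises a warning, not an error.
- Sequential reprogramming depends on visit order; the order is a
  config parameter (default input order) rather than an assumption.
- Panel files are matched to the grid exactly; off-grid wavelengths are
  an error, never interpolated.
- Coordinate matching replaces exact float equality with a 1e-9 m
  tolerance.
- PLY labels are stored as uchar codes with a header comment naming the
  mapping (PLY has no portable string property); CSV stores class names.
- The dense/k-d-tree crossover (4,000 points) is a speed knob; the
  contract is that both paths return identical neighbor lists.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run 5,000-point scenes
(20 independent seeds for the edge-recovery experiment), 300–500-point
clouds for neighbor-search oracles, and 30-point constructed clouds for
the relabeling trace oracle. On these scenes the preliminary forest
typically reaches K_Overall ≈ 0.98 and reprogramming lifts it to
≈ 0.999, with roughly 80% of changed points carrying the edge flag; the
best N in a 9–15 sweep is scene-specific.

## Known limitations

- Whiteboard averaging (multiple panel scan points per channel) is left
  to the user; the panel is a single V_b vector.
- Sequential-mode results are order-dependent by construction; use
  frozen mode when order-independence matters more than within-pass
  propagation.
- No precision/recall/F1, incidence-angle correction, LAS/LAZ I/O, or
  waveform processing.
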
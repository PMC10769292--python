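# Methods

`osteolcn` analyses 2D confocal-style scans of the osteocyte
lacunar-canalicular network (LCN): it segments osteocyte somas and their
dendritic processes, converts label masks into a cell-to-cell graph, and
compares network metrics between experimental groups. Because public
benchmark data for this task do not exist, the package carries its own
synthetic scene generator with exact ground truth; every claim the test
suite makes is a claim about recovery of planted structure.

## Synthetic scenes

A scene is a field of bright elliptical somas connected by thin curved
dendrites on a dim background.

* **Somas** are filled ellipses with uniformly random orientation,
  semi-axes drawn from 5–10 px. Real osteocyte lacunae are irregular;
  ellipses are the standard shape prior in lacuna-fitting work and are
  sufficient for testing recovery. Placement is rejection sampling with a
  7 px clearance between boundaries (1000 retries per soma, then a
  capacity error). The clearance guarantees that the 4×4 merging dilation
  of the connectomics stage can never fuse two somas.
* **Dendrites** are quadratic Bézier curves between boundary points of two
  somas (connections) or from a soma into free space (dead-end stubs),
  rasterised at a constant per-dendrite width drawn from 1.5–3 px — the
  calibre range of canaliculi in confocal scans at this magnification. The
  curve control point is displaced laterally by a waviness factor (0.2 of
  the chord). Endpoints sit 2 px inside the soma so the rendered path
  overlaps its somas. Candidate paths are rejected (and re-drawn, up to
  six control points, the last one straight) unless they keep a clearance
  from non-endpoint somas and from previously rendered dendrites large
  enough to survive the downstream 2×2/4×4 dilations without spurious
  merges or contacts. Connections that cannot be routed are dropped from
  the planted graph, which therefore always describes exactly what was
  rendered. Pair selection: soma pairs with boundary gap ≥ 12 px connect
  with probability `connection_probability · exp(−d / length_scale)`
  (d = centroid distance), so nearby cells are preferentially wired —
  the length scale is the dial that controls mean connection length.
* **Intensities and noise.** Background 20, dendrites 190, somas 210 on
  the 8-bit scale; a σ = 0.5 Gaussian softens raster edges; additive
  Gaussian noise (sd 8) and a multiplicative linear illumination ramp
  (15 % fall-off left to right) emulate microscope noise and uneven
  staining. The default pixel size is 0.284 µm/px (config-overridable);
  scans of this kind do not come with a universal calibration, so all
  µm-valued outputs scale linearly with this setting.
* **Defaults.** Seven somas per 256×256 field (the average node count of
  manually labelled scans of this kind), dead-end rate 1.5 stubs per
  soma, stub lengths 8–25 px.

Determinism: a scene is a pure function of its configuration (including
the seed); repeated calls are byte-identical.

**The aged regime.** `degrade_to_aged(config, severity)` scales, linearly
in severity ∈ [0, 1] and at severity 1: somas ×0.5, connection
probability ×0.5, pairing length scale ×0.65, stub lengths ×0.6, dead-end
rate ×2. This reproduces the degenerate phenotype reported for aged
cortical bone: fewer osteocytes, fewer and shorter connections, more
blunted canaliculi.

**What the generator does not emulate:** 3D structure and out-of-plane
dendrites, blood vessels and apoptotic cell remnants, spatially
correlated speckle, irregular soma shapes, and dendrite branching.
Passing tests show the chain recovers planted structure under these
idealised conditions; they do not certify accuracy on real scans, where
annotation noise and out-of-plane paths dominate the error budget.

## Thresholding segmentation

Both pipelines share pre- and post-processing and differ only in the
dendrite core operator.

1. Gaussian filter, σ = 2.
2. Binary split at intensity 70. The foreground is divided by a
   morphological opening (disk radius 3) that erases thin structures and
   their smoothing halos; opened components of ≥ 30 px² are the osteocyte
   candidate, the remaining foreground is the dendrite candidate. A pure
   component-area rule cannot do this job: somas joined by bright
   dendrites form a single large component, so thinness, not area alone,
   must separate the classes. A second binary threshold (default 80)
   cleans the dendrite candidate; 80 rather than a higher cut because
   σ = 2 smoothing attenuates a w-px line of amplitude A to a peak of
   roughly bg + A·erf(w/(2√2σ)), and a higher cut would discard most of
   the 1.5–3 px calibre range before the core operator runs.
3. Core operator. *Otsu*: the threshold maximising between-class variance
   over the candidate's intensity histogram restricted to [80, 255];
   dendrite = candidate pixels above it. *Canny*: Sobel gradients on the
   smoothed image, non-maximum suppression, hysteresis at (70, 220) on
   the 8-bit gradient scale; because an edge detector responds on the two
   flanks of a ridge rather than on it, the dendrite mask is the
   candidate united with edge responses within a 3 px halo of it.
4. 3×3 morphological closing of the dendrite mask, then elementwise
   subtraction of the osteocyte mask, so the final 3-class label
   {0 background, 1 osteocyte, 2 dendrite} has disjoint classes.

The osteocyte mask comes entirely from the shared stages, so the two
pipelines differ only in the dendrite class — their osteocyte scores are
identical by construction. Intensity thresholds are 8-bit; 16-bit input
is max-normalised down first. The pipeline is deterministic; it is *not*
intensity-shift covariant (the fixed thresholds see to that), which is a
property of the method, not a defect.

The Canny hysteresis thresholds are interpreted on the Sobel
gradient-magnitude scale of 8-bit images (the convention of the classical
implementations); the NMS/hysteresis chain is assembled from scipy/skimage
building blocks because library Canny variants put their thresholds on a
derivative-of-Gaussian scale that is not comparable.

## Segmentation metrics

DSC = 2|P∩G|/(|P|+|G|), IoU = |P∩G|/|P∪G|. Multi-class labels are scored
one-vs-rest per class; mIoU averages osteocyte and dendrite (background
excluded by default, `--include-background` to change). The single
reported DSC is the foreground-union Dice (all non-background pixels
pooled); a class-averaged variant (`dice_macro`) is also computed.
Empty-vs-empty comparisons score 1.0 — predicting the absence of an
absent class is correct — and this convention is pinned by tests.

## Connectomics

The label is split into binary masks; osteocytes are dilated with a 4×4
ellipsoid (corners off) and dendrites with a 2×2 square, both anchored at
the top-left pixel of the central 2×2 core (even kernels have no centre;
the anchor is pinned by tests and printed in the module docstring). A 2×2
"cross" is geometrically degenerate — no placement of it both contains
its origin and bridges a 1-px diagonal gap — so the full square, which
does both, stands in for it. Dilation merges nearby fragments; 8-connected
component labelling then defines nodes (osteocyte components) and
dendrite segments. Each dendrite segment is classified by the set of
osteocyte components it overlaps: two → an edge; one → a dead end
(blunted canaliculus); zero → isolated fragment; three or more → one edge
per overlapped pair (clique rule), since a single merged segment
evidences pairwise contact among all of them.

Geometry is measured on the original, undilated dendrite pixels. Length:
topology-preserving skeletonisation to 1 px, then path length with
orthogonal steps 1, diagonal steps √2, plus one pixel of endpoint span.
Thickness: pixel area / skeleton length (default), or twice the mean
maximal-ball radius along the skeleton (`method="edt"`); the area
estimator is the default because at 1–3 px calibres the distance
transform quantises harshly. Single-pixel components default to one pixel
of thickness.

Per-image metrics: node count, dead ends per node, connections per node
(2|E|/|V|), mean connection length and diameter (µm), mean network
diameter (total dendrite area over total skeleton length), mean shortest
path in hops over connected node pairs, and mean dendrite length over
*all* dendrite components (connections, dead ends, isolated). The last
metric is the readout in which canalicular truncation shows even when a
degraded network retains few complete connections. Metrics without
support (e.g. mean connection length with no edges) are NaN and are
dropped per-metric by the group comparison. Dead-end counting has a
second mode (`dead_end_mode="skeleton_endpoint"`) that counts blunted
skeleton termini instead of whole components — the reading under which
per-node dead-end counts reach the tens in dense fields; the
component-based mode is the default.

## Training machinery

The training module supports any per-pixel classifier exposing
`forward(images) → logits`, `backward(grad_logits) → parameter gradients`
and a `params` dict. The shipped `TinyConvNet` (two 3×3 convolution
layers with a ReLU, pure numpy with analytic gradients) is a desk-scale
test backbone, not a production segmenter.

* Red-channel grayscale conversion (the confocal signal is in red).
* Augmentation: seeded flips, 90° rotations, optional crop, applied to
  image and label in lockstep with nearest-neighbour (integer) labels.
* Dendrite-label dilation (2×2 or 3×3) to compensate under-annotation of
  thin structures; dilated pixels never overwrite osteocyte labels.
* Masked DiceCE loss: soft Dice plus cross entropy (weights 1.0/1.0 by
  default), computed exclusively over annotated pixels; its gradient with
  respect to the predictions is exactly zero outside the annotation mask
  (verified against finite differences), which is what makes partial
  labels usable. An empty mask yields a defined-zero loss with a warning.
* Fragmentation penalty: softmax → argmax → 8-connected components of the
  dendrite prediction per batch item; each component of size s adds
  s^(−penalty_factor); the sum is scaled by a weight. Larger, fewer
  components ⇒ smaller penalty. The argmax makes the term
  non-differentiable, so it enters training as a monitored auxiliary term
  computed exactly as defined on hard predictions; a straight-through or
  soft-probability variant is a possible extension. Defaults
  penalty_factor 1.0, weight 0.01 — conservative, since the term's
  observed effect on accuracy is marginal.
* Optimiser: AdamW (lr 1e-3, weight decay 1e-4), cosine-annealing
  schedule with period 10 % of total steps and floor 5e-6, global
  gradient-norm clipping (1.0), per-image min-max normalisation to [0,1].
  Fine-tuning modes: freeze all but input+head, freeze all but head, or
  reduced (×0.1) backbone learning rate.
* Separate per-class models merge with osteocyte precedence on conflicts.

## Group statistics

Per-image connectomics reports are the statistical unit. Groups are
compared metric-by-metric with a two-sided two-sample Student's t-test
(pooled variance; Welch's behind a flag) at α = 1e-4, reported as
mean ± SD per group. Zero variance in both groups with equal means is
defined as p = 1. No multiple-testing correction is applied.

## Problem sizes and reproducibility

Tests and the acceptance script run on one CPU in minutes: 50 noise-free
scenes for planted-graph recovery, 20 for segmentation quality, 16
training scenes of 64×64 px for 30 epochs, 30 scenes per group for the
phenotype comparison, and a 240-scene pool with 200 disjoint random
12-vs-12 splits for the null calibration (a permutation-style null: one
configuration, resampled group assignments). All randomness flows from
explicit seeds.

## Known limitations

* The aged-vs-young dead-end contrast is the weakest of the four
  phenotype readouts at 30 scenes per group (t ≈ 4–5; p typically
  1e-7–1e-4 across seed draws), because fragments of broken connections
  register as spurious dead ends and dilute the planted difference. The
  paper-scale design of ~100 scans per group puts it far below any
  threshold; at desk scale it can hover near α.
* Canny responds on ridge flanks, so its dendrite mask leans on the
  candidate mask; its added recall comes with flank-shaped false
  positives.
* Thickness estimates at 1.5 px calibre carry ±0.5 px rasterisation
  error; differences smaller than that are not resolvable at this
  resolution, matching the known insensitivity of thickness readouts in
  this imaging regime.
* The skeleton length estimator over-counts by up to one diagonal step at
  T-junctions; planted-arc-length recovery error is ~5 % on average.
* 3D z-stacks are out of scope; all analysis is per-2D-scan.
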
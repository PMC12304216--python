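# Methods

This note documents the models, algorithms and design choices behind
`angiorecon`: a two-phase reconstruction pipeline for 3D MR vessel-wall
imaging (MR-VWI) of the head and neck, together with the synthetic
phantom machinery used to validate it.

## Problem setting

3D MR-VWI examines the cranio-cervical arteries with complementary
sequences: bright-blood TOF-MRA shows flowing blood as high signal and
delineates the patent lumen, while black-blood T1WI (and its
contrast-enhanced variant T1WI-CE) suppresses the lumen so the vessel
wall, plaque and thrombus become visible. A fully occluded segment
disappears from TOF but usually remains traceable on black-blood
images. Reconstruction means: segment and recognise the eight large
arteries (CCA, ICA, ECA, ACA, MCA, VA, BA, PCA), extract a complete
labelled centerline per artery — across occlusions — and render
straightened curved planar reformations (CPR) along those centerlines.

## Phase I — segmentation and recognition

### Network

Both segmentation models share one encoder–decoder architecture,
implemented in numpy with hand-written forward/backward passes (each
layer's gradient is validated against finite differences in the test
suite):

* an input unit: a 3×3×3 convolution that merges the input channels
  (two for the black-blood model, one for the bright-blood model);
* four down-sampling units: stride-2 3×3×3 convolution followed by a
  bottleneck residual block (1×1×1 reduce → 3×3×3 → 1×1×1 expand, plus
  the identity path), instance normalisation after every convolution;
* four up-sampling units: 2×2×2 transposed convolution, concatenation
  with the same-scale encoder output, 1×1×1 merge convolution and
  another bottleneck residual block;
* a 1×1×1 convolution head emitting per-voxel class scores; recognition
  is the per-voxel multi-class label itself.

Channel widths grow as `base_width · 2^scale`, capped at 8×
`base_width`. Down-sampling uses strided convolution and up-sampling
transposed convolution; skip merges concatenate rather than add. These
three choices (and reading the bottleneck block as the classic
reduce/process/expand residual) were genuinely open design points.

### Channel preparation and sequence fallback

The black-blood model consumes channel 1 = T1WI and channel 2 = T1WI-CE,
both z-score normalised; the spatial frame is always channel 1's, and a
second sequence on a different grid is resampled onto it (world-aligned
trilinear). When only one black-blood sequence exists it is duplicated
into both channels, which makes the single-sequence path bit-identical
to the dual path fed two copies. TOF alone activates the bright-blood
single-channel model. No usable sequence is an error. Z-scoring is
computed over the whole volume by default; a body-mask threshold
(fraction of the intensity range) is available for data with an air
background, which the phantoms do not have.

### Training

Soft-Dice loss, averaged over non-empty foreground classes with an
epsilon-guarded denominator, supervises training. The optimiser is Adam
with momentum 0.9, initial learning rate 1e-3, exponential decay and
weight decay 1e-5 (defaults); the decay rate per epoch defaults
to 0.97. Training is full-volume, single-sample, seeded; the state with
the best validation loss is returned. A NaN loss aborts with the
offending sample named.

The scaled-down reference runs in `evaluation.py` depart from the
defaults deliberately: with tens of epochs instead of thousands, a
slightly higher rate (3e-3) and a slower decay (0.99–0.995) reach
convergence inside a single-CPU budget. Two experiments are pinned: a
2-sample overfit at 32³ (100 epochs, base width 8) that must reach
foreground Dice ≥ 0.99, and a 20-train/5-validation run at 64³
(16 epochs, base width 4, binary vessel/background) whose held-out
foreground Dice reaches ≈ 0.99 at the pinned seed. Problem sizes were
chosen so each run completes in minutes on one CPU.

### Fusion

The black-blood and bright-blood outputs, in the same frame, are fused
voxelwise: the label is the argmax over the per-class maximum of the
two probability maps, except where exactly one model sees foreground
and the other background — there the foreground model's label wins
outright. That rule preserves occluded segments (visible only to the
black-blood model) and is symmetric, hence commutative. Mismatched
frames are an error, never silently resampled.

## Phase II — centerline geometry

### Skeletonization and principal centerlines

Per label, the mask is thinned with a topology-preserving 3D
skeletonization and turned into a 26-connected voxel graph. Redundant
triangle edges that 26-connectivity creates around junctions are
dropped (longest edge first) so a Y-junction collapses to a single
degree-3 node. Leaf branches shorter than `prune_len` (default 3 mm,
a choice — roughly one vessel radius) ending at a junction are pruned.
Cycles — rare, from touching vessel loops — are broken at the node with
the minimal distance-field value, with a warning. The remaining graph
decomposes into maximal endpoint-to-junction paths; each becomes a
centerline, ordered inferior → superior (by endpoint z), with the side
(left/right/midline) assigned from the mean mid-sagittal offset
(+x = left, half-voxel dead zone = midline). Because thinning retracts
tube tips by about one radius, terminal segments are extended greedily
through the mask along the local heading.

### Distance-field path tracing

The Euclidean distance-to-background field of the mask (in mm) drives
minimal-path tracing: stepping into voxel `v` costs
`step_length / (field(v) + ε)` with ε = 0.1 mm, so paths prefer
lumen-central voxels, and crossing non-mask voxels is expensive but
possible — exactly what bridging an occlusion gap requires. Paths are
computed by Dijkstra's algorithm over the 26-connected grid
(scipy.sparse.csgraph); the cost of the returned path equals an
exhaustive brute-force Dijkstra oracle's cost exactly on all tested
grids. An unreachable or over-budget target yields an explicit
"untraceable" result. The reciprocal-distance cost is a standard choice
for vesselness-guided minimal paths; it is the one configurable
decision in this stage.

### Connection and extension

Centerline fragments are assembled into complete vessels using a
shipped, editable anatomical adjacency table (CCA→ICA/ECA, ICA→MCA/ACA,
VA→BA, BA→PCA). Same-label, same-side fragments whose endpoints are
within `max_bridge` (default 10 mm) are joined by a traced path — this
is how occlusion gaps are crossed — and the bridged index span is
recorded on the line. Fragments further apart stay separate and are
flagged incomplete. A child vessel whose nearest parent endpoint is
within `max_bridge` is attached to the junction the same way. Finally,
free ends are extended while the distance field stays above 0.6 × the
minimal voxel spacing.

### Lumen-based refinement

Each centerline point is re-centred to the centroid of its lumen
cross-section: the plane normal to the local tangent (from the
rotation-minimizing frame) is sampled on a disk (default radius 6 mm,
step half a voxel) and the point moves to the mean of the in-lumen
samples, followed by light moving-average smoothing. Bridged spans have
no lumen to centre on and are left untouched; a line more than half
outside the lumen refuses refinement with a warning.

## CPR

Straightened CPR resamples the volume on planes orthogonal to the
centerline: the line is resampled at a uniform arc-length step, frames
are transported by the double-reflection rotation-minimizing method
(well-defined on straight segments, no flips — a Frenet frame is
neither), and each output row holds trilinear samples along the
in-plane direction at the requested viewing angle within ±half-width.
Out-of-volume samples take the volume minimum (configurable) and are
flagged. Rows therefore follow arc length and the 0°/180° images are
exact mirror images up to interpolation error.

## Deviation rubric

Reconstruction quality is mechanised as the fraction of a centerline's
arc length lying outside the target label's lumen (sampled uniformly in
arc length, nearest-voxel membership). The 4-point score follows the
printed thresholds: 1 = recognised and fully inside; 2 = deviation
≤ 25 %; 3 = ≤ 50 %; 4 = worse, or a segmentation/recognition failure.
Whether "deviates by 25 %" means arc-length fraction or lateral
distance was ambiguous; the arc-length-outside-lumen fraction is used
and documented. The human artefact/clarity judgements of the original
scale are explicitly out of scope.

## Evaluation metrics

* Dice: `2|X ∩ X̄| / (|X| + |X̄|)`; both-empty is defined as 1.0.
* Centerline accuracy: the arc length of the extracted line lying
  within `tol` (default 1 mm, a parameter — "accurately extracted" is
  otherwise undefined) of the truth polyline, divided by the truth arc
  length, capped at 1.
* MCD: half the sum of the two directed mean nearest-neighbour
  distances between the point sets. Polylines are arc-length resampled
  (default 0.5 mm) first, otherwise the value depends on annotation
  point density; the step is a parameter.
* Hausdorff distance is provided as an optional extra.

## Synthetic phantoms

A phantom is a list of tubular branches: a cubic curve through ≥ 2
control points, arc-length resampled at a quarter voxel, swept with a
per-control-point radius and flat end caps. Branch labels are the eight
arteries; overlapping branches of different labels are rejected so the
ground truth stays unambiguous. Intensities follow the clinical
contrast pattern — TOF: bright lumen (240) on dark background (30);
black-blood: dark lumen (40) on mid-grey tissue (120) — with additive
Gaussian noise (σ = 5 by default) per sequence. An occluded span drops
to background on TOF but takes a bright thrombus/enhancement-like value
(200 / 220) on T1WI / T1WI-CE, so the path remains traceable there.
Everything is deterministic in (spec, seed).

What the phantoms deliberately do not model: MR physics (bias fields,
coil profiles, flow artifacts), inter-sequence misregistration,
pathology beyond occlusion, and small distal intracranial branches.
Passing tests therefore demonstrate the correctness of the geometry and
learning machinery under clean tubular anatomy, not clinical-grade
segmentation accuracy on patient data.

The augmentation suite mirrors the training-set expansion for the
segmentation model: displacement (integer-voxel translation with
background padding), truncation (field-of-view crop that must retain
vessel, re-drawn with a warning otherwise), left-right reversal (an
exact involution that swaps side labels), and simulated occlusion
(TOF lumen signal suppressed over a random arc span, black-blood and
ground truth untouched). The default configuration emits six samples
per input — the original, one of each operation, and one composed
displacement∘flip; the composition makes up the stated six-fold count
and is recorded in the config.

## Numerical conventions

World coordinates are `voxel index × spacing` (axis-aligned, 0-based
voxel centres, mm); x crosses the mid-sagittal plane, z runs inferior →
superior. Skeletons, tracing and extension use 26-connectivity.
Shortest-path determinism comes from a fixed graph construction order.
All interpolation is trilinear unless stated; CPR padding defaults to
the volume minimum. Degenerate inputs (single-point lines, empty
labels, empty point sets) either return the documented neutral value or
raise a typed error, as listed in each docstring.

## Known limitations

* The numpy network trains full volumes without batching; it is meant
  for desk-scale experiments and correctness arguments, not
  production-scale training.
* Junction-attach bridges cross the unlabelled gap between a parent and
  a child branch, so a few millimetres of bridge necessarily lie
  outside any single label's lumen (unlike occlusion bridges, which
  stay inside the dilated true lumen).
* Side assignment is geometric (mid-sagittal mean); strongly tortuous
  midline-crossing vessels could be mis-sided.
* DICOM reading covers plain single-frame series with uniform slice
  spacing; vendor-specific private tags and multi-frame objects are out
  of scope.
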
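# Methods

## Heat-flow encoding

Each cell in a labeled mask is encoded independently on its own 4-connected
support Ω; heat never crosses background, so the encoding of a multi-object
mask restricted to one object's support equals the encoding of that object
alone (tested as the per-object locality property).

**Source pixel.** The geometric centroid of Ω, rounded with halves toward the
smaller index; if the rounded centroid falls outside Ω (nonconvex cells), the
in-support pixel nearest to the float centroid is used, ties resolved in
row-major order. Rounding halves downward makes the even-sided-square case
deterministic (the row-major-first of the four central pixels).

**Diffusion.** Per iteration, every pixel of Ω is replaced by the mean of
itself and its in-support 4-neighbors (out-of-support neighbors are excluded
from the mean — a no-flux boundary), and then one unit of heat is deposited
at the source. Depositing after smoothing keeps the source the strict maximum
of the heat map at every iteration, so the normalized gradient field always
points toward it; depositing before smoothing would let a 1×3 bar's endpoints
transiently exceed the source. The iteration count is `ceil(2 × bounding-box
diagonal)` per object (configurable via `n_iter_scale` or a fixed `n_iter`):
twice the diameter bounds the graph distance from the source to any support
pixel, guaranteeing strictly positive heat everywhere and a stationary
gradient direction field.

**Gradients.** Central differences inside Ω, one-sided where a neighbor is
missing, then per-pixel normalization to unit length. Unit vectors make the
tracking step-size-controlled and match the [−1, 1] discretization range. The
source pixel (a local maximum) may have a zero gradient; every other in-object
pixel is exactly unit-norm after normalization. Axis convention: `grad_y` is
the derivative along rows (down positive), `grad_x` along columns (right
positive), 0-based pixel-center coordinates.

**Degenerate objects.** 1–2 px objects get zero gradients at their source;
decoding recovers them only if `min_object_area` permits.

## Decoding (gradient tracking)

Pixels with probability ≥ `prob_threshold` (default 0.5) are advected
`n_steps` = 200 Euler steps of `step_size` = 1 px along the bilinearly
interpolated gradient field, positions clamped to the image rectangle. 200
unit steps exceed any plausible in-crop object radius at 256×256. Final
positions are rounded to integer bins (half away from zero); occupied bins
within Chebyshev distance `cluster_radius` = 2 px are merged by single
linkage (union-find over shift offsets — exact, not an approximation by
morphological dilation); each tracked pixel adopts its bin's cluster.
Clusters with fewer than `min_object_area` = 9 member pixels are erased —
this suppresses quantization speckle in GAN-produced flows. Output labels are
renumbered 1..K by row-major order of each cluster's first member pixel, so
the result is independent of internal iteration order.

Trajectories near a source oscillate within ~1 px of it (unit steps over a
unit-norm field), which the 2 px merge radius absorbs.

## Discretization

Probability maps v ↦ round(255 v); gradients v ↦ round(255 (v+1)/2), halves
rounded away from zero (so 0.0 → 128), clipped to [0, 255]. The inverse maps
are exact on every byte value; continuous values round-trip within 1/255 (one
half quantization level each way). Ground-truth probability channels contain
only {0, 255}. On-disk channel order is (probability, grad_y, grad_x).

## Population simulator

The baseline mask generator follows the classical two-step parametric
design. Shapes: `n_vertices` (default 12) points of a regular polygon with
radius r ~ U(radius_min, radius_max), each vertex displaced by iid
N(0, perturb_sigma²) per coordinate (default σ = 1.5 px), joined by a
periodic cubic spline sampled at `spline_samples` points and rasterized by
even-odd fill over pixel centers. Self-intersecting outlines are resampled.
Even-odd fill of a smooth outline can shed isolated diagonal-touching debris
pixels; since a cell is one connected region, only the largest 4-connected
component is kept (likewise after border clipping, which can split nonconvex
outlines). Placement: object count n ~ Poisson(mean_cells) — a one-parameter
count law chosen because only a mean is specified; `n_clusters` cluster
centers uniform over the image; each object joins a cluster uniformly at
random and lands at the center plus an isotropic 2-D N(0, cluster_sigma² I)
displacement. Under `overlap_policy="reject"`, a placement whose 1-px
dilation touches existing foreground is resampled (up to
`max_placement_attempts`, then dropped); the 1-px margin guarantees distinct
ids are never 8-connected, which keeps simulated masks unambiguous as
connected-component ground truth. Under `"allow"`, later objects overwrite
earlier ones and objects reduced below `min_area` (default 9 px) are removed.
Partial cells at image borders are kept if ≥ `min_area` pixels survive,
matching real crops that cut cells at tile edges.

Vertex count and perturbation variance defaults are this package's own
choices of a realistic regime, not claims of equivalence with any particular
legacy implementation.

`simulate_dataset` spawns one child seed per mask from the top-level seed, so
datasets are byte-reproducible and each mask equals a direct
`place_population` call with its child generator.

### What the simulator does and does not emulate

It reproduces clustered layouts, touching-adjacent cells (under `allow`),
border-clipped cells, and realistic size dispersion. It does not produce the
tissue-specific global structures (ducts, epithelial sheets) that motivate
GAN-based mask synthesis, nor textured microscopy intensities — simulated
"images" in tests are synthetic rasters. Passing round-trip and metric tests
on simulated masks therefore validates the codec and metrics machinery, not
any claim about real-tissue mask realism.

`perturb_flow` stands in for GAN output imperfections: iid Gaussian noise on
the gradient channels (renormalized to unit length inside objects) plus
Bernoulli flips of the probability channel. It produces angular error rather
than the spatially correlated artifacts a real generator makes; the
robustness tests (count preservation at σ = 0.05 on well-separated discs)
are a desk-scale surrogate, not a GAN evaluation.

## Crop extraction

A `crop_size` window (default 256) slides at `stride` (default crop_size/2)
over each image/mask pair; final windows are anchored to the far edge so
coverage is complete, with duplicate offsets removed. An object counts toward
the `min_objects` filter (default 3) if at least `min_area` = 9 px of it lies
inside the window — partial-object handling is otherwise unspecified, and a
9 px sliver is below any meaningful instance. Kept crops contribute their
90°/180°/270° rotations (image and mask jointly; mask crops re-canonicalized
after rotation). Export writes flow images, image crops, and raw mask crops
to parallel zero-padded directories with a TSV manifest.

## Augmentation protocol

Photometric: out = clip(c·image + b + η, 0, 1) with c ~ U(0.6, 2.0),
b ~ U(−0.2, 0.2), η iid N(0, 0.02²); applied to the input image only. The
bias upper bound is set to 0.2 on the reading that images live in [0, 1] (a
+2 bias would saturate every pixel); the larger bound remains reachable
through `AugmentConfig`. Clipping keeps outputs valid intensities. Geometric:
per-axis flips each with probability 0.5, plus (with the same probability) a
uniformly chosen multiple of 90° — arbitrary-angle rotations are excluded
because they are not label-exact on a pixel grid. Elastic: a per-component
iid U(−1, 1) field smoothed by a Gaussian of std `elastic_sigma` = 8 px and
scaled by `elastic_alpha` = 10 px, image warped bilinearly and mask by
nearest neighbor with the identical field. Elastic deformation is meant for
raw-mask targets; for flow-field targets it is skipped, since the flow of a
deformed mask would have to be re-encoded from scratch each step.

## Metrics

Matching uses the fact that at IoU ≥ 0.5 two distinct pairs cannot share an
object (each partner would need more than half the other's union), so the
maximum matching is exactly the set of pairs at or above threshold — ties
count as matches (≥, not >). Thresholds below 0.5 are rejected as outside
the metric's domain. Empty-prediction/empty-truth images score 1.0 (no
objects, no errors); empty-vs-nonempty scores 0 through FN or FP. Dataset
aggregation pools TP/FP/FN over images per threshold before forming the
accuracy; per-image means are also reported since the convention is not
universal.

The Fréchet distance is computed from Gaussian summaries via
d² = ‖Δμ‖² + tr(Σₐ + Σᵦ − 2(Σₐ^½ Σᵦ Σₐ^½)^½), with both square roots by
symmetric eigendecomposition; eigenvalues above −10⁻⁸ (relative) are clamped
to zero, anything more negative raises. The default feature extractor is
per-channel means over an 8×8 block partition in natural units (probability
[0, 1], gradients [−1, 1]), giving 192 deterministic dimensions with no
external weights; an ImageNet-pretrained extractor can be plugged into
`flow_features` to reproduce the conventional fID configuration, but is
deliberately not bundled or tested. Absolute distances from the block
extractor are not comparable to published inception-feature values.

## Problem sizes

The verification suite uses 100 simulated 256² masks (~12 cells each) for
round-trip fidelity, 50 constructed touching-disc masks, 20 noise draws for
robustness, 500 seeds for the Poisson-rate check, and 40–60 masks per side
for Fréchet comparisons — sizes at which every distributional test has
comfortable power on one CPU.

## Known limitations

- The decoder's convergence clustering assumes sources separated by more
  than `cluster_radius` after tracking; two cells whose sources fall within
  2 px of each other (physically overlapping) merge.
- Euler tracking with bilinear interpolation can stall on plateaus created
  by heavy probability-channel corruption; `min_object_area` removes the
  resulting fragments but cannot recover the object.
- The simulator's uniform cluster centers may place clusters at the border,
  truncating their populations; this is intentional (real tiles cut tissue)
  but makes per-cluster counts at borders non-Poisson.
- `heat_diffuse` is dense per object bounding box; pathological masks (one
  object spanning a huge image) cost O(n_iter · bbox area).
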
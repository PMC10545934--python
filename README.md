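# maskflow

Structure-preserving augmentation tooling for single-cell instance
segmentation. Dense tissue images (tumor sections, epithelial layers) contain
touching cells whose labeled masks are discrete-valued and therefore hard for
generative models to learn directly: binary masks fuse touching instances, and
raw label images carry arbitrary intensities that a generator cannot
reproduce coherently. `maskflow` implements the desk-scale computational core
of a pipeline that fixes this by encoding instance masks into a continuous
heat-flow representation, training a GAN on those encodings (the GAN itself is
an external tool), and decoding generated flows back into labeled masks.

It is aimed at microscopy image-analysis researchers who need to (a) convert
labeled masks to and from the flow representation, (b) simulate parametric
cell populations as a classical baseline, (c) assemble GAN-ready crop
datasets from annotated images, (d) apply a standard augmentation protocol,
and (e) score instance segmentations and compare mask datasets in flow space.

## The representation

For a labeled mask `m` (0 = background, positive integer = cell id), each
cell is encoded independently on its own support Ω:

- a source pixel is placed at the cell's centroid (projected into Ω if the
  centroid falls outside);
- heat is diffused iteratively: each iteration averages every pixel of Ω with
  its in-support 4-neighbors (no-flux boundary), then deposits one unit of
  heat at the source;
- the gradient ∇h of the final heat map, normalized to unit vectors, gives
  two channels (∂h/∂y, ∂h/∂x); a foreground indicator gives the third.

The triple (p, ∂h/∂y, ∂h/∂x) is continuous and dense, so a convolutional
generator can learn it; it is discretized to a 3-channel 8-bit image
(probability to {0, 255}; gradients affinely from [−1, 1] to [0, 255]) for
training. Decoding advects every pixel with p ≥ 0.5 along the interpolated
gradient field (200 Euler steps of 1 px by default); trajectories converge to
their cell's source, so pixels are grouped by convergence point — touching
cells separate cleanly because their gradients point to different fixed
points.

Scoring uses the standard instance metric: predictions and ground truth are
matched one-to-one at IoU thresholds 0.50, 0.55, …, 0.90 and the mean of
TP/(TP+FP+FN) over thresholds is reported. Dataset-level mask quality is the
Fréchet distance d²(𝒩(μ₁,Σ₁), 𝒩(μ₂,Σ₂)) = ‖μ₁−μ₂‖² + tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½)
between Gaussians fitted to feature embeddings of the two flow-image sets.

## Worked example

```python
import numpy as np
from maskflow import encode_mask, decode_flow, dsb_score, match_objects

# two touching discs — the failure mode of binary-mask encodings
yy, xx = np.mgrid[0:64, 0:64]
mask = np.zeros((64, 64), dtype=np.int32)
mask[(yy - 32) ** 2 + (xx - 21) ** 2 <= 100] = 1
mask[((yy - 32) ** 2 + (xx - 41) ** 2 <= 100) & (mask == 0)] = 2

flow = encode_mask(mask)            # prob + unit-gradient channels
decoded = decode_flow(flow)         # gradient tracking + convergence clustering

print("objects decoded:", decoded.max())
print("score:", dsb_score(decoded, mask))
print("matches:", match_objects(decoded, mask, 0.5)[3])
```

Output:

```
objects decoded: 2
score: 1.0
matches: [(1, 1, 1.0), (2, 2, 1.0)]
```

Both touching discs are recovered as separate instances with IoU 1.0, so the
threshold-averaged accuracy is 1.0. A binary encoding of the same mask is a
single 40×20 blob and cannot be split.

The simulator provides a parametric baseline population (perturbed-polygon
cells with spline outlines, clustered uniformly-placed centers):

```python
from maskflow import PopulationConfig, simulate_dataset
masks = simulate_dataset(PopulationConfig(mean_cells=12, seed=0), K=5)
```

The command-line interface exposes the same steps as subcommands:
`maskflow encode`, `decode`, `simulate`, `crops`, `augment`, `score`, `fid`,
and `pipeline` (see `maskflow --help`).

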
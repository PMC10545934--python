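"""Heat-flow encoding and decoding of labeled instance masks.

A labeled mask (2-D integer grid, 0 = background, positive id = instance) is
encoded into a dense, continuous 3-channel representation that a GAN can learn:
per object, a constant unit of heat is deposited at a source pixel and diffused
iteratively inside the object's support; the normalized gradient of the final
heat map fills two channels, and a foreground-probability map fills the third.
Decoding advects every foreground pixel along the gradient field; trajectories
that converge to the same fixed point belong to the same instance, which
separates touching objects that a binary mask cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FlowField",
    "FlowImage",
    "DecodeParams",
    "canonicalize_mask",
    "source_pixel",
    "heat_diffuse",
    "encode_mask",
    "decode_flow",
    "discretize_flow",
    "dediscretize_flow",
]

#: 4-connectivity structuring element used for all instance-labeling steps.
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class FlowField:
    """Continuous per-pixel (probability, gradient) triple.

    ``prob`` lies in [0, 1]; ``grad_y``/``grad_x`` lie in [-1, 1] and are unit
    vectors inside objects (zero at heat sources and outside objects).
    Axis convention: ``grad_y`` is the derivative along rows (down positive),
    ``grad_x`` along columns (right positive); 0-based pixel-center coordinates.
    """

    prob: np.ndarray
    grad_y: np.ndarray
    grad_x: np.ndarray

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=np.float64)
        self.grad_y = np.asarray(self.grad_y, dtype=np.float64)
        self.grad_x = np.asarray(self.grad_x, dtype=np.float64)
        if not (self.prob.shape == self.grad_y.shape == self.grad_x.shape):
            raise ValueError(
                "FlowField channels must share one shape, got "
                f"{self.prob.shape}, {self.grad_y.shape}, {self.grad_x.shape}"
            )
        if self.prob.ndim != 2:
            raise ValueError("FlowField channels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prob.shape


@dataclass
class FlowImage:
    """8-bit discretization of a :class:`FlowField` (the on-disk GAN format).

    Channel order follows the file-format contract: (probability, grad_y,
    grad_x). Probability maps [0, 1] onto [0, 255]; gradients map [-1, 1]
    affinely onto [0, 255].
    """

    prob: np.ndarray
    grad_y: np.ndarray
    grad_x: np.ndarray

    def __post_init__(self) -> None:
        for name in ("prob", "grad_y", "grad_x"):
            arr = np.asarray(getattr(self, name))
            if arr.dtype != np.uint8:
                raise ValueError(f"FlowImage.{name} must be uint8, got {arr.dtype}")
            setattr(self, name, arr)
        if not (self.prob.shape == self.grad_y.shape == self.grad_x.shape):
            raise ValueError("FlowImage channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prob.shape

    def to_array(self) -> np.ndarray:
        """Stack to an (H, W, 3) uint8 array in on-disk channel order."""
        return np.stack([self.prob, self.grad_y, self.grad_x], axis=-1)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FlowImage":
        arr = np.asarray(arr)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {arr.shape}")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2])


@dataclass
class DecodeParams:
    """Tunables of the gradient-tracking decoder.

    n_steps
        Euler steps per tracked pixel; 200 unit steps exceed any plausible
        in-crop object radius at 256x256.
    step_size
        Pixels advanced per step along the (unit-norm) interpolated gradient.
    prob_threshold
        Foreground cutoff on the probability channel.
    cluster_radius
        Chebyshev radius (pixels) for merging convergence bins.
    min_object_area
        Clusters with fewer member pixels are erased (suppresses quantization
        speckle in GAN-produced flows).
    """

    n_steps: int = 200
    step_size: float = 1.0
    prob_threshold: float = 0.5
    cluster_radius: int = 2
    min_object_area: int = 9

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.cluster_radius < 0:
            raise ValueError("cluster_radius must be >= 0")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (np.round rounds halves to even)."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def canonicalize_mask(mask: np.ndarray) -> np.ndarray:
    """Return the canonical form of a labeled mask.

    Ids whose pixels form several 4-connected components are split into
    distinct ids; surviving components are renumbered 1..K in row-major order
    of each component's first pixel. Idempotent.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.issubdtype(mask.dtype, np.bool_):
            mask = mask.astype(np.int32)
        else:
            raise ValueError(f"mask must be integer-valued, got dtype {mask.dtype}")
    if mask.size and mask.min() < 0:
        raise ValueError("mask ids must be non-negative")

    components: list[tuple[int, np.ndarray]] = []  # (first flat index, bool mask)
    for obj_id in np.unique(mask):
        if obj_id == 0:
            continue
        labeled, n = ndimage.label(mask == obj_id, structure=_CROSS)
        for comp in range(1, n + 1):
            member = labeled == comp
            first = int(np.flatnonzero(member.ravel())[0])
            components.append((first, member))
    components.sort(key=lambda item: item[0])

    out = np.zeros(mask.shape, dtype=np.int32)
    for new_id, (_, member) in enumerate(components, start=1):
        out[member] = new_id
    return out


def source_pixel(support: np.ndarray) -> tuple[int, int]:
    """Heat-source pixel of one object: the centroid, projected into support.

    Returns the integer centroid when it lies inside the support, otherwise
    the in-support pixel nearest (Euclidean) to the float centroid, ties
    broken in row-major order. Halves round toward the smaller index, so the
    center of an even-sided square resolves to the row-major-first of its four
    central pixels.
    """
    support = np.asarray(support, dtype=bool)
    rows, cols = np.nonzero(support)
    if rows.size == 0:
        raise ValueError("empty support has no source pixel")
    cy = rows.mean()
    cx = cols.mean()
    ir = int(np.ceil(cy - 0.5))
    ic = int(np.ceil(cx - 0.5))
    if 0 <= ir < support.shape[0] and 0 <= ic < support.shape[1] and support[ir, ic]:
        return ir, ic
    d2 = (rows - cy) ** 2 + (cols - cx) ** 2
    best = d2.min()
    # ties: smallest flat (row-major) index among the minimizers
    candidates = np.flatnonzero(d2 <= best + 1e-12)
    flat = rows[candidates] * support.shape[1] + cols[candidates]
    pick = candidates[np.argmin(flat)]
    return int(rows[pick]), int(cols[pick])


def heat_diffuse(support: np.ndarray, source: tuple[int, int], n_iter: int) -> np.ndarray:
    """Iterative in-support heat diffusion from a point source.

    Each iteration replaces every in-support pixel by the mean of itself and
    its in-support 4-neighbors (out-of-support neighbors are excluded from
    the mean — a no-flux boundary, so heat never leaks across the
    background), then deposits one unit of heat at ``source``. Depositing
    after smoothing keeps the source the strict maximum of the heat map at
    every iteration, so the gradient field always points toward it.
    """
    support = np.asarray(support, dtype=bool)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sr, sc = source
    if not (0 <= sr < support.shape[0] and 0 <= sc < support.shape[1] and support[sr, sc]):
        raise ValueError(f"source {source!r} lies outside the support")

    sup = np.pad(support, 1)
    # denominator: self + number of in-support 4-neighbors
    denom = (
        1.0
        + sup[:-2, 1:-1]
        + sup[2:, 1:-1]
        + sup[1:-1, :-2]
        + sup[1:-1, 2:]
    )
    heat = np.zeros(support.shape, dtype=np.float64)
    pad = np.zeros_like(sup, dtype=np.float64)
    for _ in range(n_iter):
        pad[1:-1, 1:-1] = heat
        total = (
            heat
            + pad[:-2, 1:-1]
            + pad[2:, 1:-1]
            + pad[1:-1, :-2]
            + pad[1:-1, 2:]
        )
        heat = np.where(support, total / denom, 0.0)
        heat[sr, sc] += 1.0
    return heat


def _masked_gradient(heat: np.ndarray, support: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences inside the support, one-sided at its boundary."""
    sup = np.pad(support, 1)
    h = np.pad(heat, 1)
    up, down = sup[:-2, 1:-1], sup[2:, 1:-1]
    left, right = sup[1:-1, :-2], sup[1:-1, 2:]
    h_up, h_down = h[:-2, 1:-1], h[2:, 1:-1]
    h_left, h_right = h[1:-1, :-2], h[1:-1, 2:]

    gy = np.where(
        up & down,
        (h_down - h_up) / 2.0,
        np.where(down, h_down - heat, np.where(up, heat - h_up, 0.0)),
    )
    gx = np.where(
        left & right,
        (h_right - h_left) / 2.0,
        np.where(right, h_right - heat, np.where(left, heat - h_left, 0.0)),
    )
    gy = np.where(support, gy, 0.0)
    gx = np.where(support, gx, 0.0)
    return gy, gx


def default_n_iter(support: np.ndarray) -> int:
    """Heat-iteration count: twice the bounding-box diagonal, rounded up.

    Guarantees heat reaches every pixel of the object and the gradient
    direction field is approximately stationary.
    """
    rows, cols = np.nonzero(support)
    h = rows.max() - rows.min() + 1
    w = cols.max() - cols.min() + 1
    return int(np.ceil(2.0 * float(np.hypot(h, w))))


def encode_mask(mask: np.ndarray, n_iter: int | None = None, n_iter_scale: float = 2.0) -> FlowField:
    """Encode a labeled mask into its heat-flow representation.

    Heat is diffused per object, strictly within the object's support, from a
    source pixel at the (projected) centroid; the final heat map's gradient is
    normalized to unit vectors. Probability is 1 on object pixels, 0 elsewhere.

    Parameters
    ----------
    mask
        2-D non-negative integer grid; canonicalized internally.
    n_iter
        Fixed per-object heat-iteration count; overrides the policy.
    n_iter_scale
        Iterations per pixel of object bounding-box diagonal (default 2).
    """
    mask = canonicalize_mask(mask)
    prob = (mask > 0).astype(np.float64)
    grad_y = np.zeros(mask.shape, dtype=np.float64)
    grad_x = np.zeros(mask.shape, dtype=np.float64)

    slices = ndimage.find_objects(mask)
    for obj_id, sl in enumerate(slices, start=1):
        if sl is None:
            warnings.warn(f"object id {obj_id} has empty support; skipped", stacklevel=2)
            continue
        support = mask[sl] == obj_id
        if not support.any():  # pragma: no cover - canonical masks never hit this
            raise ValueError(f"object id {obj_id}: no placeable source pixel")
        src = source_pixel(support)
        if n_iter is not None:
            iters = int(n_iter)
        else:
            rows_, cols_ = np.nonzero(support)
            h = rows_.max() - rows_.min() + 1
            w = cols_.max() - cols_.min() + 1
            iters = int(np.ceil(n_iter_scale * float(np.hypot(h, w))))
        heat = heat_diffuse(support, src, iters)
        gy, gx = _masked_gradient(heat, support)
        norm = np.hypot(gy, gx)
        nonzero = norm > 0
        gy = np.where(nonzero, gy / np.where(nonzero, norm, 1.0), 0.0)
        gx = np.where(nonzero, gx / np.where(nonzero, norm, 1.0), 0.0)
        grad_y[sl] = np.where(support, gy, grad_y[sl])
        grad_x[sl] = np.where(support, gx, grad_x[sl])

    return FlowField(prob=prob, grad_y=grad_y, grad_x=grad_x)


def _merge_bins(bins: np.ndarray, shape: tuple[int, int], radius: int) -> np.ndarray:
    """Single-linkage merge of occupied bins within a Chebyshev radius.

    Returns, per input bin row, a cluster index. Two bins belong to one
    cluster iff they are linked by a chain of bins pairwise within ``radius``
    (Chebyshev).
    """
    coords = np.unique(bins, axis=0)
    n = coords.shape[0]
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    index = np.full(shape, -1, dtype=np.int64)
    index[coords[:, 0], coords[:, 1]] = np.arange(n)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if (dy, dx) <= (0, 0):
                continue
            ny = coords[:, 0] + dy
            nx = coords[:, 1] + dx
            ok = (ny >= 0) & (ny < shape[0]) & (nx >= 0) & (nx < shape[1])
            ok[ok] &= index[ny[ok], nx[ok]] >= 0
            for i, j in zip(np.flatnonzero(ok), index[ny[ok], nx[ok]]):
                union(int(i), int(j))

    roots = np.array([find(i) for i in range(n)])
    per_bin_cluster = np.unique(roots, return_inverse=True)[1]
    return per_bin_cluster[index[bins[:, 0], bins[:, 1]]]


def decode_flow(flow: FlowField, params: DecodeParams | None = None) -> np.ndarray:
    """Reconstruct a labeled mask from a (possibly noisy) flow field.

    Every pixel at or above the probability threshold is advected along the
    bilinearly interpolated gradient field; final positions are binned to
    integer pixels and bins merged within a Chebyshev radius (single
    linkage). Pixels whose trajectories converge into one merged cluster
    share an output label; clusters below the minimum area are erased.
    Labels are renumbered 1..K in row-major order of first member pixel, so
    the output geometry is independent of internal iteration order.
    """
    if params is None:
        params = DecodeParams()
    for name, chan in (("prob", flow.prob), ("grad_y", flow.grad_y), ("grad_x", flow.grad_x)):
        if np.isnan(chan).any():
            raise ValueError(f"NaN in flow channel {name}")
    h, w = flow.shape
    out = np.zeros((h, w), dtype=np.int32)

    fg = flow.prob >= params.prob_threshold
    if not fg.any():
        return out
    rows, cols = np.nonzero(fg)
    pos = np.stack([rows, cols]).astype(np.float64)

    for _ in range(params.n_steps):
        vy = ndimage.map_coordinates(flow.grad_y, pos, order=1, mode="nearest")
        vx = ndimage.map_coordinates(flow.grad_x, pos, order=1, mode="nearest")
        pos[0] = np.clip(pos[0] + params.step_size * vy, 0.0, h - 1.0)
        pos[1] = np.clip(pos[1] + params.step_size * vx, 0.0, w - 1.0)

    bins = np.clip(_round_half_away(pos.T), 0, [h - 1, w - 1]).astype(np.int64)
    cluster = _merge_bins(bins, (h, w), params.cluster_radius)

    n_clusters = cluster.max() + 1
    sizes = np.bincount(cluster, minlength=n_clusters)
    flat = rows.astype(np.int64) * w + cols
    first_pixel = np.full(n_clusters, np.iinfo(np.int64).max)
    np.minimum.at(first_pixel, cluster, flat)

    keep = sizes >= params.min_object_area
    order = np.argsort(first_pixel[keep], kind="stable")
    relabel = np.zeros(n_clusters, dtype=np.int32)
    relabel[np.flatnonzero(keep)[order]] = np.arange(1, keep.sum() + 1)
    out[rows, cols] = relabel[cluster]
    return out


def discretize_flow(flow: FlowField, eps: float = 1e-6) -> FlowImage:
    """Discretize a flow field to the 3-channel 8-bit GAN interchange format.

    Probability maps by ``v -> round(255 v)``; gradients by
    ``v -> round(255 (v + 1) / 2)``, halves rounded away from zero, clipped to
    [0, 255]. Values outside the declared ranges beyond ``eps`` are an error.
    """
    if flow.prob.size:
        if flow.prob.min() < -eps or flow.prob.max() > 1.0 + eps:
            raise ValueError("probability channel outside [0, 1]")
        for name, chan in (("grad_y", flow.grad_y), ("grad_x", flow.grad_x)):
            if chan.min() < -1.0 - eps or chan.max() > 1.0 + eps:
                raise ValueError(f"{name} outside [-1, 1]")
    to_byte = lambda x: np.clip(_round_half_away(x), 0, 255).astype(np.uint8)
    return FlowImage(
        prob=to_byte(flow.prob * 255.0),
        grad_y=to_byte((flow.grad_y + 1.0) / 2.0 * 255.0),
        grad_x=to_byte((flow.grad_x + 1.0) / 2.0 * 255.0),
    )


def dediscretize_flow(img: FlowImage) -> FlowField:
    """Invert :func:`discretize_flow` (exact on every representable byte)."""
    return FlowField(
        prob=img.prob.astype(np.float64) / 255.0,
        grad_y=img.grad_y.astype(np.float64) / 255.0 * 2.0 - 1.0,
        grad_x=img.grad_x.astype(np.float64) / 255.0 * 2.0 - 1.0,
    )
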
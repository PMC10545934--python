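"""Parametric cell-population mask simulator and flow-perturbation fixtures.

Implements the classical two-step population simulator used as the baseline
for GAN-based mask synthesis: individual cell outlines are perturbed regular
polygons smoothed by a closed cubic spline, and cells are placed on an empty
canvas in clusters — each object joins a cluster with uniform probability,
in-cluster centroid displacements are normally distributed, and cluster
centers are uniform over the image. Also provides the noise model that stands
in for GAN output imperfections when exercising the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from matplotlib.path import Path
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .flow_codec import FlowField, canonicalize_mask

__all__ = [
    "ShapeConfig",
    "PopulationConfig",
    "sample_shape",
    "place_population",
    "simulate_dataset",
    "perturb_flow",
]


@dataclass
class ShapeConfig:
    """Parameters of a single simulated cell outline.

    A regular ``n_vertices``-gon of radius r ~ U(radius_min, radius_max) has
    iid Normal(0, perturb_sigma) displacements added to each vertex
    coordinate; a periodic cubic spline through the vertices gives the
    outline, rasterized by even-odd fill of ``spline_samples`` polygon points.
    """

    n_vertices: int = 12
    radius_min: float = 6.0
    radius_max: float = 14.0
    perturb_sigma: float = 1.5
    spline_samples: int = 120
    max_attempts: int = 25

    def __post_init__(self) -> None:
        if self.n_vertices < 3:
            raise ValueError("n_vertices must be >= 3")
        if not 0 < self.radius_min <= self.radius_max:
            raise ValueError("need 0 < radius_min <= radius_max")
        if self.perturb_sigma < 0:
            raise ValueError("perturb_sigma must be >= 0")
        if self.spline_samples < 3 * self.n_vertices:
            raise ValueError("spline_samples must be >= 3 * n_vertices")


@dataclass
class PopulationConfig:
    """Parameters of a simulated cell population mask."""

    image_height: int = 256
    image_width: int = 256
    mean_cells: float = 12.0
    n_clusters: int = 3
    cluster_sigma: float = 40.0
    shape: ShapeConfig = field(default_factory=ShapeConfig)
    overlap_policy: str = "reject"
    max_placement_attempts: int = 50
    min_area: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_cells < 0:
            raise ValueError("mean_cells must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_sigma < 0:
            raise ValueError("cluster_sigma must be >= 0")
        if self.overlap_policy not in ("reject", "allow"):
            raise ValueError("overlap_policy must be 'reject' or 'allow'")


def _closed_spline(vertices: np.ndarray, n_samples: int) -> np.ndarray:
    """Periodic cubic spline through (y, x) vertices, sampled densely."""
    closed = np.vstack([vertices, vertices[:1]])
    t = np.arange(closed.shape[0], dtype=np.float64)
    spline = CubicSpline(t, closed, bc_type="periodic")
    ts = np.linspace(0.0, t[-1], n_samples, endpoint=False)
    return spline(ts)


def _largest_component(raster: np.ndarray) -> np.ndarray:
    """Largest 4-connected component of a binary raster.

    Even-odd fill of a spline outline can shed diagonal-only debris pixels;
    a cell is one connected region, so only the dominant component is kept.
    """
    labeled, n = ndimage.label(raster, structure=ndimage.generate_binary_structure(2, 1))
    if n <= 1:
        return raster
    sizes = np.bincount(labeled.ravel())[1:]
    return labeled == (int(np.argmax(sizes)) + 1)


def _rasterize(outline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Even-odd fill of a closed polygon over pixel centers.

    Returns (raster, outline-in-raster-frame); the raster is cropped to the
    outline bounding box.
    """
    ymin = np.floor(outline[:, 0].min())
    xmin = np.floor(outline[:, 1].min())
    shifted = outline - [ymin, xmin]
    h = int(np.ceil(shifted[:, 0].max())) + 1
    w = int(np.ceil(shifted[:, 1].max())) + 1
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    inside = Path(shifted).contains_points(pts)
    return _largest_component(inside.reshape(h, w)), shifted


def sample_shape(cfg: ShapeConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one cell shape: (binary raster, outline in raster coordinates).

    Self-intersecting outlines (after perturbation) are resampled up to
    ``cfg.max_attempts`` times, then raise.
    """
    angles = 2.0 * np.pi * np.arange(cfg.n_vertices) / cfg.n_vertices
    unit = np.column_stack([np.sin(angles), np.cos(angles)])
    for _ in range(cfg.max_attempts):
        radius = rng.uniform(cfg.radius_min, cfg.radius_max)
        verts = radius * unit + rng.normal(0.0, cfg.perturb_sigma, size=unit.shape)
        outline = _closed_spline(verts, cfg.spline_samples)
        # outline is (y, x); shapely wants (x, y) but validity is symmetric
        if not shapely.Polygon(outline).is_valid:
            continue
        raster, shifted = _rasterize(outline)
        if raster.any():
            return raster, shifted
    raise ValueError("could not sample a simple (non-self-intersecting) outline")


def place_population(
    cfg: PopulationConfig,
    rng: np.random.Generator,
    return_info: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Simulate one labeled population mask.

    Object count is Poisson(mean_cells). Cluster centers are uniform over the
    image; each object picks a cluster uniformly and lands at the center plus
    an isotropic Normal(0, cluster_sigma^2 I) displacement. Under the
    ``reject`` overlap policy a placement whose 1-px dilation touches existing
    objects is resampled up to ``max_placement_attempts`` times, then dropped,
    so distinct ids are never 8-connected. Objects clipped at the border are
    kept if at least ``min_area`` pixels survive.

    With ``return_info=True`` also returns per-object bookkeeping (cluster
    assignments of placed objects, drop count) for distributional checks.
    """
    H, W = cfg.image_height, cfg.image_width
    if H < 2 * cfg.shape.radius_max or W < 2 * cfg.shape.radius_max:
        raise ValueError(
            f"image {H}x{W} smaller than 2 * radius_max = {2 * cfg.shape.radius_max:g} "
            "in at least one dimension"
        )
    n_objects = int(rng.poisson(cfg.mean_cells))
    centers = np.column_stack([rng.uniform(0, H, cfg.n_clusters), rng.uniform(0, W, cfg.n_clusters)])

    canvas = np.zeros((H, W), dtype=np.int32)
    clusters_used: list[int] = []
    n_dropped = 0
    next_id = 1
    for _ in range(n_objects):
        placed = False
        for _attempt in range(cfg.max_placement_attempts):
            k = int(rng.integers(cfg.n_clusters))
            cy, cx = centers[k] + rng.normal(0.0, cfg.cluster_sigma, size=2)
            raster, _ = sample_shape(cfg.shape, rng)
            h, w = raster.shape
            top = int(np.floor(cy - h / 2.0 + 0.5))
            left = int(np.floor(cx - w / 2.0 + 0.5))
            r0, r1 = max(top, 0), min(top + h, H)
            c0, c1 = max(left, 0), min(left + w, W)
            if r0 >= r1 or c0 >= c1:
                continue
            patch = raster[r0 - top : r1 - top, c0 - left : c1 - left]
            if patch.any():
                # border clipping can split a nonconvex outline; keep one cell
                patch = _largest_component(patch)
            if patch.sum() < cfg.min_area:
                continue
            if cfg.overlap_policy == "reject":
                grown = ndimage.binary_dilation(patch, structure=np.ones((3, 3)))
                if (canvas[r0:r1, c0:c1][grown] > 0).any():
                    continue
            canvas[r0:r1, c0:c1][patch] = next_id
            if cfg.overlap_policy == "allow":
                # occlusion may shrink earlier objects below min_area; pruned below
                pass
            next_id += 1
            clusters_used.append(k)
            placed = True
            break
        if not placed:
            n_dropped += 1

    if cfg.overlap_policy == "allow":
        ids, counts = np.unique(canvas[canvas > 0], return_counts=True)
        for obj_id, area in zip(ids, counts):
            if area < cfg.min_area:
                canvas[canvas == obj_id] = 0
    mask = canonicalize_mask(canvas)
    if return_info:
        return mask, {
            "n_sampled": n_objects,
            "n_dropped": n_dropped,
            "clusters": np.asarray(clusters_used, dtype=int),
            "cluster_centers": centers,
        }
    return mask


def simulate_dataset(cfg: PopulationConfig, K: int) -> list[np.ndarray]:
    """Generate K independent masks, reproducible from ``cfg.seed``.

    Each mask uses its own child seed spawned from the top-level seed, so
    mask j is identical to a direct :func:`place_population` call with the
    j-th child generator.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    children = np.random.SeedSequence(cfg.seed).spawn(K)
    return [place_population(cfg, np.random.default_rng(child)) for child in children]


def perturb_flow(
    flow: FlowField,
    grad_sigma: float,
    prob_flip: float,
    rng: np.random.Generator,
) -> FlowField:
    """Corrupt a flow field the way an imperfect GAN would.

    Adds iid Normal(0, grad_sigma) to both gradient channels, renormalizes
    in-object vectors to unit length, and flips each probability pixel with
    probability ``prob_flip``.
    """
    if grad_sigma < 0:
        raise ValueError("grad_sigma must be >= 0")
    if not 0.0 <= prob_flip <= 1.0:
        raise ValueError("prob_flip must lie in [0, 1]")
    inside = flow.prob >= 0.5
    if grad_sigma > 0:
        gy = flow.grad_y + rng.normal(0.0, grad_sigma, size=flow.shape)
        gx = flow.grad_x + rng.normal(0.0, grad_sigma, size=flow.shape)
        norm = np.hypot(gy, gx)
        renorm = inside & (norm > 0)
        gy = np.where(renorm, gy / np.where(renorm, norm, 1.0), np.where(inside, gy, 0.0))
        gx = np.where(renorm, gx / np.where(renorm, norm, 1.0), np.where(inside, gx, 0.0))
    else:
        gy = flow.grad_y.copy()
        gx = flow.grad_x.copy()
    prob = flow.prob.copy()
    if prob_flip > 0:
        flips = rng.random(flow.shape) < prob_flip
        prob = np.where(flips, 1.0 - prob, prob)
    return FlowField(prob=prob, grad_y=gy, grad_x=gx)
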
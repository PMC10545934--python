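"""File formats, manifests, and the end-to-end pipeline driver.

On-disk contracts: labeled masks are single-channel integer images (8/16-bit
TIFF or PNG, 0 = background); flow images are lossless 3-channel 8-bit
PNG/TIFF in channel order (probability, grad_y, grad_x). Every file the
pipeline writes is re-readable into an equal in-memory value.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import dataset_builder, flow_codec, population_sim
from .flow_codec import FlowField, FlowImage, canonicalize_mask

__all__ = [
    "read_labeled_mask",
    "write_labeled_mask",
    "read_flow_image",
    "write_flow_image",
    "read_image",
    "write_image",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("maskflow")


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_labeled_mask(path: str | Path) -> np.ndarray:
    """Read and canonicalize a labeled mask (single-channel integer image)."""
    arr = _read_array(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: labeled masks must be single-channel, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{path}: labeled masks must be integer-valued (8/16-bit), got {arr.dtype}"
        )
    return canonicalize_mask(arr.astype(np.int32))


def write_labeled_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a labeled mask as a 16-bit single-channel TIFF or PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be a 2-D integer array")
    if mask.size and (mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max):
        raise ValueError("mask ids must fit in uint16")
    path = Path(path)
    out = mask.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_flow_image(path: str | Path) -> FlowImage:
    """Read a 3-channel 8-bit flow image; anything else is a contract error."""
    arr = _read_array(path)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: flow images must have exactly 3 channels, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: flow images must be 8-bit, got {arr.dtype}")
    return FlowImage.from_array(arr)


def write_flow_image(flow: FlowImage | FlowField, path: str | Path) -> None:
    """Write a flow image losslessly (PNG or TIFF); FlowFields are discretized."""
    if isinstance(flow, FlowField):
        flow = flow_codec.discretize_flow(flow)
    path = Path(path)
    arr = flow.to_array()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path: str | Path) -> np.ndarray:
    return _read_array(path)


def write_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating):
        image = np.clip(image * 255.0, 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def load_config(path: str | Path) -> dict:
    """Load a TOML or JSON configuration file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def population_config_from_dict(cfg: dict) -> population_sim.PopulationConfig:
    """Build a PopulationConfig from a flat/nested dict mirroring field names."""
    cfg = dict(cfg)
    shape_cfg = cfg.pop("shape", {})
    shape = population_sim.ShapeConfig(**shape_cfg)
    return population_sim.PopulationConfig(shape=shape, **cfg)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Manifest:
    """Record of every file a pipeline run wrote, with checksums."""

    records: list[dict] = field(default_factory=list)

    def add(self, role: str, path: Path, source: str, offset=(0, 0), rotation: int = 0) -> None:
        self.records.append(
            {
                "role": role,
                "path": str(path),
                "source": source,
                "offset_row": offset[0],
                "offset_col": offset[1],
                "rotation": rotation,
                "checksum": _checksum(Path(path)),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, out_dir: str | Path) -> Manifest:
    """Run the desk-scale pipeline stages named by ``config``.

    Stages: ``simulate`` (population simulator -> masks -> flow images) and/or
    ``crops`` (paired image/mask directories -> crop extraction -> GAN folder
    export). External GAN/translation trainers are hook points that consume
    the exported directories; they are never invoked here. Logs the crop
    count M and the synthesized count K at each stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()

    if "simulate" in config:
        sim_cfg = dict(config["simulate"])
        K = int(sim_cfg.pop("k"))
        pop = population_config_from_dict(sim_cfg)
        masks = population_sim.simulate_dataset(pop, K)
        mask_dir = out_dir / "sim_masks"
        flow_dir = out_dir / "sim_flows"
        mask_dir.mkdir(exist_ok=True)
        flow_dir.mkdir(exist_ok=True)
        for i, mask in enumerate(masks):
            stem = f"{i:05d}"
            mpath = mask_dir / f"{stem}.tif"
            fpath = flow_dir / f"{stem}.png"
            write_labeled_mask(mask, mpath)
            write_flow_image(flow_codec.encode_mask(mask), fpath)
            manifest.add("mask", mpath, source=f"sim:{stem}")
            manifest.add("flow", fpath, source=f"sim:{stem}")
        logger.info("simulate: K=%d masks synthesized and encoded", K)

    if "crops" in config:
        crop_cfg = dict(config["crops"])
        image_dir = Path(crop_cfg.pop("images"))
        mask_dir = Path(crop_cfg.pop("masks"))
        image_paths = sorted(p for p in image_dir.iterdir() if p.is_file())
        mask_paths = sorted(p for p in mask_dir.iterdir() if p.is_file())
        if len(image_paths) != len(mask_paths):
            raise ValueError(
                f"crops stage: {len(image_paths)} images vs {len(mask_paths)} masks"
            )
        images = [read_image(p) for p in image_paths]
        masks = [read_labeled_mask(p) for p in mask_paths]
        ds = dataset_builder.extract_crops(images, masks, **crop_cfg)
        logger.info("crops: M=%d records extracted", len(ds))
        gan_manifest = dataset_builder.export_gan_folder(ds, out_dir / "gan")
        for row in gan_manifest.itertuples():
            off = (row.offset_row, row.offset_col)
            manifest.add("flow", Path(row.flow), source=str(row.source_id), offset=off, rotation=row.rotation)
            manifest.add("image", Path(row.image), source=str(row.source_id), offset=off, rotation=row.rotation)
            manifest.add("mask", Path(row.mask), source=str(row.source_id), offset=off, rotation=row.rotation)

    manifest.write(out_dir / "manifest.tsv")
    return manifest
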
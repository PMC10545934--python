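"""GAN-dataset assembly: overlapping crop extraction and folder export.

Crops of a fixed size are slid at a given stride over each image/mask pair
(final windows anchored to the far edge so coverage is complete), windows with
too few objects are discarded, and the three orthogonal rotations of every
kept crop are added. The export step materializes each mask crop's discretized
heat-flow image next to its microscopy crop in a layout directly consumable as
a GAN training folder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import flow_codec
from .flow_codec import FlowField, canonicalize_mask

__all__ = ["CropRecord", "CropDataset", "extract_crops", "export_gan_folder"]


@dataclass
class CropRecord:
    """One (image crop, mask crop) pair with provenance."""

    image: np.ndarray
    mask: np.ndarray
    source_id: int
    offset: tuple[int, int]  # (row, col) of the crop's top-left corner
    rotation: int  # degrees, one of {0, 90, 180, 270}


@dataclass
class CropDataset:
    records: list[CropRecord] = field(default_factory=list)
    crop_size: int = 256

    def __len__(self) -> int:
        return len(self.records)


def window_offsets(dim: int, crop: int, stride: int) -> list[int]:
    """Window start offsets along one axis, far edge anchored, deduplicated."""
    offs = list(range(0, dim - crop + 1, stride))
    last = dim - crop
    if last not in offs:
        offs.append(last)
    return offs


def _count_objects(mask_crop: np.ndarray, min_area: int) -> int:
    ids, counts = np.unique(mask_crop[mask_crop > 0], return_counts=True)
    return int((counts >= min_area).sum())


def extract_crops(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    crop_size: int = 256,
    stride: int | None = None,
    min_objects: int = 3,
    min_area: int = 9,
    add_rotations: bool = True,
) -> CropDataset:
    """Slide a square window over each pair and keep object-rich crops.

    A window is kept if it contains at least ``min_objects`` objects with at
    least ``min_area`` pixels inside the window. Each kept crop contributes
    its 90/180/270-degree rotations as well (image and mask rotated jointly),
    and mask crops are relabeled to canonical form.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must be paired lists of equal length")
    if stride is None:
        stride = crop_size // 2
    ds = CropDataset(crop_size=crop_size)
    for src_id, (img, msk) in enumerate(zip(images, masks)):
        img = np.asarray(img)
        msk = np.asarray(msk)
        if img.shape[:2] != msk.shape[:2]:
            raise ValueError(
                f"pair {src_id}: image shape {img.shape[:2]} != mask shape {msk.shape[:2]}"
            )
        H, W = msk.shape[:2]
        if crop_size > H or crop_size > W:
            raise ValueError(f"pair {src_id}: crop_size {crop_size} exceeds image {H}x{W}")
        for r in window_offsets(H, crop_size, stride):
            for c in window_offsets(W, crop_size, stride):
                mask_crop = msk[r : r + crop_size, c : c + crop_size]
                if _count_objects(mask_crop, min_area) < min_objects:
                    continue
                mask_crop = canonicalize_mask(mask_crop)
                img_crop = img[r : r + crop_size, c : c + crop_size].copy()
                rotations = (0, 90, 180, 270) if add_rotations else (0,)
                for rot in rotations:
                    k = rot // 90
                    ds.records.append(
                        CropRecord(
                            image=np.rot90(img_crop, k).copy(),
                            # rotation permutes pixels; relabel restores id order
                            mask=canonicalize_mask(np.rot90(mask_crop, k)),
                            source_id=src_id,
                            offset=(r, c),
                            rotation=rot,
                        )
                    )
    return ds


def export_gan_folder(
    ds: CropDataset,
    out_dir: str | Path,
    codec: Callable[[np.ndarray], FlowField] = flow_codec.encode_mask,
) -> pd.DataFrame:
    """Write flow images and image crops to parallel GAN-ready directories.

    Produces ``out_dir/flows/NNNNN.png`` and ``out_dir/images/NNNNN.png`` with
    matching zero-padded stems plus ``out_dir/masks/NNNNN.tif`` for the raw
    labels; returns the manifest as a DataFrame.
    """
    from . import io as mio  # local import to avoid a cycle at module load

    if len(ds) == 0:
        raise ValueError("cannot export an empty crop dataset")
    out_dir = Path(out_dir)
    flow_dir = out_dir / "flows"
    image_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    for d in (flow_dir, image_dir, mask_dir):
        d.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, rec in enumerate(ds.records):
        stem = f"{i:05d}"
        flow_img = flow_codec.discretize_flow(codec(rec.mask))
        mio.write_flow_image(flow_img, flow_dir / f"{stem}.png")
        mio.write_image(rec.image, image_dir / f"{stem}.png")
        mio.write_labeled_mask(rec.mask, mask_dir / f"{stem}.tif")
        rows.append(
            {
                "stem": stem,
                "flow": str(flow_dir / f"{stem}.png"),
                "image": str(image_dir / f"{stem}.png"),
                "mask": str(mask_dir / f"{stem}.tif"),
                "source_id": rec.source_id,
                "offset_row": rec.offset[0],
                "offset_col": rec.offset[1],
                "rotation": rec.rotation,
                "n_objects": int(rec.mask.max()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
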
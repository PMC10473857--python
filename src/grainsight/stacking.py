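"""Five-channel stacking and fixed-size per-grain crop extraction.

A scene's R, G, B planes and the two co-registered NIR planes are stacked
into one (H, W, 5) image; each segmented grain is cut out, square-padded and
resized to a fixed 100 x 100 x 5 tensor for the classifier.  All five planes
go through the identical geometric transform, so cross-plane registration is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

from .synthetic_scenes import CHANNEL_NAMES, MultiChannelImage, SceneGroundTruth

CROP_SIZE = 100

BackgroundFill = Literal["zero", "scene_background"]


@dataclass
class GrainCrop:
    """One grain as a fixed-size five-plane tensor plus provenance."""

    tensor: np.ndarray  # (size, size, 5) uint8
    source_scene: str
    region_label: int
    label: Optional[str] = None  # 'perfect' | 'imperfect' when known

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor)
        if t.ndim != 3 or t.shape[2] != 5 or t.shape[0] != t.shape[1]:
            raise ValueError(f"crop tensor must be (S, S, 5), got {t.shape}")


def stack_five(
    rgb: np.ndarray, nir1: np.ndarray, nir2: np.ndarray
) -> MultiChannelImage:
    """Stack an (H, W, 3) RGB image and two NIR planes in fixed order."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"rgb must be (H, W, 3), got {rgb.shape}")
    for name, plane in (("NIR1", nir1), ("NIR2", nir2)):
        if np.asarray(plane).shape != rgb.shape[:2]:
            raise ValueError(
                f"plane {name} has shape {np.asarray(plane).shape}, "
                f"expected {rgb.shape[:2]}"
            )
    planes = np.dstack([rgb, np.asarray(nir1), np.asarray(nir2)]).astype(np.uint8)
    return MultiChannelImage(planes)


def crop_grain(
    image: MultiChannelImage,
    grain_mask: np.ndarray,
    size: int = CROP_SIZE,
    background_fill: BackgroundFill = "zero",
    source_scene: str = "",
    region_label: int = 0,
    label: Optional[str] = None,
) -> GrainCrop:
    """Extract one grain as a ``size x size x 5`` tensor.

    The mask's bounding box is padded symmetrically to a square, the window
    is resized with bilinear interpolation (identically in all five planes),
    and pixels outside the grain mask are set to the fill value (0 or the
    original scene content).  Output is rounded half-up to uint8.
    """
    mask = np.asarray(grain_mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match the scene")
    if not mask.any():
        raise ValueError("empty grain mask")
    rr, cc = np.nonzero(mask)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1

    window = image.planes[r0:r1, c0:c1].astype(np.float64)
    mwin = mask[r0:r1, c0:c1]
    if background_fill == "zero":
        window = window * mwin[..., None]
    elif background_fill != "scene_background":
        raise ValueError(f"unknown background_fill {background_fill!r}")

    h, w = window.shape[:2]
    side = max(h, w)
    pr, pc = side - h, side - w
    pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2), (0, 0))
    # pad with the fill value so padding is indistinguishable from background
    if background_fill == "zero":
        window = np.pad(window, pad, mode="constant", constant_values=0.0)
    else:
        window = np.pad(window, pad, mode="edge")

    if side == size:
        out = window
    else:
        out = resize(
            window, (size, size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    tensor = np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)
    return GrainCrop(tensor, source_scene, region_label, label)


def crops_from_ground_truth(
    image: MultiChannelImage,
    gt: SceneGroundTruth,
    size: int = CROP_SIZE,
    background_fill: BackgroundFill = "zero",
    source_scene: str = "",
) -> list[GrainCrop]:
    """Labeled crops for every grain of a generated scene (training data)."""
    return [
        crop_grain(
            image, gt.grain_mask(k), size, background_fill,
            source_scene=source_scene, region_label=k, label=gt.labels[k - 1],
        )
        for k in range(1, gt.n_grains + 1)
    ]


def write_crops(
    crops: Sequence[GrainCrop], out_dir: str | Path
) -> pd.DataFrame:
    """Write crops as 5-page TIFFs plus a CSV index; returns the index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, crop in enumerate(crops):
        path = out / f"crop_{i:05d}.tiff"
        # one page per channel, fixed (R, G, B, NIR1, NIR2) order
        tifffile.imwrite(path, np.moveaxis(crop.tensor, -1, 0))
        rows.append(
            {
                "path": path.name,
                "scene": crop.source_scene,
                "region_label": crop.region_label,
                "class_label": crop.label if crop.label is not None else "",
            }
        )
    index = pd.DataFrame(rows, columns=["path", "scene", "region_label", "class_label"])
    index.to_csv(out / "crops.csv", index=False)
    return index
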
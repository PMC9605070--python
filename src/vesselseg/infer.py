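"""Whole-volume segmentation: patch, forward, stitch, threshold.

Inference grids use non-overlapping strides equal to the patch size with
end-aligned remainder patches, so every voxel is covered at least once;
overlapping probabilities are averaged before thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .nets import UNetMSS
from .patching import compute_patch_origins, extract_patches, stitch_patches
from .volio import LabelVolume, Volume


@dataclass
class InferenceConfig:
    patch_size: int = 64
    threshold: float = 0.5
    batch_size: int = 4

    def __post_init__(self):
        if self.patch_size % 16:
            raise ValueError(
                f"patch_size must be divisible by 16, got {self.patch_size}"
            )
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


def segment_volume(
    net: UNetMSS, v: Volume, cfg: InferenceConfig
) -> Tuple[LabelVolume, Volume]:
    """Segment a normalised volume; returns (binary mask, probability map).

    Volumes smaller than the patch are zero-padded to patch size and the
    outputs cropped back, with a warning.
    """
    data = v.data.astype(np.float32)
    orig_shape = data.shape
    pad = [max(0, cfg.patch_size - s) for s in orig_shape]
    if any(pad):
        warnings.warn(
            f"volume shape {orig_shape} smaller than patch "
            f"{cfg.patch_size}; zero-padding for inference",
            stacklevel=2,
        )
        data = np.pad(data, [(0, p) for p in pad])
    grid = compute_patch_origins(
        data.shape, cfg.patch_size, (cfg.patch_size,) * 3, cover_ends=True
    )
    patches = extract_patches(data, grid)
    net.eval()
    probs = []
    for start in range(0, len(patches), cfg.batch_size):
        batch = np.stack(patches[start : start + cfg.batch_size])[:, None]
        out = net(batch)
        probs.extend(out.full_res.data[:, 0])
    prob, coverage = stitch_patches(probs, grid)
    assert coverage.min() >= 1, "inference grid left voxels uncovered"
    sl = tuple(slice(0, s) for s in orig_shape)
    prob = prob[sl].astype(np.float32)
    mask = (prob > cfg.threshold).astype(np.uint8)
    return (
        LabelVolume(mask, v.spacing, v.affine),
        Volume(prob, v.spacing, v.affine),
    )
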
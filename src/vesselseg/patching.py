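"""Deterministic 3D patch grids, extraction, and averaged stitching.

Training grids typically use ``cover_ends=False`` (pure stride enumeration);
inference grids use ``cover_ends=True`` so that end-aligned patches cover
every voxel of the volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .volio import Volume


@dataclass
class PatchGrid:
    """Ordered patch origins for one volume."""

    patch_size: int
    strides: tuple
    origins: list
    volume_shape: tuple
    cover_ends: bool = False

    def __len__(self):
        return len(self.origins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "patch_size": self.patch_size,
                "strides": list(self.strides),
                "volume_shape": list(self.volume_shape),
                "cover_ends": self.cover_ends,
                "origins": [list(map(int, o)) for o in self.origins],
            }
        )

    @staticmethod
    def from_json(s: str) -> "PatchGrid":
        d = json.loads(s)
        return PatchGrid(
            d["patch_size"],
            tuple(d["strides"]),
            [tuple(o) for o in d["origins"]],
            tuple(d["volume_shape"]),
            d["cover_ends"],
        )


def compute_patch_origins(
    shape: Sequence[int],
    patch_size: int,
    strides: Sequence[int],
    cover_ends: bool = False,
) -> PatchGrid:
    """Enumerate patch origins on a regular per-axis stride lattice.

    Per axis the origins are {0, s, 2s, ...} up to shape - patch_size; with
    ``cover_ends`` an extra end-aligned origin is appended when the stride
    lattice leaves a remainder, so stitched patches cover the whole volume.
    """
    shape = tuple(int(s) for s in shape)
    strides = tuple(int(s) for s in strides)
    axis_origins = []
    for a, (d, s) in enumerate(zip(shape, strides)):
        if patch_size > d:
            raise ValueError(
                f"patch size {patch_size} exceeds volume extent {d} on axis {a}"
            )
        if s <= 0:
            raise ValueError(f"stride must be positive on axis {a}, got {s}")
        k = (d - patch_size) // s
        origins = list(range(0, k * s + 1, s))
        if cover_ends and origins[-1] < d - patch_size:
            origins.append(d - patch_size)
        axis_origins.append(origins)
    grid = [
        (x, y, z)
        for x in axis_origins[0]
        for y in axis_origins[1]
        for z in axis_origins[2]
    ]
    return PatchGrid(patch_size, strides, grid, shape, cover_ends)


def extract_patches(v, g: PatchGrid) -> list:
    """Copy out one patch-size^3 array per origin, in origin order."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    if tuple(data.shape) != tuple(g.volume_shape):
        raise ValueError(
            f"volume shape {data.shape} does not match grid shape {g.volume_shape}"
        )
    p = g.patch_size
    return [
        data[o[0] : o[0] + p, o[1] : o[1] + p, o[2] : o[2] + p].copy()
        for o in g.origins
    ]


def stitch_patches(patches: Sequence[np.ndarray], g: PatchGrid):
    """Reassemble patches into a volume, averaging overlaps.

    Returns ``(stitched, coverage)`` where coverage counts contributing
    patches per voxel; voxels never covered are 0 in the output.
    """
    if len(patches) != len(g.origins):
        raise ValueError(
            f"{len(patches)} patches given for {len(g.origins)} origins"
        )
    p = g.patch_size
    acc = np.zeros(g.volume_shape, dtype=np.float64)
    cov = np.zeros(g.volume_shape, dtype=np.int32)
    for patch, o in zip(patches, g.origins):
        sl = (
            slice(o[0], o[0] + p),
            slice(o[1], o[1] + p),
            slice(o[2], o[2] + p),
        )
        acc[sl] += patch
        cov[sl] += 1
    out = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    return out, cov
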
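"""Synthetic vascular phantoms: tubular ground truth, MRA-like corruption,
and label-noise emulation.

Phantoms emulate the qualitative appearance of time-of-flight MR angiography:
bright tubular trees (small branches one to two voxels in apparent diameter)
on a dark background, Gaussian noise, smooth multiplicative bias fields,
optional k-space spike interference, and imperfect labels with dropped thin
branches and gaps.  No MR physics is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .volio import LabelVolume, Volume


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 64)
    n_trees: int = 3
    branch_depth: int = 3
    radius_range: Tuple[float, float] = (1.0, 2.5)
    vessel_intensity: float = 0.8
    background_intensity: float = 0.1
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.2
    n_spikes: int = 0
    spike_amplitude: float = 0.2
    seed: int = 0

    def validate(self):
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel intensity must exceed background")
        rmin, rmax = self.radius_range
        if rmin < 0.5 or rmax > min(self.shape) / 4:
            raise ValueError(
                f"radius range {self.radius_range} outside [0.5, min(shape)/4]"
            )
        if rmin > rmax:
            raise ValueError("radius_range must be (min, max)")


_BALL_CACHE = {}


def _ball_offsets(radius: float):
    key = round(float(radius), 2)
    if key not in _BALL_CACHE:
        r = int(np.ceil(radius))
        ax = np.arange(-r, r + 1)
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        keep = dx**2 + dy**2 + dz**2 <= radius**2
        _BALL_CACHE[key] = np.stack(
            [dx[keep], dy[keep], dz[keep]], axis=1
        )
    return _BALL_CACHE[key]


def _stamp(label: np.ndarray, center, radius: float):
    offs = _ball_offsets(radius) + np.round(center).astype(int)
    shape = np.array(label.shape)
    ok = np.all((offs >= 0) & (offs < shape), axis=1)
    offs = offs[ok]
    label[offs[:, 0], offs[:, 1], offs[:, 2]] = 1


def _grow_tree(rng, shape, spec: PhantomSpec, samples):
    """Random-walk branching growth with bounded curvature; radius tapers
    linearly from radius_range max at the root to min at the deepest level."""
    rmin, rmax = spec.radius_range
    depth_max = max(spec.branch_depth, 1)
    step = 0.5
    curvature = 0.12
    branch_prob = 0.02
    start = rng.uniform(0.15, 0.85, size=3) * np.array(shape)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    stack = [(start, direction, 0)]
    max_steps = int(1.0 * min(shape) / step)
    while stack:
        point, d, depth = stack.pop()
        radius = rmax - (rmax - rmin) * min(depth, depth_max) / depth_max
        for _ in range(max_steps):
            samples.append((point.copy(), radius))
            d = d + curvature * rng.normal(size=3)
            d /= np.linalg.norm(d)
            point = point + step * d
            if np.any(point < -radius) or np.any(point > np.array(shape) + radius):
                break
            if depth < depth_max and rng.random() < branch_prob:
                child_dir = d + rng.normal(scale=0.8, size=3)
                child_dir /= np.linalg.norm(child_dir)
                stack.append((point.copy(), child_dir, depth + 1))


def _render(label: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Intensity image: background plus vessel signal, boundary-smoothed."""
    soft = gaussian_filter(label.astype(np.float32), sigma=0.5)
    img = spec.background_intensity + (
        spec.vessel_intensity - spec.background_intensity
    ) * np.clip(soft, 0.0, 1.0)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, LabelVolume]:
    """Grow seeded random branching trees and rasterise them as a binary
    label plus a bright-tube intensity volume; bit-reproducible from seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    label = np.zeros(spec.shape, dtype=np.uint8)
    samples = []
    for _ in range(spec.n_trees):
        _grow_tree(rng, spec.shape, spec, samples)
    for point, radius in samples:
        _stamp(label, point, radius)
    img = _render(label, spec)
    return Volume(img), LabelVolume(label)


def straight_tube_phantom(
    shape=(64, 64, 64), radius: float = 2.0, axis: int = 0,
    vessel_intensity: float = 0.8, background_intensity: float = 0.1,
) -> Tuple[Volume, LabelVolume]:
    """A single straight tube through the volume centre along ``axis``."""
    label = np.zeros(shape, dtype=np.uint8)
    center = np.array(shape) / 2.0
    for s in np.arange(0, shape[axis], 0.5):
        point = center.copy()
        point[axis] = s
        _stamp(label, point, radius)
    spec = PhantomSpec(
        shape=tuple(shape),
        vessel_intensity=vessel_intensity,
        background_intensity=background_intensity,
        radius_range=(1.0, max(1.0, radius)),
    )
    return Volume(_render(label, spec)), LabelVolume(label)


def _bias_field(rng, shape, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (second-order polynomial
    in normalised coordinates, scaled to unit maximum magnitude)."""
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    basis = [X, Y, Z, X * Y, Y * Z, X * Z, X**2, Y**2, Z**2]
    coeff = rng.normal(size=len(basis))
    poly = sum(c * b for c, b in zip(coeff, basis))
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def add_artifacts(v: Volume, spec: PhantomSpec) -> Volume:
    """Corrupt a normalised volume with noise, bias field, and k-space
    spikes (global additive sinusoids); output is re-clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    img = v.data.astype(np.float64).copy()
    if spec.bias_amplitude > 0:
        img *= _bias_field(rng, img.shape, spec.bias_amplitude)
    if spec.n_spikes > 0:
        coords = [np.linspace(0, 1, s, endpoint=False) for s in img.shape]
        X, Y, Z = np.meshgrid(*coords, indexing="ij")
        for _ in range(spec.n_spikes):
            freq = rng.uniform(2, 12, size=3)
            phase = rng.uniform(0, 2 * np.pi)
            img += spec.spike_amplitude * np.sin(
                2 * np.pi * (freq[0] * X + freq[1] * Y + freq[2] * Z) + phase
            )
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return Volume(
        np.clip(img, 0.0, 1.0).astype(np.float32), v.spacing, v.affine
    )


def corrupt_labels(
    y: LabelVolume,
    drop_fraction: float = 0.3,
    gap_length: float = 0.0,
    seed: int = 0,
    n_gaps: int = 3,
    thin_radius: float = 1.5,
) -> LabelVolume:
    """Emulate imperfect semi-automatic labels: drop thin-branch chunks
    totalling ~``drop_fraction`` of the foreground, then carve ``n_gaps``
    gaps of ``gap_length`` voxels.  The result is a subset of ``y``."""
    rng = np.random.default_rng(seed)
    out = y.data.astype(np.uint8).copy()
    total = int(out.sum())
    if total == 0 or (drop_fraction <= 0 and gap_length <= 0):
        return LabelVolume(out, y.spacing, y.affine)
    target = int(round(drop_fraction * total))
    if target > 0:
        dt = distance_transform_edt(out)
        thin = (out > 0) & (dt <= thin_radius)
        candidates = np.argwhere(thin)
        rng.shuffle(candidates)
        removed = 0
        chunk = _ball_offsets(2.0)
        shape = np.array(out.shape)
        for c in candidates:
            if removed >= target:
                break
            offs = chunk + c
            ok = np.all((offs >= 0) & (offs < shape), axis=1)
            offs = offs[ok]
            hit = out[offs[:, 0], offs[:, 1], offs[:, 2]] == 1
            removed += int(hit.sum())
            out[offs[hit, 0], offs[hit, 1], offs[hit, 2]] = 0
    if gap_length > 0 and out.sum() > 0:
        fg = np.argwhere(out > 0)
        for _ in range(n_gaps):
            c = fg[rng.integers(len(fg))]
            offs = _ball_offsets(gap_length / 2.0) + c
            ok = np.all((offs >= 0) & (offs < np.array(out.shape)), axis=1)
            offs = offs[ok]
            out[offs[:, 0], offs[:, 1], offs[:, 2]] = 0
    return LabelVolume(out, y.spacing, y.affine)
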
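"""Random elastic deformations via cubic B-spline control grids.

A coarse lattice of random displacement vectors (in normalised coordinates,
each axis spanning [-1, 1]) is densified to a per-voxel displacement field by
separable cubic B-spline interpolation, then applied as a backward warp
(``g'(v) = g(v + d(v))``).  The outermost control-point rings are locked to
zero so the deformation vanishes at patch borders.

``max_displacement`` is expressed in normalised units: 0.02 is 1% of the axis
extent, i.e. about 0.63 voxels on a 64-voxel axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import autodiff

CONTROL_POINT_CHOICES = (5, 6, 7)
DEFAULT_MAX_DISPLACEMENT = 0.02
DEFAULT_LOCKED_BORDER = 2


def bspline3(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel; support |t| < 2, partition of unity."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    inner = t <= 1.0
    outer = (t > 1.0) & (t < 2.0)
    out[inner] = t[inner] ** 3 / 2.0 - t[inner] ** 2 + 2.0 / 3.0
    out[outer] = (2.0 - t[outer]) ** 3 / 6.0
    return out


@dataclass
class ControlGrid:
    """Lattice of random control-point displacements (normalised units)."""

    n_points: int
    displacements: np.ndarray  # (n, n, n, 3)
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT
    locked_border: int = DEFAULT_LOCKED_BORDER

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        n = self.n_points
        if self.displacements.shape != (n, n, n, 3):
            raise ValueError(
                f"displacements shape {self.displacements.shape} != {(n, n, n, 3)}"
            )
        if np.any(np.abs(self.displacements) > self.max_displacement + 1e-12):
            raise ValueError("control displacement exceeds max_displacement")
        b = self.locked_border
        if b > 0:
            mask = np.zeros((n, n, n), dtype=bool)
            mask[b:-b, b:-b, b:-b] = True if n > 2 * b else False
            if np.any(self.displacements[~mask] != 0):
                raise ValueError("locked border control points must be zero")


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (voxel units), shape (X, Y, Z, 3)."""

    field: np.ndarray

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=np.float64)
        if self.field.ndim != 4 or self.field.shape[-1] != 3:
            raise ValueError(f"field must be (X,Y,Z,3), got {self.field.shape}")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.field.shape[:3]


def sample_control_grid(
    rng: np.random.Generator,
    shape,
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
    locked_border: int = DEFAULT_LOCKED_BORDER,
) -> ControlGrid:
    """Draw a random control grid: n uniform in {5,6,7}, displacements
    uniform in [-max_displacement, max_displacement], border rings zeroed."""
    if min(shape) < 8:
        raise ValueError(f"image shape {tuple(shape)} too small to deform")
    n = int(rng.choice(CONTROL_POINT_CHOICES))
    disp = rng.uniform(-max_displacement, max_displacement, size=(n, n, n, 3))
    b = locked_border
    if b > 0:
        mask = np.zeros((n, n, n), dtype=bool)
        if n > 2 * b:
            mask[b:-b, b:-b, b:-b] = True
        disp[~mask] = 0.0
    return ControlGrid(n, disp, max_displacement, locked_border)


def _norm_coords(n_vox: int) -> np.ndarray:
    """Voxel indices mapped to normalised [-1, 1] (single voxel -> 0)."""
    if n_vox == 1:
        return np.zeros(1)
    return -1.0 + 2.0 * np.arange(n_vox) / (n_vox - 1)


def densify(grid: ControlGrid, shape) -> DisplacementField:
    """Interpolate the control lattice to a dense voxel field.

    Separable evaluation: field(v) = sum_c d_c * prod_a B3((v_a - u_ca)/h),
    with control points at linspace(-1, 1, n) and spacing h = 2/(n-1).
    Normalised displacements are converted to voxel units via the per-axis
    half-extent (axis span [-1, 1] maps onto the full voxel extent).
    """
    n = grid.n_points
    u_ctrl = np.linspace(-1.0, 1.0, n)
    h = 2.0 / (n - 1)
    mats = []
    for d in shape:
        v = _norm_coords(d)
        mats.append(bspline3((v[:, None] - u_ctrl[None, :]) / h))  # (D, n)
    f = np.einsum(
        "xi,yj,zk,ijkd->xyzd", mats[0], mats[1], mats[2], grid.displacements
    )
    half_extent = np.array([(d - 1) / 2.0 if d > 1 else 0.0 for d in shape])
    return DisplacementField(f * half_extent.reshape(1, 1, 1, 3))


@dataclass
class ElasticTransform:
    """A sampled elastic deformation bound to one patch shape."""

    grid: ControlGrid
    shape: tuple
    seed: Optional[int] = None
    _field: Optional[DisplacementField] = dc_field(default=None, repr=False)

    @property
    def field(self) -> DisplacementField:
        if self._field is None:
            self._field = densify(self.grid, self.shape)
        return self._field

    @staticmethod
    def sample(rng: np.random.Generator, shape, **kw) -> "ElasticTransform":
        return ElasticTransform(sample_control_grid(rng, shape, **kw), tuple(shape))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_points": self.grid.n_points,
                "max_displacement": self.grid.max_displacement,
                "locked_border": self.grid.locked_border,
                "shape": list(self.shape),
                "seed": self.seed,
                "displacements": self.grid.displacements.tolist(),
            }
        )

    @staticmethod
    def from_json(s: str) -> "ElasticTransform":
        d = json.loads(s)
        grid = ControlGrid(
            d["n_points"],
            np.asarray(d["displacements"]),
            d["max_displacement"],
            d["locked_border"],
        )
        return ElasticTransform(grid, tuple(d["shape"]), d.get("seed"))


def warp(img: np.ndarray, field: DisplacementField, mode: str = "trilinear"):
    """Backward warp of a 3D array; out-of-bounds samples read 0."""
    img = np.asarray(img)
    if img.shape != field.shape:
        raise ValueError(
            f"image shape {img.shape} does not match field shape {field.shape}"
        )
    idx = np.indices(img.shape, dtype=np.float64)
    coords = idx + np.moveaxis(field.field, -1, 0)
    order = {"trilinear": 1, "nearest": 0}[mode]
    return map_coordinates(
        img.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )


def warp_tensor(x: "autodiff.Tensor", field: DisplacementField) -> "autodiff.Tensor":
    """Differentiable trilinear warp of a (N, C, X, Y, Z) tensor.

    Gradients flow through the sampled image, which lets the consistency
    objective backpropagate through the deformed prediction.
    """
    N = x.shape[0]
    shape = field.shape
    idx = np.indices(shape, dtype=x.data.dtype)
    coords = idx + np.moveaxis(field.field, -1, 0).astype(x.data.dtype)
    coords = np.broadcast_to(coords[None], (N, 3) + tuple(shape))
    return autodiff.warp_trilinear(x, coords)


def apply_transform_pair(t: ElasticTransform, x: np.ndarray, y: np.ndarray):
    """Warp an image/label pair: image trilinearly, label trilinearly then
    re-binarised at 0.5 so the supervised branch sees a binary target."""
    if x.shape != y.shape:
        raise ValueError(f"image {x.shape} and label {y.shape} shapes differ")
    tx = warp(x, t.field, mode="trilinear")
    ty = (warp(y.astype(np.float64), t.field, mode="trilinear") > 0.5).astype(
        y.dtype
    )
    return tx, ty
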
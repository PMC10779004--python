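"""Pseudo-density rendering, cross-correlation and biasing forces.

The fitting objective compares a density simulated from the current
atomic coordinates with the experimental particle (a 2-D projection
image or a 3-D subtomogram).  The simulated density places an isotropic
Gaussian of standard deviation σ at every atomic position (projected
analytically for images); the similarity measure is the zero-mean,
unit-variance normalized cross-correlation (ZNCC, "CC") over the full
grid, and the biasing potential is

    U_bias = −k_bias · CC(simulated(x), data),

whose exact negative gradient with respect to the coordinates is
returned by :func:`bias_forces` (computed analytically through the
Gaussian rendering and the pose rotation).

Conventions: Euler angles (rot, tilt, psi) in degrees, intrinsic ZYZ
(RELION-style); a pose rotates the model, shifts are applied in pixels
(in-plane for images) or voxels; images are projections along the grid
z axis; grids are D×D(-×D) with D even, the origin at the grid center
(index D/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import mrcfile
import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomicModel

logger = logging.getLogger(__name__)

__all__ = [
    "Pose", "DensityImage", "DensityVolume", "render_volume",
    "render_projection", "zncc", "bias_forces", "read_mrc", "write_mrc",
    "read_mrcs_stack", "write_mrcs_stack",
]

#: per-axis truncation radius of the rendered Gaussians, in units of σ
TRUNCATION_SIGMAS = 4.0


@dataclass
class Pose:
    """Rigid-body alignment: intrinsic ZYZ Euler angles + shifts.

    ``shift`` is in pixels (2-vector, images) or voxels (3-vector,
    volumes), applied after rotation.
    """

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift: tuple[float, ...] = (0.0, 0.0)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True)

    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()


@dataclass
class DensityImage:
    """Pixel values on a square D×D grid, origin at the grid center."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("image must be square")
        if self.data.shape[0] % 2:
            raise ValueError("grid dimension must be even")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite pixel values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class DensityVolume:
    """Voxel values on a cubic D×D×D grid, origin at the grid center."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("volume must be cubic")
        if self.data.shape[0] % 2:
            raise ValueError("grid dimension must be even")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voxel values")

    @property
    def shape(self):
        return self.data.shape


def _check_margin(pos: np.ndarray, D: int, sampling: float, sigma: float) -> None:
    half = D // 2 * sampling
    if np.any(np.abs(pos) > half - 3.0 * sigma):
        logger.warning("model approaches the box edge within 3σ; "
                       "density will be clipped")


def _stencil(center: float, D: int, sampling: float, sigma: float):
    """1-D index window and Gaussian values around `center` (Å)."""
    r = TRUNCATION_SIGMAS * sigma
    lo = max(0, int(math.ceil((center - r) / sampling)) + D // 2)
    hi = min(D - 1, int(math.floor((center + r) / sampling)) + D // 2)
    if lo > hi:
        return None
    idx = np.arange(lo, hi + 1)
    d = (idx - D // 2) * sampling - center
    return idx, d, np.exp(-0.5 * (d / sigma) ** 2)


def render_volume(
    model: AtomicModel, voxel_size: float, D: int, sigma: float,
    coords: np.ndarray | None = None,
) -> DensityVolume:
    """Sum of unit-amplitude 3-D Gaussians at the atomic positions.

    Axis order of the array is (z, y, x) as is conventional for EM
    volumes; truncation at ``TRUNCATION_SIGMAS``·σ per axis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos = model.coords if coords is None else np.asarray(coords).reshape(-1, 3)
    _check_margin(pos, D, voxel_size, sigma)
    vol = np.zeros((D, D, D))
    for p in pos:
        sx = _stencil(p[0], D, voxel_size, sigma)
        sy = _stencil(p[1], D, voxel_size, sigma)
        sz = _stencil(p[2], D, voxel_size, sigma)
        if sx is None or sy is None or sz is None:
            continue
        gx, gy, gz = sx[2], sy[2], sz[2]
        vol[np.ix_(sz[0], sy[0], sx[0])] += (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :])
    return DensityVolume(vol, voxel_size)


def _posed_coords(coords: np.ndarray, pose: Pose, sampling: float,
                  ndim: int) -> np.ndarray:
    """Rotate coordinates by the pose and apply shifts (Å)."""
    y = coords @ pose.matrix().T
    shift = np.zeros(3)
    shift[: len(pose.shift)] = np.asarray(pose.shift, dtype=float) * sampling
    if ndim == 2:
        y = y + shift[None, :]
    else:
        y = y + shift[None, :]
    return y


def render_projection(
    model: AtomicModel, pose: Pose, pixel_size: float, D: int, sigma: float,
    coords: np.ndarray | None = None,
) -> DensityImage:
    """Analytic projection image of the posed model.

    The model is rotated by the pose, shifted in-plane, and projected
    along z: each atom contributes a 2-D Gaussian of the same σ with
    amplitude √(2π)·σ/pixel_size, which makes the image numerically
    equal to the z-sum of the corresponding volumetric render.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = model.coords if coords is None else np.asarray(coords).reshape(-1, 3)
    y = _posed_coords(x, pose, pixel_size, ndim=2)
    _check_margin(y[:, :2], D, pixel_size, sigma)
    amp = math.sqrt(2.0 * math.pi) * sigma / pixel_size
    img = np.zeros((D, D))
    for p in y:
        sx = _stencil(p[0], D, pixel_size, sigma)
        sy = _stencil(p[1], D, pixel_size, sigma)
        if sx is None or sy is None:
            continue
        img[np.ix_(sy[0], sx[0])] += amp * np.outer(sy[2], sx[2])
    return DensityImage(img, pixel_size)


def zncc(a, b) -> float:
    """Zero-mean, unit-variance normalized cross-correlation in [−1, 1]."""
    def _values(obj):
        if isinstance(obj, (DensityImage, DensityVolume)):
            return obj.data.ravel()
        return np.asarray(obj, dtype=float).ravel()

    xa = _values(a)
    xb = _values(b)
    if xa.shape != xb.shape:
        raise ValueError("shape mismatch")
    ca = xa - xa.mean()
    cb = xb - xb.mean()
    na = np.linalg.norm(ca)
    nb = np.linalg.norm(cb)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-variance input to zncc")
    return float(np.dot(ca, cb) / (na * nb))


def bias_forces(
    model: AtomicModel,
    data: DensityImage | DensityVolume,
    pose: Pose,
    k_bias: float,
    sigma: float,
    coords: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """CC and the exact forces of the biasing potential −k_bias·CC.

    The gradient is taken analytically through the Gaussian rendering
    and the pose rotation; forces are returned in the unrotated model
    frame.  Raises on zero-variance simulated density.
    """
    if k_bias < 0:
        raise ValueError("k_bias must be ≥ 0")
    x = model.coords if coords is None else np.asarray(coords).reshape(-1, 3)
    n = x.shape[0]
    R = pose.matrix()
    if isinstance(data, DensityImage):
        ndim, D, sampling = 2, data.data.shape[0], data.pixel_size
        sim = render_projection(model, pose, sampling, D, sigma, coords=x)
    else:
        ndim, D, sampling = 3, data.data.shape[0], data.voxel_size
        sim = render_volume(model, sampling, D, sigma,
                            coords=_posed_coords(x, pose, sampling, ndim=3))
    s = sim.data.ravel()
    d = data.data.ravel()
    cs = s - s.mean()
    ns = np.linalg.norm(cs)
    if ns < 1e-12:
        raise ValueError("zero-variance simulated density")
    cd = d - d.mean()
    nd = np.linalg.norm(cd)
    if nd < 1e-12:
        raise ValueError("zero-variance data")
    shat = cs / ns
    dhat = cd / nd
    cc = float(np.dot(shat, dhat))
    # ∂CC/∂s_p, with the centering projector absorbed (C dhat = dhat)
    dcc_ds = (dhat - cc * shat) / ns
    grid = dcc_ds.reshape(sim.data.shape)

    y = _posed_coords(x, pose, sampling, ndim=ndim)
    grad_cc = np.zeros((n, 3))
    amp = math.sqrt(2.0 * math.pi) * sigma / sampling if ndim == 2 else 1.0
    for i, p in enumerate(y):
        sx = _stencil(p[0], D, sampling, sigma)
        sy = _stencil(p[1], D, sampling, sigma)
        if sx is None or sy is None:
            continue
        if ndim == 2:
            g2 = amp * np.outer(sy[2], sx[2])          # (ny, nx)
            w = grid[np.ix_(sy[0], sx[0])] * g2
            # ∂s_p/∂pos_x = g·(grid_x − pos_x)/σ², and sx[1] = grid − pos
            gx = np.sum(w * sx[1][None, :]) / sigma**2
            gy = np.sum(w * sy[1][:, None]) / sigma**2
            grad_pos = np.array([gx, gy, 0.0])
        else:
            sz = _stencil(p[2], D, sampling, sigma)
            if sz is None:
                continue
            g3 = (sz[2][:, None, None] * sy[2][None, :, None]
                  * sx[2][None, None, :])
            w = grid[np.ix_(sz[0], sy[0], sx[0])] * g3
            gx = np.sum(w * sx[1][None, None, :]) / sigma**2
            gy = np.sum(w * sy[1][None, :, None]) / sigma**2
            gz = np.sum(w * sz[1][:, None, None]) / sigma**2
            grad_pos = np.array([gx, gy, gz])
        # chain rule through pos = R x + t  →  ∇_x = Rᵀ ∇_pos
        grad_cc[i] = R.T @ grad_pos
    forces = k_bias * grad_cc            # F = −∇(−k·CC) = k ∇CC
    return cc, forces


def normalize_density(arr: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization applied to data at load."""
    arr = np.asarray(arr, dtype=float)
    sd = arr.std()
    if sd < 1e-12:
        raise ValueError("zero-variance density cannot be normalized")
    return (arr - arr.mean()) / sd


def read_mrc(path: str | Path, voxel_size: float | None = None) -> DensityVolume:
    """Read a 3-D MRC volume; voxel size from the header unless given."""
    with mrcfile.open(str(path), permissive=True) as mrc:
        data = np.asarray(mrc.data, dtype=float)
        vs = float(mrc.voxel_size.x) if voxel_size is None else voxel_size
    if vs <= 0:
        vs = 1.0
    return DensityVolume(data, vs)


def write_mrc(vol: DensityVolume, path: str | Path) -> None:
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(vol.data.astype(np.float32))
        mrc.voxel_size = vol.voxel_size


def read_mrcs_stack(
    path: str | Path, pixel_size: float | None = None
) -> list[DensityImage]:
    """Read a 2-D particle stack from an MRCS file."""
    with mrcfile.open(str(path), permissive=True) as mrc:
        data = np.asarray(mrc.data, dtype=float)
        ps = float(mrc.voxel_size.x) if pixel_size is None else pixel_size
    if ps <= 0:
        ps = 1.0
    if data.ndim == 2:
        data = data[None]
    return [DensityImage(frame, ps) for frame in data]


def write_mrcs_stack(images: list[DensityImage], path: str | Path) -> None:
    if not images:
        raise ValueError("empty image stack")
    stack = np.stack([im.data for im in images]).astype(np.float32)
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(stack)
        mrc.voxel_size = images[0].pixel_size
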
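"""Conformational landscape construction and analysis.

The per-particle fitted models are rigid-body superposed on a common
reference (Kabsch least-squares alignment) to discard the overall
rotations/translations picked up during the simulations, then embedded
in a low-dimensional space by PCA of the flattened Cα coordinates (or
UMAP, when available, for non-linear structure).  The resulting point
cloud supports free-energy surfaces (−k_B T log density), clustering
(equal-width bins along an axis, or K-means), synthetic motion
trajectories along principal axes, and per-cluster averages of models
and densities (backprojection reconstruction for images, re-oriented
averaging for subtomograms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .em_bias import DensityImage, DensityVolume, Pose
from .structure_io import AtomicModel

logger = logging.getLogger(__name__)

__all__ = [
    "Landscape", "ClusterAssignment", "align_ensemble", "pca_landscape",
    "umap_landscape", "free_energy_map", "cluster_along_axis",
    "cluster_kmeans", "trajectory_along_axis", "cluster_averages",
]


@dataclass
class Landscape:
    """Low-dimensional embedding of an ensemble of conformations."""

    coords: np.ndarray                      # (n_particles, n_components)
    mean_model: np.ndarray                  # (3N,)
    components: np.ndarray                  # (n_components, 3N); pca only
    explained_variance_fraction: np.ndarray
    method: str = "pca"                     # pca | umap

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class ClusterAssignment:
    """Integer label per particle; −1 marks unassigned points."""

    labels: np.ndarray
    n_clusters: int
    method: str                              # kmeans | along_axis

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        assigned = self.labels[self.labels >= 0]
        if len(assigned) and assigned.max() >= self.n_clusters:
            raise ValueError("label exceeds n_clusters")


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal least-squares superposition of `mobile` onto `ref`."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    a = mobile - mc
    b = ref - rc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return (a @ rot) + rc


def align_ensemble(
    models: list[AtomicModel], reference: AtomicModel
) -> list[AtomicModel]:
    """Superpose every model on the reference (rotation + translation)."""
    n = reference.n_atoms
    if n < 3:
        raise ValueError("need at least 3 atoms for rigid alignment")
    out = []
    for m in models:
        if m.n_atoms != n:
            raise ValueError("model size differs from reference")
        out.append(m.with_coords(_kabsch(m.coords, reference.coords)))
    return out


def pca_landscape(models: list[AtomicModel], n_components: int) -> Landscape:
    """PCA of the flattened, aligned coordinates about the ensemble mean."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    flat = np.vstack([m.coords.ravel() for m in models])
    if n_components > min(len(models) - 1, flat.shape[1]):
        raise ValueError("n_components too large for the ensemble")
    if np.allclose(flat.var(axis=0), 0.0):
        raise ValueError("zero-variance ensemble (identical models)")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(flat)
    return Landscape(
        coords=coords,
        mean_model=pca.mean_,
        components=pca.components_,
        explained_variance_fraction=pca.explained_variance_ratio_,
        method="pca",
    )


def umap_landscape(
    models: list[AtomicModel], n_components: int, seed: int = 0
) -> Landscape:
    """Non-linear UMAP embedding of the aligned ensemble (2–3 dims)."""
    if n_components > 3:
        raise ValueError("umap embedding supports at most 3 components")
    if len(models) < 10:
        raise ValueError("need at least 10 models for a UMAP embedding")
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "umap-learn is not installed; use pca_landscape instead") from exc
    flat = np.vstack([m.coords.ravel() for m in models])
    reducer = umap.UMAP(n_components=n_components, random_state=seed,
                        n_jobs=1)
    coords = reducer.fit_transform(flat)
    return Landscape(
        coords=np.asarray(coords, dtype=float),
        mean_model=flat.mean(axis=0),
        components=np.zeros((0, flat.shape[1])),
        explained_variance_fraction=np.zeros(0),
        method="umap",
    )


def free_energy_map(
    coords: np.ndarray,
    axes: list[int] | tuple[int, ...] = (0, 1),
    grid_resolution: int = 64,
    temperature: float = 1.0,
) -> tuple[np.ma.MaskedArray, list[np.ndarray]]:
    """Free-energy surface over a histogram of landscape points.

    ΔG = −k_B T ln(ρ/ρ_max) in units of k_B T (``temperature`` is a
    multiplicative factor on that scale, default 1).  Empty bins are
    masked.  Returns the masked ΔG grid and the bin edges per axis.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    axes = list(axes)
    if not 1 <= len(axes) <= 3:
        raise ValueError("1 to 3 axes required")
    pts = coords[:, axes]
    for k in range(pts.shape[1]):
        if np.ptp(pts[:, k]) == 0 and len(pts) > 1:
            raise ValueError(f"zero-extent axis {axes[k]}")
    hist, edges = np.histogramdd(pts, bins=grid_resolution)
    rho_max = hist.max()
    if rho_max == 0:
        raise ValueError("no points to histogram")
    with np.errstate(divide="ignore"):
        dg = -temperature * np.log(hist / rho_max)
    return np.ma.masked_invalid(dg), list(edges)


def cluster_along_axis(
    coords: np.ndarray, axis: np.ndarray | int, n_clusters: int
) -> ClusterAssignment:
    """Equal-width bins of the projection onto an axis (or component id)."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be ≥ 1")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if np.isscalar(axis) or np.ndim(axis) == 0:
        proj = coords[:, int(axis)]
    else:
        axis = np.asarray(axis, dtype=float)
        proj = coords @ (axis / np.linalg.norm(axis))
    lo, hi = proj.min(), proj.max()
    if hi - lo == 0:
        if n_clusters > 1:
            raise ValueError("degenerate projection: zero range")
        return ClusterAssignment(np.zeros(len(proj), int), 1, "along_axis")
    edges = np.linspace(lo, hi, n_clusters + 1)
    labels = np.clip(np.searchsorted(edges, proj, side="right") - 1,
                     0, n_clusters - 1)
    return ClusterAssignment(labels, n_clusters, "along_axis")


def cluster_kmeans(coords: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """Seeded K-means (10 restarts, best inertia kept)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if k > coords.shape[0]:
        raise ValueError("k exceeds number of points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    return ClusterAssignment(labels, k, "kmeans")


def trajectory_along_axis(
    landscape: Landscape,
    axis_index: int,
    n_frames: int,
    amplitude_range: tuple[float, float],
    template: AtomicModel,
) -> list[AtomicModel]:
    """Synthetic motion along one principal axis.

    Frame t is mean_model + a_t · component, with a_t evenly spaced
    over ``amplitude_range``; ``template`` supplies atom metadata.
    """
    if landscape.method != "pca":
        raise ValueError("trajectories require a PCA landscape")
    if not 0 <= axis_index < landscape.components.shape[0]:
        raise ValueError("axis_index out of range")
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    amps = np.linspace(amplitude_range[0], amplitude_range[1], n_frames)
    comp = landscape.components[axis_index]
    n = template.n_atoms
    return [
        template.with_coords((landscape.mean_model + a * comp).reshape(n, 3))
        for a in amps
    ]


def _rotate_volume_to_reference(vol: DensityVolume, pose: Pose) -> np.ndarray:
    """Resample a posed volume into the reference frame.

    The subtomogram shows the particle rotated by R and shifted; the
    reference-frame density at point x is the subtomogram sampled at
    R·x + shift.
    """
    D = vol.data.shape[0]
    R = pose.matrix()
    shift_vox = np.zeros(3)
    shift_vox[: len(pose.shift)] = pose.shift
    idx = np.indices((D, D, D)).astype(float)   # (3, D, D, D) in (z, y, x)
    center = D // 2
    # physical (x, y, z) of each output voxel
    xyz = np.stack([idx[2] - center, idx[1] - center, idx[0] - center])
    pts = np.tensordot(R, xyz, axes=(1, 0))     # R · x, in voxels
    pts += shift_vox[:, None, None, None]
    sample = np.stack([pts[2] + center, pts[1] + center, pts[0] + center])
    return scipy.ndimage.map_coordinates(vol.data, sample, order=1,
                                         mode="constant", cval=0.0)


def _backproject(images: list[DensityImage], poses: list[Pose],
                 D: int) -> DensityVolume:
    """Direct real-space backprojection of projection images.

    Each image is smeared back along its viewing direction: the value
    at volume point x is the mean over images of the image sampled at
    the in-plane coordinates of R·x (plus the recorded shift).
    """
    px = images[0].pixel_size
    center = D // 2
    idx = np.indices((D, D, D)).astype(float)
    xyz = np.stack([idx[2] - center, idx[1] - center, idx[0] - center]) * px
    vol = np.zeros((D, D, D))
    for img, pose in zip(images, poses):
        R = pose.matrix()
        pts = np.tensordot(R, xyz, axes=(1, 0))
        sx = (pts[0] + pose.shift[0] * px) / px + center
        sy = (pts[1] + pose.shift[1] * px) / px + center
        vol += scipy.ndimage.map_coordinates(
            img.data, np.stack([sy, sx]), order=1, mode="constant", cval=0.0)
    return DensityVolume(vol / len(images), px)


def cluster_averages(
    models: list[AtomicModel],
    assignment: ClusterAssignment,
    particles=None,
    volume_size: int | None = None,
) -> dict[int, tuple[AtomicModel, DensityVolume | None]]:
    """Per-cluster average model and average density.

    ``models`` must already be rigid-body aligned.  When ``particles``
    is given, the density is a backprojection reconstruction from the
    member images (2-D data) or the re-oriented member average (3-D
    data).  Empty clusters are skipped with a warning.
    """
    out: dict[int, tuple[AtomicModel, DensityVolume | None]] = {}
    labels = assignment.labels
    for c in range(assignment.n_clusters):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            logger.warning("cluster %d is empty; skipped", c)
            continue
        mean_coords = np.mean([models[i].coords for i in members], axis=0)
        avg_model = models[members[0]].with_coords(mean_coords)
        density = None
        if particles is not None:
            items = [particles.items[i] for i in members]
            poses = [particles.poses[i] for i in members]
            if particles.is_volume:
                acc = np.mean([
                    _rotate_volume_to_reference(v, p)
                    for v, p in zip(items, poses)], axis=0)
                density = DensityVolume(acc, particles.sampling)
            else:
                D = volume_size or items[0].data.shape[0]
                density = _backproject(items, poses, D)
        out[c] = (avg_model, density)
    return out
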
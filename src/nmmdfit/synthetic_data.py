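"""Ground-truth heterogeneous dataset generation.

Every downstream module is exercised on data produced here: a toy Cα
structure is displaced along chosen elastic-network normal modes with
known per-particle amplitudes, rendered to projection images or volumes
at known poses with Gaussian smearing, and corrupted with additive
white Gaussian noise of a stated standard deviation.  The generator
records the full ground truth (amplitudes, poses, noise level, true
RMSD from the reference) so that recovery can be measured exactly.

The clean signal is rendered before noise is added, so it is
independent of ``noise_sd``; everything is reproducible bit-for-bit
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .em_bias import (DensityImage, DensityVolume, Pose, render_projection,
                      render_volume, write_mrc, write_mrcs_stack)
from .enm_nma import NormalModeSet
from .structure_io import AtomicModel, rmsd

__all__ = [
    "make_toy_structure", "make_heterogeneous_set", "ParticleSet",
    "uniform_amplitudes", "gaussian_mixture_amplitudes",
    "uniform_poses", "identity_poses", "amplitude_for_rmsd",
]


@dataclass
class ParticleSet:
    """Data items (images or volumes) with per-item pose and identifier."""

    items: list
    poses: list[Pose]
    ids: list[str]
    sampling: float        # pixel/voxel size, Å

    def __post_init__(self) -> None:
        if not (len(self.items) == len(self.poses) == len(self.ids)):
            raise ValueError("items, poses and ids must have equal length")
        shapes = {item.data.shape for item in self.items}
        if len(shapes) > 1:
            raise ValueError("all items must share one shape")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def is_volume(self) -> bool:
        return isinstance(self.items[0], DensityVolume)


def _helix(n_res: int) -> np.ndarray:
    # CA spiral: rise 1.5 Å, 100°/residue; radius set for 3.8 Å spacing
    rise, turn = 1.5, np.deg2rad(100.0)
    radius = np.sqrt(3.8**2 - rise**2) / (2.0 * np.sin(turn / 2.0))
    t = np.arange(n_res)
    return np.column_stack([
        radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t])


def _hairpin(n_res: int) -> np.ndarray:
    # two antiparallel strands ~5 Å apart joined by a turn bead; the
    # strands carry a pleat in y and z so the fold is genuinely 3-D
    # (a flat hairpin would have floppy out-of-plane ENM modes)
    n1 = (n_res - 1) // 2
    coords = [np.zeros(3)]
    for i in range(n1 - 1):
        step = np.array([1.0, 0.35 * (-1.0) ** i,
                         0.5 * np.cos(2.0 * np.pi * i / 3.0)])
        coords.append(coords[-1] + 3.8 * step / np.linalg.norm(step))
    d = 4.5
    a = np.sqrt(3.8**2 - (d / 2.0) ** 2)
    coords.append(coords[-1] + np.array([a, d / 2.0, 0.0]))
    coords.append(coords[-1] + np.array([-a, d / 2.0, 0.0]))
    for i in range(n_res - n1 - 2):
        step = np.array([-1.0, 0.35 * (-1.0) ** i,
                         0.5 * np.cos(2.0 * np.pi * i / 3.0 + 1.0)])
        coords.append(coords[-1] + 3.8 * step / np.linalg.norm(step))
    return np.vstack(coords)


def _two_domain(n_res: int) -> np.ndarray:
    # two compact helical lobes joined by a 3-residue extended linker;
    # the hinge guarantees collective low-frequency modes
    n_link = 3
    n1 = (n_res - n_link) // 2
    n2 = n_res - n_link - n1
    lobe1 = _helix(n1)
    end = lobe1[-1]
    # the 3-residue linker arcs up and over so the second lobe folds
    # back against the first: the domains stay within spring reach of
    # each other, which turns the hinge into a soft (but nonzero)
    # collective mode instead of a zero-energy mechanism
    dirs = [np.array([1.0, 0.3, 1.0]), np.array([0.2, -0.3, 1.0]),
            np.array([-1.0, 0.3, 1.0])]
    steps = [3.8 * d / np.linalg.norm(d) for d in dirs]
    linker = end + np.cumsum(steps, axis=0)
    lobe2 = _helix(n2)
    rot = Rotation.from_euler("x", 150, degrees=True).as_matrix()
    lobe2 = lobe2 @ rot.T
    # attach along a bent direction (a straight junction would create a
    # 180° angle term with a singular Cartesian gradient)
    attach = np.array([-1.0, -0.4, 0.9])
    offset = linker[-1] + 3.8 * attach / np.linalg.norm(attach) - lobe2[0]
    return np.vstack([lobe1, linker, lobe2 + offset])


def make_toy_structure(n_res: int, kind: str, seed: int = 0) -> AtomicModel:
    """Deterministic CA-only toy model with 3.8 Å consecutive spacing.

    ``kind`` selects the geometry: ``helix``, ``hairpin`` or
    ``two_domain``.  The seed adds a reproducible sub-0.005 Å jitter to
    break exact symmetries; consecutive spacing stays within 3.8±0.01 Å.
    """
    if n_res < 8:
        raise ValueError("n_res must be ≥ 8")
    builders = {"helix": _helix, "hairpin": _hairpin, "two_domain": _two_domain}
    if kind not in builders:
        raise ValueError(f"unknown structure kind {kind!r}; "
                         f"choose from {sorted(builders)}")
    coords = builders[kind](n_res)
    rng = np.random.default_rng(seed)
    coords = coords + np.clip(rng.normal(0.0, 0.002, coords.shape),
                              -0.005, 0.005)
    coords -= coords.mean(axis=0)
    n = coords.shape[0]
    return AtomicModel(
        atom_name=np.array(["CA"] * n, dtype=object),
        residue_index=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n, dtype=object),
        coords=coords,
    )


def amplitude_for_rmsd(target_rmsd: float, n_atoms: int) -> float:
    """Mode amplitude giving a displacement of the requested RMSD.

    For a unit-normalized mode over N atoms the displacement RMSD is
    |a|/√N, so a = RMSD·√N.
    """
    return float(target_rmsd * np.sqrt(n_atoms))


def uniform_amplitudes(low: float, high: float):
    """Sampler: amplitude uniform in [low, high] (single-mode direction)."""
    def sample(rng: np.random.Generator, n_modes: int) -> np.ndarray:
        a = np.zeros(n_modes)
        a[0] = rng.uniform(low, high)
        return a
    return sample


def gaussian_mixture_amplitudes(centers, sd: float, weights=None):
    """Sampler: two (or more) Gaussian clusters along the first mode."""
    centers = np.asarray(centers, dtype=float)
    weights = (np.full(len(centers), 1.0 / len(centers))
               if weights is None else np.asarray(weights, dtype=float))

    def sample(rng: np.random.Generator, n_modes: int) -> np.ndarray:
        a = np.zeros(n_modes)
        k = rng.choice(len(centers), p=weights / weights.sum())
        a[0] = rng.normal(centers[k], sd)
        return a
    return sample


def uniform_poses(with_shifts: float = 0.0):
    """Pose sampler: orientation uniform over SO(3), optional shift range."""
    def sample(rng: np.random.Generator, ndim: int) -> Pose:
        quat = rng.normal(size=4)
        quat /= np.linalg.norm(quat)
        rot, tilt, psi = Rotation.from_quat(quat).as_euler("ZYZ", degrees=True)
        nshift = 2 if ndim == 2 else 3
        shift = tuple(rng.uniform(-with_shifts, with_shifts, nshift))
        return Pose(rot=rot, tilt=tilt, psi=psi, shift=shift)
    return sample


def identity_poses():
    """Pose sampler: identity orientation, zero shift (subtomogram-like)."""
    def sample(rng: np.random.Generator, ndim: int) -> Pose:
        return Pose(shift=(0.0,) * (2 if ndim == 2 else 3))
    return sample


def make_heterogeneous_set(
    model: AtomicModel,
    modes: NormalModeSet,
    mode_indices,
    amplitude_sampler,
    n_particles: int,
    data_kind: str,
    D: int,
    sampling: float,
    sigma: float,
    noise_sd: float,
    pose_sampler,
    seed: int = 0,
) -> tuple[ParticleSet, pd.DataFrame]:
    """Generate a heterogeneous particle set with full ground truth.

    Per particle: draw mode amplitudes and a pose, displace the model
    along the selected modes, render a projection image (``images``) or
    a volume (``subtomograms``) with Gaussian width ``sigma``, and add
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.

    Returns the particle set and a ground-truth table with one row per
    particle (id, amplitudes, pose, noise sd, true RMSD from reference).
    """
    if data_kind not in ("images", "subtomograms"):
        raise ValueError("data_kind must be 'images' or 'subtomograms'")
    ndim = 2 if data_kind == "images" else 3
    basis = modes.select(mode_indices)          # (n_modes, 3N)
    n = model.n_atoms
    rng = np.random.default_rng(seed)
    items, poses, ids, rows = [], [], [], []
    for p in range(n_particles):
        amp = np.asarray(amplitude_sampler(rng, basis.shape[0]), dtype=float)
        disp = (amp @ basis).reshape(n, 3)
        coords = model.coords + disp
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for particle {p}")
        pose = pose_sampler(rng, ndim)
        if ndim == 2:
            clean = render_projection(model, pose, sampling, D, sigma,
                                      coords=coords)
            noisy = clean.data + rng.normal(0.0, noise_sd, clean.data.shape)
            items.append(DensityImage(noisy, sampling))
        else:
            from .em_bias import _posed_coords
            posed = _posed_coords(coords, pose, sampling, ndim=3)
            clean = render_volume(model, sampling, D, sigma, coords=posed)
            noisy = clean.data + rng.normal(0.0, noise_sd, clean.data.shape)
            items.append(DensityVolume(noisy, sampling))
        poses.append(pose)
        pid = f"particle_{p:05d}"
        ids.append(pid)
        rows.append({
            "id": pid,
            **{f"amp_{m}": amp[k] for k, m in enumerate(mode_indices)},
            "rot": pose.rot, "tilt": pose.tilt, "psi": pose.psi,
            "shift_x": pose.shift[0], "shift_y": pose.shift[1],
            **({"shift_z": pose.shift[2]} if ndim == 3 else {}),
            "noise_sd": noise_sd,
            "true_rmsd": rmsd(coords, model.coords),
        })
    table = pd.DataFrame(rows)
    return ParticleSet(items, poses, ids, sampling), table


def write_particle_set(particles: ParticleSet, table: pd.DataFrame,
                       prefix: str | Path) -> None:
    """Write the stack (MRC/MRCS), pose metadata TSV and ground truth TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta_cols = ["id", "rot", "tilt", "psi", "shift_x", "shift_y"] + (
        ["shift_z"] if particles.is_volume else [])
    table[meta_cols].to_csv(f"{prefix}_poses.tsv", sep="\t", index=False)
    table.to_csv(f"{prefix}_ground_truth.tsv", sep="\t", index=False)
    if particles.is_volume:
        for pid, vol in zip(particles.ids, particles.items):
            write_mrc(vol, f"{prefix}_{pid}.mrc")
    else:
        write_mrcs_stack(particles.items, f"{prefix}.mrcs")
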
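"""Per-particle NMMD flexible fitting with iterative PCA refinement.

Each particle (a projection image or a subtomogram) is fitted
independently: an NMMD simulation starts from the energy-minimized
reference model and evolves under the Gō force field plus the
cross-correlation biasing force toward that particle's data, with the
selected normal modes as amplified collective degrees of freedom.

For image data the conformational space obtained after one pass can be
refined: the fitted models are rigid-body aligned, a PCA of the
ensemble is computed, and its top principal component vectors replace
the normal-mode basis in the next pass (each particle restarting from
the minimized reference).  For subtomograms a single pass is used —
the extra dimension removes the difficult-view ambiguity that the
refinement addresses.

Particles are embarrassingly parallel; per-particle seeds are derived
as ``seed + particle_index`` so results do not depend on worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dynamics import SimulationParams, TrajectoryRecord, run_simulation
from .em_bias import DensityImage, DensityVolume, Pose, bias_forces, zncc
from .go_model import GoTopology, go_energy_forces
from .structure_io import AtomicModel
from .synthetic_data import ParticleSet
from . import landscape as landscape_mod

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "RefinementConfig", "fit_particle", "run_mdspace",
           "run_mdtomo", "summarize_fits", "load_pose_table", "ParticleSet"]


@dataclass
class FitResult:
    """Outcome of fitting one particle."""

    particle_id: str
    model: AtomicModel
    trajectory: TrajectoryRecord
    converged: bool = True
    failed: bool = False
    message: str = ""


@dataclass
class RefinementConfig:
    """Iterative conformational-space refinement settings."""

    n_iterations: int = 1
    n_pcs: int = 3

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be ≥ 1")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be ≥ 1")


def load_pose_table(path) -> tuple[list[str], list[Pose]]:
    """Read the tab-separated alignment table (id, rot, tilt, psi, shifts)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "rot", "tilt", "psi", "shift_x", "shift_y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    has_z = "shift_z" in df.columns
    poses = [
        Pose(rot=row.rot, tilt=row.tilt, psi=row.psi,
             shift=(row.shift_x, row.shift_y, row.shift_z) if has_z
             else (row.shift_x, row.shift_y))
        for row in df.itertuples()
    ]
    return [str(i) for i in df["id"]], poses


def fit_particle(
    start: AtomicModel,
    top: GoTopology,
    basis: np.ndarray,
    item: DensityImage | DensityVolume,
    pose: Pose,
    params: SimulationParams,
    particle_id: str = "particle",
) -> FitResult:
    """Fit one particle by a biased NMMD run from ``start``.

    Total force = Gō forces + bias forces; CC, RMSD-to-start, energy
    and mode amplitudes are recorded at the reporting interval.  A
    diverged simulation yields a result flagged ``failed`` rather than
    an exception, so batch runs continue.
    """
    sigma = params.sigma_gauss

    def force_fn(coords):
        report, f_go = go_energy_forces(top, coords)
        cc, f_bias = bias_forces(start, item, pose, params.k_bias, sigma,
                                 coords=coords)
        return report.total - params.k_bias * cc, f_go + f_bias

    def cc_fn(coords):
        from .em_bias import render_projection, render_volume, _posed_coords
        if isinstance(item, DensityImage):
            sim = render_projection(start, pose, item.pixel_size,
                                    item.data.shape[0], sigma, coords=coords)
        else:
            posed = _posed_coords(coords, pose, item.voxel_size, ndim=3)
            sim = render_volume(start, item.voxel_size, item.data.shape[0],
                                sigma, coords=posed)
        return zncc(sim, item)

    try:
        state, record = run_simulation(
            start, params, force_fn,
            basis=basis if len(basis) else None, cc_fn=cc_fn)
        final = start.with_coords(state.coords)
        return FitResult(particle_id, final, record)
    except (FloatingPointError, ValueError) as exc:
        logger.warning("fit of %s failed: %s", particle_id, exc)
        return FitResult(particle_id, start.copy(), TrajectoryRecord(),
                         converged=False, failed=True, message=str(exc))


def _fit_one(args):
    start, top, basis, item, pose, params, pid, seed = args
    p = replace(params, seed=seed)
    return fit_particle(start, top, basis, item, pose, p, particle_id=pid)


def _fit_all(particles: ParticleSet, start, top, basis, params,
             n_workers: int) -> list[FitResult]:
    jobs = [
        (start, top, basis, particles.items[i], particles.poses[i], params,
         particles.ids[i], params.seed + i)
        for i in range(len(particles))
    ]
    if n_workers == 1:
        results = [_fit_one(j) for j in jobs]
    else:
        results = Parallel(n_jobs=n_workers)(delayed(_fit_one)(j) for j in jobs)
    failed = [r.particle_id for r in results if r.failed]
    if failed:
        logger.warning("%d/%d fits failed: %s", len(failed), len(results),
                       failed[:20])
    if len(failed) == len(results):
        raise RuntimeError("all particle fits failed")
    return results


def run_mdspace(
    particles: ParticleSet,
    model: AtomicModel,
    top: GoTopology,
    modes,
    refine: RefinementConfig,
    params: SimulationParams,
    n_workers: int = 1,
) -> tuple[list[FitResult], list]:
    """Image-set fitting with iterative PCA refinement of the basis.

    Iteration 1 uses the normal modes selected by
    ``params.mode_indices``; each further iteration replaces the basis
    with the top ``refine.n_pcs`` unit-normalized principal component
    vectors of the aligned fitted ensemble and restarts every particle
    from the minimized reference model.

    Returns the final-iteration fit results and the per-iteration
    landscapes.
    """
    if particles.is_volume:
        raise ValueError("run_mdspace expects 2-D image data; "
                         "use run_mdtomo for subtomograms")
    basis = modes.select(params.mode_indices)
    landscapes = []
    results: list[FitResult] = []
    for iteration in range(refine.n_iterations):
        logger.info("refinement iteration %d/%d (basis size %d)",
                    iteration + 1, refine.n_iterations, basis.shape[0])
        results = _fit_all(particles, model, top, basis, params, n_workers)
        ok = [r for r in results if not r.failed]
        aligned = landscape_mod.align_ensemble(
            [r.model for r in ok], model)
        n_comp = min(refine.n_pcs, len(aligned) - 1, 3 * model.n_atoms)
        scape = landscape_mod.pca_landscape(aligned, n_comp)
        landscapes.append(scape)
        basis = scape.components / np.linalg.norm(
            scape.components, axis=1, keepdims=True)
    return results, landscapes


def run_mdtomo(
    subtomos: ParticleSet,
    model: AtomicModel,
    top: GoTopology,
    modes,
    params: SimulationParams,
    n_workers: int = 1,
    refine: RefinementConfig | None = None,
) -> tuple[list[FitResult], object]:
    """Subtomogram-set fitting (single pass, volumetric bias)."""
    if not subtomos.is_volume:
        raise ValueError("run_mdtomo expects 3-D subtomogram data; "
                         "use run_mdspace for images")
    if refine is not None and refine.n_iterations != 1:
        raise ValueError("subtomogram fitting supports a single refinement "
                         "iteration only (n_iterations must be 1)")
    basis = modes.select(params.mode_indices)
    results = _fit_all(subtomos, model, top, basis, params, n_workers)
    ok = [r for r in results if not r.failed]
    aligned = landscape_mod.align_ensemble([r.model for r in ok], model)
    n_comp = min(3, len(aligned) - 1, 3 * model.n_atoms)
    scape = landscape_mod.pca_landscape(aligned, n_comp)
    return results, scape


def summarize_fits(
    results: list[FitResult], selection: list[int] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-step statistics of CC/energy/RMSD across selected particles.

    Returns ``{"per_step": ..., "per_particle": ...}``: per-step mean
    and standard deviation columns over the selection, and a final-value
    table with one row per particle.
    """
    ok = [r for r in results if not r.failed and len(r.trajectory)]
    if selection is not None:
        ok = [ok[i] for i in selection]
    if not ok:
        raise ValueError("empty selection: no successful fits to summarize")
    n_steps = min(len(r.trajectory) for r in ok)
    per_step = {"time": np.asarray(ok[0].trajectory.time[:n_steps])}
    for name in ("cc", "potential", "rmsd"):
        mat = np.vstack([
            np.asarray(getattr(r.trajectory, name)[:n_steps]) for r in ok])
        per_step[f"{name}_mean"] = mat.mean(axis=0)
        per_step[f"{name}_std"] = mat.std(axis=0)
    per_particle = pd.DataFrame({
        "id": [r.particle_id for r in ok],
        "final_cc": [r.trajectory.cc[-1] for r in ok],
        "final_potential": [r.trajectory.potential[-1] for r in ok],
        "final_rmsd": [r.trajectory.rmsd[-1] for r in ok],
        "converged": [r.converged for r in ok],
    })
    return {"per_step": pd.DataFrame(per_step), "per_particle": per_particle}
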
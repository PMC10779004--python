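"""Per-particle fitting, batch orchestration and refinement contracts."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import linregress

from nmmdfit.dynamics import SimulationParams
from nmmdfit.em_bias import Pose, render_projection
from nmmdfit.fitting_pipeline import (FitResult, RefinementConfig,
                                      fit_particle, load_pose_table,
                                      run_mdspace, run_mdtomo,
                                      summarize_fits)
from nmmdfit.structure_io import rmsd
from nmmdfit.synthetic_data import (ParticleSet, identity_poses,
                                    make_heterogeneous_set,
                                    uniform_amplitudes, uniform_poses)

D, PX, SIGMA = 32, 2.0, 2.0


def short_params(**overrides):
    base = dict(sim_type="nmmd", n_steps=400, dt=0.002, nm_mass=5.0,
                k_bias=3000.0, temperature=300.0, seed=0,
                report_interval=100)
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture(scope="module")
def image_set(minimized, modes):
    from nmmdfit.synthetic_data import amplitude_for_rmsd

    a = amplitude_for_rmsd(2.0, minimized.n_atoms)
    return make_heterogeneous_set(
        minimized, modes, [7], uniform_amplitudes(-a, a), 6, "images",
        D, PX, SIGMA, 0.0, uniform_poses(), seed=5)


def test_fit_stays_near_stationary_answer(minimized, topology, mode_basis):
    """Data rendered from the start itself: the fit must not wander."""
    pose = Pose(rot=30.0, tilt=45.0, psi=10.0)
    data = render_projection(minimized, pose, PX, D, SIGMA)
    result = fit_particle(minimized, topology, mode_basis, data, pose,
                          short_params(n_steps=600))
    assert not result.failed
    assert rmsd(result.model, minimized) < 0.5


def test_unbiased_run_ignores_the_data(minimized, topology, mode_basis,
                                       modes):
    """k_bias = 0: the data exerts no pull.  The trajectory is
    bit-identical whatever image is supplied, and the CC toward a
    deformed target shows no statistically significant upward drift
    (thermal fluctuation only, 5 independent seeds)."""
    from nmmdfit.synthetic_data import amplitude_for_rmsd

    pose = Pose(rot=10.0, tilt=70.0, psi=0.0)
    amp = amplitude_for_rmsd(2.0, minimized.n_atoms)
    target = minimized.coords + (amp * mode_basis[0]).reshape(-1, 3)
    data_target = render_projection(minimized, pose, PX, D, SIGMA,
                                    coords=target)
    data_self = render_projection(minimized, pose, PX, D, SIGMA)

    a = fit_particle(minimized, topology, mode_basis, data_target, pose,
                     short_params(n_steps=200, k_bias=0.0, seed=0))
    b = fit_particle(minimized, topology, mode_basis, data_self, pose,
                     short_params(n_steps=200, k_bias=0.0, seed=0))
    np.testing.assert_array_equal(a.model.coords, b.model.coords)

    slopes = []
    for seed in range(5):
        result = fit_particle(
            minimized, topology, mode_basis, data_target, pose,
            short_params(n_steps=800, k_bias=0.0, seed=seed,
                         report_interval=25))
        t = np.asarray(result.trajectory.time)
        cc = np.asarray(result.trajectory.cc)
        slopes.append(linregress(t, cc).slope)
    slopes = np.asarray(slopes)
    # one-sided: mean slope must not be significantly positive
    half_width = 2.132 * slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert slopes.mean() <= half_width


def test_failed_particle_does_not_abort_batch(minimized, topology,
                                              mode_basis):
    pose = Pose()
    data = render_projection(minimized, pose, PX, D, SIGMA)
    # an absurd time step makes the first particle diverge
    result = fit_particle(minimized, topology, mode_basis, data, pose,
                          short_params(dt=5.0, n_steps=50))
    assert result.failed
    assert isinstance(result, FitResult)


def test_single_iteration_equals_independent_fits(minimized, topology,
                                                  modes, image_set):
    particles, _ = image_set
    subset = ParticleSet(particles.items[:2], particles.poses[:2],
                         particles.ids[:2], particles.sampling)
    params = short_params(n_steps=200)
    results, _ = run_mdspace(subset, minimized, topology, modes,
                             RefinementConfig(n_iterations=1), params)
    basis = modes.select(params.mode_indices)
    for i in range(2):
        direct = fit_particle(minimized, topology, basis,
                              subset.items[i], subset.poses[i],
                              replace(params, seed=params.seed + i))
        np.testing.assert_array_equal(results[i].model.coords,
                                      direct.model.coords)


def test_two_iterations_swap_basis_to_n_pcs(minimized, topology, modes,
                                            image_set):
    particles, _ = image_set
    results, scapes = run_mdspace(
        particles, minimized, topology, modes,
        RefinementConfig(n_iterations=2, n_pcs=3),
        short_params(n_steps=200))
    assert len(scapes) == 2
    # the basis used in iteration 2 is the top-3 PCA subspace
    assert scapes[0].components.shape == (3, 3 * minimized.n_atoms)
    assert len(results) == len(particles)


def test_worker_count_does_not_change_results(minimized, topology, modes,
                                              image_set):
    particles, _ = image_set
    subset = ParticleSet(particles.items[:2], particles.poses[:2],
                         particles.ids[:2], particles.sampling)
    params = short_params(n_steps=150)
    serial, _ = run_mdspace(subset, minimized, topology, modes,
                            RefinementConfig(), params)
    parallel, _ = run_mdspace(subset, minimized, topology, modes,
                              RefinementConfig(), params, n_workers=2)
    for a, b in zip(serial, parallel):
        np.testing.assert_array_equal(a.model.coords, b.model.coords)


def test_mdspace_rejects_volumes_and_mdtomo_rejects_images(
        minimized, topology, modes, image_set):
    particles, _ = image_set
    subs, _ = make_heterogeneous_set(
        minimized, modes, [7], uniform_amplitudes(-1, 1), 2, "subtomograms",
        24, PX, SIGMA, 0.0, identity_poses(), seed=0)
    with pytest.raises(ValueError, match="2-D"):
        run_mdspace(subs, minimized, topology, modes, RefinementConfig(),
                    short_params())
    with pytest.raises(ValueError, match="3-D"):
        run_mdtomo(particles, minimized, topology, modes, short_params())


def test_mdtomo_single_iteration_contract(minimized, topology, modes):
    subs, _ = make_heterogeneous_set(
        minimized, modes, [7], uniform_amplitudes(-1, 1), 2, "subtomograms",
        24, PX, SIGMA, 0.0, identity_poses(), seed=1)
    with pytest.raises(ValueError, match="single refinement"):
        run_mdtomo(subs, minimized, topology, modes, short_params(),
                   refine=RefinementConfig(n_iterations=2))
    results, scape = run_mdtomo(subs, minimized, topology, modes,
                                short_params(n_steps=200, k_bias=1000.0))
    assert len(results) == 2
    assert scape.method == "pca"


# ------------------------------------------------------------ summaries

def fake_result(pid, ccs, energies, rmsds):
    from nmmdfit.dynamics import TrajectoryRecord

    rec = TrajectoryRecord()
    for k, (c, e, r) in enumerate(zip(ccs, energies, rmsds)):
        rec.append(0.1 * k, e, 0.0, c, r, [])
    from nmmdfit.structure_io import AtomicModel

    model = AtomicModel(["CA"], [1], ["A"], [[0, 0, 0]])
    return FitResult(pid, model, rec)


def test_summary_single_particle_has_zero_std():
    res = [fake_result("p0", [0.1, 0.2], [5.0, 4.0], [0.0, 1.0])]
    tables = summarize_fits(res)
    assert np.all(tables["per_step"]["cc_std"] == 0)
    assert len(tables["per_particle"]) == 1


def test_summary_identical_trajectories():
    res = [fake_result(f"p{i}", [0.1, 0.3], [2.0, 1.0], [0.0, 0.5])
           for i in range(2)]
    tables = summarize_fits(res)
    np.testing.assert_array_equal(tables["per_step"]["cc_mean"], [0.1, 0.3])
    assert np.all(tables["per_step"]["cc_std"] == 0)


def test_summary_mean_matches_hand_computation():
    ccs = [[0.1, 0.4], [0.2, 0.5], [0.6, 0.9]]
    res = [fake_result(f"p{i}", c, [0.0, 0.0], [0.0, 0.0])
           for i, c in enumerate(ccs)]
    tables = summarize_fits(res)
    np.testing.assert_allclose(tables["per_step"]["cc_mean"],
                               np.mean(ccs, axis=0))
    np.testing.assert_allclose(tables["per_step"]["cc_std"],
                               np.std(ccs, axis=0))


def test_summary_empty_selection_rejected():
    res = [fake_result("p0", [0.1], [0.0], [0.0])]
    with pytest.raises(ValueError, match="empty selection"):
        summarize_fits(res, selection=[])


# ------------------------------------------------------------- metadata

def test_pose_table_roundtrip(tmp_path):
    df = pd.DataFrame({
        "id": ["a", "b"], "rot": [10.0, 20.0], "tilt": [30.0, 40.0],
        "psi": [-5.0, 5.0], "shift_x": [1.0, 0.0], "shift_y": [0.0, -1.0],
    })
    path = tmp_path / "poses.tsv"
    df.to_csv(path, sep="\t", index=False)
    ids, poses = load_pose_table(path)
    assert ids == ["a", "b"]
    assert poses[1].rot == 20.0
    assert poses[0].shift == (1.0, 0.0)


def test_pose_table_missing_column_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"id": ["a"], "rot": [0.0]}).to_csv(path, sep="\t",
                                                     index=False)
    with pytest.raises(ValueError, match="missing columns"):
        load_pose_table(path)
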
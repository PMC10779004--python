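"""Ensemble alignment, embedding, free energy, clustering and averages."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nmmdfit.em_bias import Pose, render_projection, render_volume
from nmmdfit.landscape import (ClusterAssignment, align_ensemble,
                               cluster_along_axis, cluster_averages,
                               cluster_kmeans, free_energy_map,
                               pca_landscape, trajectory_along_axis,
                               umap_landscape)
from nmmdfit.structure_io import AtomicModel, rmsd
from nmmdfit.synthetic_data import ParticleSet


# ------------------------------------------------------------- alignment

def test_rigid_copy_aligns_exactly(two_domain):
    rot = Rotation.random(random_state=0).as_matrix()
    moved = two_domain.with_coords(
        two_domain.coords @ rot.T + np.array([4.0, -7.0, 2.0]))
    aligned, = align_ensemble([moved], two_domain)
    assert rmsd(aligned, two_domain) < 1e-8


def test_alignment_preserves_internal_distances(two_domain):
    rng = np.random.default_rng(1)
    moved = two_domain.with_coords(
        two_domain.coords + rng.normal(0, 1.0, two_domain.coords.shape))
    aligned, = align_ensemble([moved], two_domain)
    from scipy.spatial.distance import pdist

    np.testing.assert_allclose(pdist(aligned.coords), pdist(moved.coords),
                               atol=1e-9)


def test_alignment_never_increases_rmsd(two_domain):
    rng = np.random.default_rng(2)
    for k in range(100):
        rot = Rotation.random(random_state=k).as_matrix()
        pert = (two_domain.coords + rng.normal(0, 0.5, two_domain.coords.shape))
        moved = two_domain.with_coords(pert @ rot.T + rng.normal(0, 3.0, 3))
        aligned, = align_ensemble([moved], two_domain)
        assert rmsd(aligned, two_domain) <= rmsd(moved, two_domain) + 1e-12


def test_alignment_idempotent(two_domain):
    rng = np.random.default_rng(3)
    moved = two_domain.with_coords(
        two_domain.coords + rng.normal(0, 0.8, two_domain.coords.shape))
    once, = align_ensemble([moved], two_domain)
    twice, = align_ensemble([once], two_domain)
    np.testing.assert_allclose(twice.coords, once.coords, atol=1e-10)


def test_alignment_needs_three_atoms(make_ca_chain):
    tiny = make_ca_chain([[0, 0, 0], [3.8, 0, 0]])
    with pytest.raises(ValueError, match="3 atoms"):
        align_ensemble([tiny], tiny)


# ------------------------------------------------------------------ PCA

def one_dimensional_ensemble(two_domain, n=20, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=3 * two_domain.n_atoms)
    v /= np.linalg.norm(v)
    models = [
        two_domain.with_coords(
            two_domain.coords + t * v.reshape(-1, 3))
        for t in np.linspace(-3, 3, n)
    ]
    return models, v


def test_pca_recovers_single_direction(two_domain):
    models, v = one_dimensional_ensemble(two_domain)
    scape = pca_landscape(models, 3)
    assert scape.explained_variance_fraction[0] > 0.999
    assert abs(scape.components[0] @ v) > 0.999


def test_pca_reconstruction_complete(two_domain):
    rng = np.random.default_rng(5)
    models = [
        two_domain.with_coords(
            two_domain.coords + rng.normal(0, 0.5, two_domain.coords.shape))
        for _ in range(6)
    ]
    scape = pca_landscape(models, 5)  # n-1 components: full basis
    for k, m in enumerate(models):
        recon = scape.mean_model + scape.coords[k] @ scape.components
        np.testing.assert_allclose(recon, m.coords.ravel(), atol=1e-8)


def test_pca_invariants(two_domain):
    models, _ = one_dimensional_ensemble(two_domain)
    rng = np.random.default_rng(6)
    models = [m.with_coords(m.coords + rng.normal(0, 0.05, m.coords.shape))
              for m in models]
    scape = pca_landscape(models, 4)
    evf = scape.explained_variance_fraction
    assert np.all(np.diff(evf) <= 1e-12)
    assert np.all((evf >= 0) & (evf <= 1))
    assert evf.sum() <= 1 + 1e-9
    np.testing.assert_allclose(scape.coords.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(scape.components @ scape.components.T,
                               np.eye(4), atol=1e-10)


def test_pca_identical_models_rejected(two_domain):
    with pytest.raises(ValueError, match="zero-variance"):
        pca_landscape([two_domain, two_domain.copy()], 1)


# ----------------------------------------------------------------- UMAP

def two_group_ensemble(two_domain, n=30, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=3 * two_domain.n_atoms)
    v /= np.linalg.norm(v)
    labels = np.array([0, 1] * (n // 2))
    models = []
    for lab in labels:
        t = (-8.0 if lab == 0 else 8.0) + rng.normal(0, 0.3)
        models.append(two_domain.with_coords(
            two_domain.coords + t * v.reshape(-1, 3)))
    return models, labels


def test_umap_deterministic_per_seed(two_domain):
    models, _ = two_group_ensemble(two_domain)
    a = umap_landscape(models, 2, seed=1)
    b = umap_landscape(models, 2, seed=1)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_umap_separates_two_conformational_groups(two_domain):
    models, labels = two_group_ensemble(two_domain)
    scape = umap_landscape(models, 2, seed=0)
    # 1-nearest-neighbor label purity
    from scipy.spatial.distance import cdist

    dist = cdist(scape.coords, scape.coords)
    np.fill_diagonal(dist, np.inf)
    nn = dist.argmin(axis=1)
    purity = (labels[nn] == labels).mean()
    assert purity >= 0.95


def test_umap_dimension_limit(two_domain):
    models, _ = two_group_ensemble(two_domain)
    with pytest.raises(ValueError, match="3"):
        umap_landscape(models, 4, seed=0)


# ---------------------------------------------------------- free energy

def test_single_occupied_bin_is_zero_rest_masked():
    # a lone point occupies one bin: ΔG = 0 there, all else masked
    dg, _ = free_energy_map(np.zeros((1, 1)), axes=[0], grid_resolution=8)
    assert dg.count() == 1
    assert dg.compressed()[0] == pytest.approx(0.0)


def test_uniform_occupancy_is_flat():
    pts = (np.arange(8) + 0.5).reshape(-1, 1)
    dg, _ = free_energy_map(pts, axes=[0], grid_resolution=8)
    assert dg.count() == 8
    np.testing.assert_allclose(dg.compressed(), 0.0, atol=1e-12)


def test_two_bin_count_ratio_gives_ln2():
    pts = np.array([[0.25]] * 10 + [[0.75]] * 5)
    dg, _ = free_energy_map(pts, axes=[0], grid_resolution=2)
    diff = dg.compressed().max() - dg.compressed().min()
    assert diff == pytest.approx(np.log(2.0), rel=1e-12)


def test_zero_extent_axis_rejected():
    pts = np.column_stack([np.zeros(5), np.arange(5.0)])
    with pytest.raises(ValueError, match="zero-extent"):
        free_energy_map(pts, axes=[0, 1])


# ------------------------------------------------------------ clustering

def test_single_cluster_along_axis():
    a = cluster_along_axis(np.random.default_rng(0).normal(size=(9, 2)),
                           axis=0, n_clusters=1)
    assert np.all(a.labels == 0)


def test_along_axis_bins():
    pts = np.array([[0.0], [1.0], [9.0], [10.0]])
    a = cluster_along_axis(pts, axis=0, n_clusters=2)
    np.testing.assert_array_equal(a.labels, [0, 0, 1, 1])


def test_along_axis_degenerate_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        cluster_along_axis(np.zeros((4, 1)), axis=0, n_clusters=2)


def test_kmeans_separated_blobs_pure():
    rng = np.random.default_rng(0)
    blob1 = rng.normal([0, 0], 0.5, size=(20, 2))
    blob2 = rng.normal([10, 10], 0.5, size=(20, 2))
    pts = np.vstack([blob1, blob2])
    a = cluster_kmeans(pts, 2, seed=0)
    assert len(set(a.labels[:20])) == 1
    assert len(set(a.labels[20:])) == 1
    assert a.labels[0] != a.labels[-1]


def test_kmeans_k_equals_n_points():
    pts = np.arange(10.0).reshape(-1, 1)
    a = cluster_kmeans(pts, 10, seed=0)
    assert len(set(a.labels)) == 10


def test_kmeans_deterministic_and_k_too_large():
    pts = np.random.default_rng(1).normal(size=(12, 2))
    a = cluster_kmeans(pts, 3, seed=5)
    b = cluster_kmeans(pts, 3, seed=5)
    np.testing.assert_array_equal(a.labels, b.labels)
    with pytest.raises(ValueError, match="exceeds"):
        cluster_kmeans(pts, 13, seed=0)


def test_label_bound_validated():
    with pytest.raises(ValueError, match="exceeds"):
        ClusterAssignment(np.array([0, 3]), 2, "kmeans")


# ----------------------------------------------------------- trajectory

def test_trajectory_frames_along_axis(two_domain):
    models, v = one_dimensional_ensemble(two_domain)
    scape = pca_landscape(models, 2)
    frames = trajectory_along_axis(scape, 0, 5, (-2.0, 2.0), two_domain)
    assert len(frames) == 5
    # midpoint frame is the mean model
    np.testing.assert_allclose(frames[2].coords.ravel(), scape.mean_model,
                               atol=1e-10)
    # projecting frames back returns the prescribed amplitudes
    for frame, a in zip(frames, np.linspace(-2, 2, 5)):
        proj = scape.components @ (frame.coords.ravel() - scape.mean_model)
        assert proj[0] == pytest.approx(a, abs=1e-8)
        np.testing.assert_allclose(proj[1:], 0.0, atol=1e-8)


def test_trajectory_axis_out_of_range(two_domain):
    models, _ = one_dimensional_ensemble(two_domain)
    scape = pca_landscape(models, 2)
    with pytest.raises(ValueError, match="axis_index"):
        trajectory_along_axis(scape, 5, 4, (-1, 1), two_domain)


# ------------------------------------------------------------- averages

def test_average_of_identical_members_is_member(two_domain):
    models = [two_domain.copy() for _ in range(4)]
    assignment = ClusterAssignment(np.zeros(4, int), 1, "kmeans")
    out = cluster_averages(models, assignment)
    np.testing.assert_allclose(out[0][0].coords, two_domain.coords,
                               atol=1e-12)


def test_subtomogram_average_of_identity_posed_volumes(two_domain):
    vol = render_volume(two_domain, 2.0, 32, 2.0)
    particles = ParticleSet([vol, vol], [Pose(shift=(0, 0, 0))] * 2,
                            ["a", "b"], 2.0)
    assignment = ClusterAssignment(np.zeros(2, int), 1, "kmeans")
    out = cluster_averages([two_domain] * 2, assignment, particles)
    np.testing.assert_allclose(out[0][1].data, vol.data, atol=1e-6)


def test_backprojection_peaks_at_point_source():
    atom = AtomicModel(["CA"], [1], ["A"], [[4.0, -2.0, 6.0]])
    rng = np.random.default_rng(1)
    images, poses = [], []
    for _ in range(60):
        quat = rng.normal(size=4)
        quat /= np.linalg.norm(quat)
        rot, tilt, psi = Rotation.from_quat(quat).as_euler("ZYZ",
                                                           degrees=True)
        pose = Pose(rot, tilt, psi)
        images.append(render_projection(atom, pose, 2.0, 32, 2.0))
        poses.append(pose)
    particles = ParticleSet(images, poses, [str(i) for i in range(60)], 2.0)
    assignment = ClusterAssignment(np.zeros(60, int), 1, "kmeans")
    out = cluster_averages([atom] * 60, assignment, particles)
    vol = out[0][1].data
    iz, iy, ix = np.unravel_index(np.argmax(vol), vol.shape)
    peak = (np.array([ix, iy, iz]) - 16) * 2.0
    assert np.abs(peak - np.array([4.0, -2.0, 6.0])).max() <= 2.0


def test_empty_cluster_skipped_with_warning(two_domain, caplog):
    import logging

    assignment = ClusterAssignment(np.zeros(2, int), 2, "kmeans")
    with caplog.at_level(logging.WARNING, logger="nmmdfit.landscape"):
        out = cluster_averages([two_domain] * 2, assignment)
    assert 1 not in out
    assert any("empty" in r.message for r in caplog.records)
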
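"""Loader atom selection, rigid-body alignment, whitening and region split."""

import numpy as np
import pandas as pd
import pytest

import ensemblediff as ed
from ensemblediff.featurize import WhiteningTransform, atom_coord_indices


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def test_loader_keeps_four_backbone_atoms_per_residue(tmp_path, toy_spec):
    dataset, flags = ed.generate_toy_ensembles(
        ed.ToyEnsembleSpec(n_frames_per_variant=5, seed=0)
    )
    paths = ed.write_toy_ensemble(tmp_path, dataset, flags)
    loaded = ed.load_ensemble(
        paths["topology"], paths["trajectories"], paths["variant_classes"]
    )
    assert loaded.n_atoms == 4 * (dataset.n_atoms // 4)
    assert sorted(set(loaded.atoms["atom_name"])) == ["C", "CA", "CB", "N"]


def test_glycine_contributes_three_atoms(tmp_path):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    for resname in ("ALA", "GLY", "ALA"):
        res = top.add_residue(resname, chain)
        names = ["N", "CA", "C", "O"] if resname == "GLY" else ["N", "CA", "CB", "C", "O"]
        for n in names:
            top.add_atom(n, md.element.carbon if n != "N" else md.element.nitrogen, res)
    xyz = np.random.default_rng(0).normal(size=(1, top.n_atoms, 3)).astype(np.float32)
    pdb = tmp_path / "gly.pdb"
    md.Trajectory(xyz, top).save_pdb(str(pdb))
    traj = tmp_path / "gly_traj.pdb"
    md.Trajectory(np.repeat(xyz, 3, axis=0), top).save_pdb(str(traj))

    loaded = ed.load_ensemble(pdb, {"v": [traj]}, {"v": 0})
    # two ALA x 4 + one GLY x 3 (no CB); carbonyl O always dropped
    assert loaded.n_atoms == 4 + 3 + 4


def test_empty_trajectory_is_a_format_error(tmp_path):
    dataset, flags = ed.generate_toy_ensembles(
        ed.ToyEnsembleSpec(n_frames_per_variant=2, seed=0)
    )
    paths = ed.write_toy_ensemble(tmp_path, dataset, flags)
    empty = tmp_path / "empty.dcd"
    empty.write_bytes(b"")
    with pytest.raises(ed.FormatError):
        ed.load_ensemble(paths["topology"], {"pos0": [empty]}, {"pos0": 1})


def test_unknown_variant_in_class_table(tmp_path):
    dataset, flags = ed.generate_toy_ensembles(
        ed.ToyEnsembleSpec(n_frames_per_variant=2, seed=0)
    )
    paths = ed.write_toy_ensemble(tmp_path, dataset, flags)
    with pytest.raises(ed.ValidationError, match="class table"):
        ed.load_ensemble(
            paths["topology"],
            {"mystery": [paths["trajectories"]["pos0"]]},
            {"pos0": 1},
        )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _make_dataset(frames, reference):
    n_atoms = reference.shape[0]
    return ed.EnsembleDataset(
        coords=frames,
        frame_variants=np.array(["v"] * frames.shape[0], dtype=object),
        variant_classes={"v": 0},
        atoms=pd.DataFrame(
            {
                "residue_index": np.arange(n_atoms) // 4,
                "residue_name": "ALA",
                "atom_name": (["N", "CA", "CB", "C"] * n_atoms)[:n_atoms],
            }
        ),
        reference=reference,
    )


def _rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def test_alignment_recovers_rigid_transform_exactly():
    ref = ed.template_coordinates(4)
    frame = (ref - ref.mean(axis=0)) @ _rotation_z(np.pi / 2).T + np.array([1.0, 1.0, 1.0])
    aligned = ed.align_to_reference(_make_dataset(frame[None], ref))
    rmsd = np.sqrt(((aligned.coords[0] - aligned.reference) ** 2).sum(axis=1).mean())
    assert rmsd <= 1e-9


def test_alignment_is_idempotent_and_distance_preserving():
    rng = np.random.default_rng(1)
    ref = ed.template_coordinates(4)
    frames = ref[None] + rng.normal(0, 0.1, size=(5, *ref.shape))
    once = ed.align_to_reference(_make_dataset(frames, ref))
    twice = ed.align_to_reference(once)
    assert np.allclose(once.coords, twice.coords, atol=1e-9)
    # rigid-body: intra-frame pairwise distances unchanged
    def pdists(x):
        return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    for before, after in zip(frames, once.coords):
        assert np.allclose(pdists(before), pdists(after), atol=1e-9)


def test_alignment_is_optimal_against_rotation_grid():
    """The closed-form superposition beats every rotation on a coarse grid
    (least-squares optimality, brute-force oracle on a 4-atom toy)."""
    rng = np.random.default_rng(2)
    ref = np.array(
        [[0.0, 0, 0], [0.4, 0, 0], [0.4, 0.4, 0], [0.1, 0.2, 0.5]]
    )
    ref -= ref.mean(axis=0)
    frame = ref + rng.normal(0, 0.08, size=ref.shape)
    aligned = ed.align_to_reference(_make_dataset(frame[None], ref))
    best = np.sqrt(((aligned.coords[0] - ref) ** 2).sum(axis=1).mean())

    centered = frame - frame.mean(axis=0)
    angles = np.linspace(0, 2 * np.pi, 25, endpoint=False)
    grid_best = np.inf
    from scipy.spatial.transform import Rotation

    for a in angles:
        for b in angles:
            for c in angles[:13]:
                rot = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                rmsd = np.sqrt(((centered @ rot.T - ref) ** 2).sum(axis=1).mean())
                grid_best = min(grid_best, rmsd)
    assert best <= grid_best + 1e-12


def test_degenerate_geometry_raises():
    ref = np.zeros((4, 3))
    ref[:, 0] = np.arange(4)  # collinear
    with pytest.raises(ed.DegenerateGeometryError):
        ed.align_to_reference(_make_dataset(ref[None].copy(), ref))


# ---------------------------------------------------------------------------
# Whitening
# ---------------------------------------------------------------------------

def test_whitening_of_whitened_data_is_identity():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(400, 6)) @ rng.normal(size=(6, 6))
    t1 = ed.fit_whitening(x)
    whitened = t1.apply(x)
    t2 = ed.fit_whitening(whitened)
    assert np.abs(t2.whitening_matrix - np.eye(6)).max() <= 1e-6
    assert np.abs(t2.mean_vector).max() <= 1e-10


def test_one_dimensional_scale_is_closed_form():
    x = np.array([[-2.0], [2.0]])  # biased sample variance 4
    t = ed.fit_whitening(x)
    assert t.whitening_matrix[0, 0] == pytest.approx(0.5, abs=1e-12)
    assert t.unwhitening_matrix[0, 0] == pytest.approx(2.0, abs=1e-12)


def test_rank_deficient_data_round_trips_on_retained_subspace():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(10, 30))  # fewer frames than coordinates
    t = ed.fit_whitening(x)
    assert t.retained_rank <= 9
    w = t.apply(x)
    # projection onto retained subspace is reproduced through the round trip
    assert np.allclose(t.apply(t.inverse(w)), w, atol=1e-8)


def test_whitened_training_data_has_identity_covariance(toy_data):
    dataset, _ = toy_data
    x = dataset.flat_coords()
    t = ed.fit_whitening(x)
    w = t.apply(x)
    assert np.abs(w.mean(axis=0)).max() <= 1e-6
    cov = w.T @ w / w.shape[0]
    evals = np.linalg.eigvalsh(cov)
    keep = evals > 0.5  # retained directions have unit variance, dropped ~0
    assert np.allclose(evals[keep], 1.0, atol=1e-5)
    assert int(keep.sum()) == t.retained_rank


def test_mean_maps_to_zero_and_round_trip(toy_data):
    dataset, _ = toy_data
    x = dataset.flat_coords()
    t = ed.fit_whitening(x)
    assert np.abs(t.apply(t.mean_vector)).max() <= 1e-9
    sample = x[:50]
    back = t.inverse(t.apply(sample))
    assert np.abs(back - sample).max() <= 1e-5
    with pytest.raises(ed.ValidationError):
        t.apply(sample[:, :10])


def test_fit_whitening_requires_two_frames():
    with pytest.raises(ed.ValidationError):
        ed.fit_whitening(np.zeros((1, 6)))


def test_restricted_transform_whitens_the_marginal(toy_data):
    dataset, _ = toy_data
    x = dataset.flat_coords()
    t = ed.fit_whitening(x)
    idx = atom_coord_indices([3, 4, 10])
    sub = t.restrict(idx)
    w = sub.apply(x[:, idx])
    cov = (w - w.mean(axis=0)).T @ (w - w.mean(axis=0)) / w.shape[0]
    evals = np.linalg.eigvalsh(cov)
    assert np.allclose(evals[evals > 0.5], 1.0, atol=1e-5)


# ---------------------------------------------------------------------------
# Region split
# ---------------------------------------------------------------------------

def test_split_partitions_all_atoms(toy_data, toy_region):
    dataset, _ = toy_data
    a, b = toy_region.encoder_a_atoms, toy_region.encoder_b_atoms
    assert a.size + b.size == dataset.n_atoms
    assert np.intersect1d(a, b).size == 0


def test_feature_pair_lies_in_encoder_a(toy_data, toy_region, toy_spec):
    assert set(toy_spec.feature_atom_pair) <= set(toy_region.encoder_a_atoms.tolist())


def test_zero_cutoff_selects_only_target_residue(toy_data):
    dataset, _ = toy_data
    region = ed.split_region(dataset, 15, cutoff=0.0)
    expected = np.flatnonzero(dataset.atoms["residue_index"].to_numpy() == 15)
    assert np.array_equal(np.sort(region.encoder_a_atoms), expected)


def test_oversized_cutoff_suggests_unsplit_architecture(toy_data):
    dataset, _ = toy_data
    with pytest.raises(ed.ValidationError, match="unsplit"):
        ed.split_region(dataset, 15, cutoff=1e6)


def test_missing_target_residue(toy_data):
    dataset, _ = toy_data
    with pytest.raises(ed.ValidationError, match="residue"):
        ed.split_region(dataset, 999)
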
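"""Interpretation analyses: state labeling, frozen-latent ROC, clustering,
distance-correlation attribution, binned profiles, held-out prediction."""

import numpy as np
import pandas as pd
import pytest

import ensemblediff as ed
from ensemblediff.interpret import _nearest


# ---------------------------------------------------------------------------
# Compact-state labeling (all hydrogen bonds below threshold, strictly)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "distances, expected",
    [
        ((4.0, 4.1, 4.19), "compact"),
        ((4.0, 4.3, 4.0), "extended"),
        ((4.2, 4.2, 4.2), "extended"),  # strict inequality at the threshold
    ],
)
def test_label_compact_state(distances, expected):
    assert ed.label_compact_state(distances) == expected


def test_label_compact_state_rejects_negative_distance():
    with pytest.raises(ed.ValidationError):
        ed.label_compact_state((4.0, -1.0, 4.0))


# ---------------------------------------------------------------------------
# Frozen-latent ROC
# ---------------------------------------------------------------------------

def test_perfectly_separated_latents_give_auc_one():
    y = np.array([0] * 50 + [1] * 50)
    z = np.where(y, 5.0, -5.0)[:, None] + np.random.default_rng(0).normal(
        0, 0.1, size=(100, 1)
    )
    roc = ed.frozen_latent_roc(z, y, seed=0)
    assert np.allclose(roc.fold_aucs, 1.0)
    negated = ed.frozen_latent_roc(-z, y, seed=0)
    assert np.allclose(negated.fold_aucs, 1.0)  # logistic regression flips sign


def test_permuted_labels_give_chance_auc():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(2000, 3))
    y = rng.permutation(np.array([0, 1] * 1000))
    roc = ed.frozen_latent_roc(z, y, seed=1)
    assert abs(roc.mean_auc - 0.5) <= 0.1


def test_single_class_input_rejected():
    with pytest.raises(ed.ValidationError):
        ed.frozen_latent_roc(np.zeros((10, 2)), np.ones(10))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_k_equals_n_makes_every_frame_a_center():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(40, 5))
    centers, assign = ed.cluster_conformations(x, k=40, seed=0)
    assert sorted(centers.tolist()) == list(range(40))
    assert np.array_equal(centers[assign], np.arange(40))  # each frame is its own center


def test_k_one_finds_the_true_medoid():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(150, 4))
    centers, assign = ed.cluster_conformations(x, k=1, seed=0)
    from scipy.spatial.distance import cdist

    totals = cdist(x, x).sum(axis=1)
    assert centers[0] == int(totals.argmin())  # brute-force medoid oracle
    assert np.all(assign == 0)


def test_cluster_radius_non_increasing_with_k():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(300, 6))
    radii = []
    for k in (5, 20, 80):
        centers, assign = ed.cluster_conformations(x, k=k, seed=0)
        _, dist = _nearest(x, x[centers])
        radii.append(dist.max())
    assert radii[0] >= radii[1] >= radii[2]


def test_assignments_map_to_nearest_center():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(200, 4))
    centers, assign = ed.cluster_conformations(x, k=12, seed=1)
    expected, _ = _nearest(x, x[centers])
    assert np.array_equal(assign, expected)


def test_k_larger_than_n_rejected_and_determinism():
    x = np.random.default_rng(6).normal(size=(30, 3))
    with pytest.raises(ed.ValidationError):
        ed.cluster_conformations(x, k=31)
    a = ed.cluster_conformations(x, k=5, seed=7)
    b = ed.cluster_conformations(x, k=5, seed=7)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# Distance-correlation scan
# ---------------------------------------------------------------------------

def _toy_centers(n_centers=30, n_atoms=6, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n_centers, n_atoms, 3))
    atoms = pd.DataFrame(
        {
            "residue_index": np.arange(n_atoms),  # all different residues
            "residue_name": "ALA",
            "atom_name": "CA",
        }
    )
    return coords, atoms


def test_label_equal_to_pair_distance_ranks_first():
    coords, atoms = _toy_centers()
    labels = np.linalg.norm(coords[:, 0] - coords[:, 1], axis=1)
    report = ed.distance_correlation_scan(
        coords, np.arange(6), labels, ("top_n", 3), atoms
    )
    top = report.records.iloc[0]
    assert (top.atom_i, top.atom_j) == (0, 1)
    assert top.pearson_r == pytest.approx(1.0, abs=1e-12)
    assert top.direction == "expanding"


def test_zero_variance_pairs_are_skipped():
    coords, atoms = _toy_centers()
    coords[:, 2] = coords[:, 3] + np.array([1.0, 0, 0])  # constant pair distance
    labels = np.random.default_rng(1).random(coords.shape[0])
    report = ed.distance_correlation_scan(
        coords, np.arange(6), labels, ("top_percent", 100.0), atoms
    )
    assert report.n_pairs_skipped == 1
    assert len(report.records) == report.n_pairs_scored
    pairs = set(zip(report.records.atom_i, report.records.atom_j))
    assert (2, 3) not in pairs


def test_same_residue_pairs_excluded():
    coords, atoms = _toy_centers()
    atoms.loc[:2, "residue_index"] = 0  # atoms 0-2 share a residue
    labels = np.random.default_rng(2).random(coords.shape[0])
    report = ed.distance_correlation_scan(
        coords, np.arange(6), labels, ("top_percent", 100.0), atoms
    )
    assert report.n_pairs_enumerated == 15 - 3  # minus the 3 intra-residue pairs


def test_perfect_anticorrelation_is_contracting():
    coords, atoms = _toy_centers()
    labels = -np.linalg.norm(coords[:, 4] - coords[:, 5], axis=1)
    labels = (labels - labels.min()) / (labels.max() - labels.min())
    report = ed.distance_correlation_scan(
        coords, np.arange(6), labels, ("top_n", 1), atoms
    )
    top = report.records.iloc[0]
    assert (top.atom_i, top.atom_j) == (4, 5)
    assert top.pearson_r == pytest.approx(-1.0, abs=1e-12)
    assert top.direction == "contracting"


def test_scan_preconditions():
    coords, atoms = _toy_centers(n_centers=2)
    with pytest.raises(ed.ValidationError, match="centers"):
        ed.distance_correlation_scan(coords, np.arange(6), np.zeros(2))
    coords, atoms = _toy_centers()
    with pytest.raises(ed.ValidationError, match="2 atoms"):
        ed.distance_correlation_scan(coords, np.array([0]), np.zeros(30))


# ---------------------------------------------------------------------------
# Label-binned profiles
# ---------------------------------------------------------------------------

def test_single_bin_population():
    profile = ed.label_binned_profile(np.full(20, 0.05), np.ones(20))
    assert profile.loc[0, "count"] == 20
    assert profile.loc[1:, "count"].sum() == 0
    assert profile.loc[1:, "mean_distance"].isna().all()


def test_monotone_construction_gives_increasing_bin_means():
    rng = np.random.default_rng(3)
    d = np.sort(rng.uniform(1.0, 5.0, size=500))
    labels = (d - d.min()) / (d.max() - d.min())
    profile = ed.label_binned_profile(labels, d)
    means = profile["mean_distance"].dropna().to_numpy()
    assert np.all(np.diff(means) > 0)


def test_labels_outside_unit_interval_rejected():
    with pytest.raises(ed.ValidationError):
        ed.label_binned_profile(np.array([1.5]), np.array([1.0]))


# ---------------------------------------------------------------------------
# Held-out prediction
# ---------------------------------------------------------------------------

def test_prediction_reproduces_model_outputs(toy_data, toy_region, tmp_path):
    dataset, _ = toy_data
    spec = ed.ArchitectureSpec.for_split(toy_region, 8, seed=0)
    res = ed.run_training(
        dataset, spec, ed.TrainingConfig(epochs_per_stage=1), region=toy_region
    )
    report = ed.predict_new_variant(res.params, dataset)
    _, _, y_direct = ed.forward(res.params, ed.align_to_reference(dataset).coords)
    assert np.allclose(report.labels, y_direct, atol=1e-10)
    # round trip through a checkpoint file gives identical labels
    path = tmp_path / "m.npz"
    ed.save_checkpoint(res.params, path)
    again = ed.predict_new_variant(path, dataset)
    assert np.array_equal(report.labels, again.labels)


def test_prediction_atom_mismatch_rejected(toy_data, toy_region):
    dataset, _ = toy_data
    spec = ed.ArchitectureSpec.for_split(toy_region, 8, seed=0)
    res = ed.run_training(
        dataset, spec, ed.TrainingConfig(epochs_per_stage=1), region=toy_region
    )
    small = dataset.take(np.arange(10))
    import dataclasses

    broken = dataclasses.replace(
        small,
        coords=small.coords[:, :100],
        reference=small.reference[:100],
        atoms=small.atoms.iloc[:100],
    )
    with pytest.raises(ed.ValidationError, match="atoms"):
        ed.predict_new_variant(res.params, broken)


def test_extrapolating_input_triggers_dominant_warning(toy_data, toy_region):
    dataset, _ = toy_data
    spec = ed.ArchitectureSpec.for_split(toy_region, 8, seed=0)
    res = ed.run_training(
        dataset, spec, ed.TrainingConfig(epochs_per_stage=1), region=toy_region
    )
    import dataclasses

    far = dataclasses.replace(
        dataset.take(np.arange(20)),
        coords=dataset.coords[:20] * 5.0,  # far outside the training ensemble
    )
    report = ed.predict_new_variant(res.params, far)
    assert report.summary["extrapolation_warning"]
    assert report.summary["fraction_extrapolating"] > 0.5
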
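"""Synthetic two-class conformational ensembles with a planted subtle feature.

Emulates the setting where two classes of protein variants have heavily
overlapping structural ensembles distinguished only by a shift in the
probability of a geometrically subtle feature — a sub-Ångstrom change in one
pairwise distance — superimposed on a large-amplitude nuisance motion (a
floppy-loop collective mode) and isotropic thermal jitter.

The template is a regular zig-zag chain of pseudo-residues, each carrying
four points named N, CA, CB, C at protein-like spacings, so the backbone
atom-name filters of :mod:`ensemblediff.featurize` apply unchanged.

Frames are i.i.d. draws (no temporal autocorrelation): each frame picks its
compact/extended state from the class probability, places the feature atom
pair at exactly the corresponding distance, translates the nuisance atom set
along a fixed random unit direction by a Gaussian per-frame coefficient, and
finally adds isotropic thermal noise to every coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .featurize import EnsembleDataset

ATOM_NAMES = ("N", "CA", "CB", "C")
ATOMS_PER_RESIDUE = len(ATOM_NAMES)

#: Residue whose neighbourhood contains the planted feature; the natural
#: target for :func:`ensemblediff.featurize.split_region` on this fixture.
DEFAULT_TARGET_RESIDUE = 15


def _default_feature_pair() -> tuple:
    # CB atoms of residues 14 and 15 (0-based); CB is atom 2 within a residue
    return (14 * ATOMS_PER_RESIDUE + 2, 15 * ATOMS_PER_RESIDUE + 2)


def _default_nuisance_atoms() -> np.ndarray:
    # a 5-residue "loop" adjacent to the feature region (residues 17-21)
    return np.arange(17 * ATOMS_PER_RESIDUE, 22 * ATOMS_PER_RESIDUE)


@dataclass(frozen=True)
class ToyEnsembleSpec:
    """Study conditions for the synthetic fixture.

    Defaults are sized for desk-scale runs: a 30-residue chain (120 atoms),
    2 variants per class with 4000 frames each, a 0.50 nm vs 0.58 nm feature
    distance (a 0.8 Å shift) against a 0.5 nm RMS nuisance mode on a
    5-residue loop, and 0.02 nm thermal jitter per coordinate.
    """

    n_atoms: int = 120
    n_variants_per_class: int = 2
    n_frames_per_variant: int = 4000
    feature_atom_pair: tuple = field(default_factory=_default_feature_pair)
    compact_distance: float = 0.50  # nm
    extended_distance: float = 0.58  # nm
    p_compact_positive: float = 0.75
    p_compact_negative: float = 0.25
    nuisance_atom_set: np.ndarray = field(default_factory=_default_nuisance_atoms)
    nuisance_amplitude: float = 0.5  # nm RMS displacement of the loop mode
    thermal_sigma: float = 0.02  # nm per coordinate
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return self.n_atoms // ATOMS_PER_RESIDUE

    def validate(self) -> None:
        if self.n_atoms <= 0 or self.n_atoms % ATOMS_PER_RESIDUE != 0:
            raise ValidationError(
                "n_atoms must be a positive multiple of 4 (residues carry N, CA, CB, C)"
            )
        for name in ("n_variants_per_class", "n_frames_per_variant"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.p_compact_negative < self.p_compact_positive <= 1.0:
            raise ValidationError(
                "require 0 <= p_compact_negative < p_compact_positive <= 1"
            )
        if not abs(self.extended_distance - self.compact_distance) < self.nuisance_amplitude:
            raise ValidationError(
                "|extended_distance - compact_distance| must be < nuisance_amplitude "
                "(the planted feature must be subtle relative to nuisance motion)"
            )
        i, j = self.feature_atom_pair
        for k in (i, j):
            if not 0 <= k < self.n_atoms:
                raise ValidationError("feature_atom_pair indices out of range")
        if i == j:
            raise ValidationError("feature_atom_pair atoms must differ")
        nuis = np.asarray(self.nuisance_atom_set, dtype=int)
        if nuis.size and (nuis.min() < 0 or nuis.max() >= self.n_atoms):
            raise ValidationError("nuisance_atom_set indices out of range")
        if self.thermal_sigma < 0 or self.nuisance_amplitude < 0:
            raise ValidationError("noise amplitudes must be nonnegative")


def template_coordinates(n_residues: int) -> np.ndarray:
    """Zig-zag pseudo-backbone template, (4 * n_residues, 3) in nm.

    Residues are spaced 0.38 nm along x with alternating y displacement; the
    four points per residue sit at protein-like offsets from CA.
    """
    coords = np.empty((n_residues * ATOMS_PER_RESIDUE, 3))
    for r in range(n_residues):
        s = 1.0 if r % 2 == 0 else -1.0
        ca = np.array([0.38 * r, 0.13 * s, 0.0])
        offsets = {
            "N": np.array([-0.147, 0.045 * s, 0.020]),
            "CA": np.zeros(3),
            "CB": np.array([0.0, -0.110 * s, 0.120]),
            "C": np.array([0.147, 0.045 * s, -0.020]),
        }
        for a, name in enumerate(ATOM_NAMES):
            coords[r * ATOMS_PER_RESIDUE + a] = ca + offsets[name]
    return coords


def _atom_table(n_residues: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_index": np.repeat(np.arange(n_residues), ATOMS_PER_RESIDUE),
            "residue_name": ["ALA"] * (n_residues * ATOMS_PER_RESIDUE),
            "atom_name": list(ATOM_NAMES) * n_residues,
        }
    )


def generate_toy_ensembles(spec: ToyEnsembleSpec):
    """Generate the two-class toy ensembles plus per-frame ground truth.

    Returns
    -------
    dataset : EnsembleDataset
        Frames for ``2 * n_variants_per_class`` variants named ``pos<i>`` /
        ``neg<i>`` with class labels 1 / 0.
    compact_flags : (n_frames,) bool array
        True where the frame was drawn in the compact state.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = template_coordinates(spec.n_residues)
    i, j = spec.feature_atom_pair
    midpoint = 0.5 * (template[i] + template[j])
    axis = template[j] - template[i]
    axis = axis / np.linalg.norm(axis)
    nuis = np.asarray(spec.nuisance_atom_set, dtype=int)
    # one rigid collective mode: a fixed random translation direction
    mode = rng.normal(size=3)
    mode /= np.linalg.norm(mode)

    variants = [(f"pos{k}", 1) for k in range(spec.n_variants_per_class)] + [
        (f"neg{k}", 0) for k in range(spec.n_variants_per_class)
    ]
    n_total = len(variants) * spec.n_frames_per_variant
    coords = np.empty((n_total, spec.n_atoms, 3))
    frame_variants = np.empty(n_total, dtype=object)
    flags = np.empty(n_total, dtype=bool)

    row = 0
    for name, cls in variants:
        p = spec.p_compact_positive if cls == 1 else spec.p_compact_negative
        nf = spec.n_frames_per_variant
        compact = rng.random(nf) < p
        coeff = rng.normal(0.0, spec.nuisance_amplitude, size=nf)
        noise = rng.normal(0.0, spec.thermal_sigma, size=(nf, spec.n_atoms, 3))
        block = np.broadcast_to(template, (nf, spec.n_atoms, 3)).copy()
        if nuis.size:
            block[:, nuis, :] += coeff[:, None, None] * mode
        d = np.where(compact, spec.compact_distance, spec.extended_distance)
        block[:, i, :] = midpoint - 0.5 * d[:, None] * axis
        block[:, j, :] = midpoint + 0.5 * d[:, None] * axis
        block += noise
        coords[row : row + nf] = block
        frame_variants[row : row + nf] = name
        flags[row : row + nf] = compact
        row += nf

    dataset = EnsembleDataset(
        coords=coords,
        frame_variants=frame_variants,
        variant_classes={name: cls for name, cls in variants},
        atoms=_atom_table(spec.n_residues),
        reference=template,
    )
    return dataset, flags


def feature_pair_distances(
    dataset: EnsembleDataset, pair: tuple
) -> np.ndarray:
    """Per-frame distance (nm) of an atom pair."""
    i, j = pair
    return np.linalg.norm(dataset.coords[:, i, :] - dataset.coords[:, j, :], axis=1)


def write_toy_ensemble(directory, dataset: EnsembleDataset, compact_flags) -> dict:
    """Write one reference PDB, one DCD per variant, and a ground-truth table.

    Returns a manifest of written paths.
    """
    import mdtraj as md

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    top = md.Topology()
    chain = top.add_chain()
    carbon = md.element.carbon
    nitrogen = md.element.nitrogen
    n_residues = dataset.n_atoms // ATOMS_PER_RESIDUE
    for r in range(n_residues):
        res = top.add_residue("ALA", chain)
        for name in ATOM_NAMES:
            top.add_atom(name, nitrogen if name == "N" else carbon, res)

    paths = {}
    ref = md.Trajectory(dataset.reference[None].astype(np.float32), top)
    pdb_path = directory / "reference.pdb"
    ref.save_pdb(str(pdb_path))
    paths["topology"] = str(pdb_path)

    paths["trajectories"] = {}
    for variant in dict.fromkeys(dataset.frame_variants):  # insertion order
        mask = dataset.frame_variants == variant
        traj = md.Trajectory(dataset.coords[mask].astype(np.float32), top)
        dcd_path = directory / f"{variant}.dcd"
        traj.save_dcd(str(dcd_path))
        paths["trajectories"][str(variant)] = str(dcd_path)

    truth = pd.DataFrame(
        {
            "frame": np.arange(dataset.n_frames),
            "variant": dataset.frame_variants,
            "class": dataset.frame_classes,
            "compact_flag": np.asarray(compact_flags, dtype=int),
        }
    )
    truth_path = directory / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = str(truth_path)

    classes = pd.DataFrame(
        sorted(dataset.variant_classes.items()), columns=["variant_id", "class"]
    )
    class_path = directory / "variant_classes.csv"
    classes.to_csv(class_path, index=False)
    paths["variant_classes"] = str(class_path)
    return paths
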
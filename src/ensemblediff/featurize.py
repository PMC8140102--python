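"""Trajectory loading, alignment, and coordinate whitening.

The feature vector of a simulation frame is the flattened XYZ coordinates
(nm) of the protein backbone without carbonyl oxygens (atom names C, CA, CB,
N), rigid-body superposed onto an origin-centered reference structure.
Whitening mean-shifts the pooled coordinates to zero and multiplies by the
inverse square root of their pooled covariance, so the network trains on
decorrelated, unit-variance inputs.

Internal length unit is nm throughout; Ångstroms appear only at reporting
boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, FormatError, ValidationError

BACKBONE_ATOM_NAMES = ("C", "CA", "CB", "N")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class EnsembleDataset:
    """Aligned backbone coordinates for a set of variant ensembles.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, nm
    frame_variants : (n_frames,) array of variant ids (strings)
    variant_classes : mapping variant id -> binary class label {0, 1}
    atoms : DataFrame with columns residue_index, residue_name, atom_name
    reference : (n_atoms, 3) float array, nm
    """

    coords: np.ndarray
    frame_variants: np.ndarray
    variant_classes: dict
    atoms: pd.DataFrame
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.frame_variants = np.asarray(self.frame_variants)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if len(self.frame_variants) != self.coords.shape[0]:
            raise ValidationError("one variant id required per frame")
        if self.reference.shape != self.coords.shape[1:]:
            raise ValidationError("reference shape must match frame shape")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValidationError("atom table length must match atom count")
        unknown = set(np.unique(self.frame_variants)) - set(self.variant_classes)
        if unknown:
            raise ValidationError(f"variants missing from class table: {sorted(unknown)}")
        for v, c in self.variant_classes.items():
            if c not in (0, 1):
                raise ValidationError(f"class label for {v!r} must be 0 or 1, got {c!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_classes(self) -> np.ndarray:
        """Binary class label per frame, inherited from the frame's variant."""
        return np.array([self.variant_classes[v] for v in self.frame_variants])

    def flat_coords(self) -> np.ndarray:
        """Frames as (n_frames, 3 * n_atoms) feature vectors."""
        return self.coords.reshape(self.n_frames, -1)

    def take(self, frame_indices: np.ndarray) -> "EnsembleDataset":
        idx = np.asarray(frame_indices)
        return replace(
            self,
            coords=self.coords[idx],
            frame_variants=self.frame_variants[idx],
        )


def atom_coord_indices(atom_indices: Sequence[int]) -> np.ndarray:
    """Expand atom indices to flattened xyz coordinate indices."""
    a = np.asarray(atom_indices, dtype=int)
    return (3 * a[:, None] + np.arange(3)).ravel()


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_variant_class_table(path) -> dict:
    """Read a delimited text table with columns (variant_id, class)."""
    table = pd.read_csv(path)
    if "variant_id" not in table.columns or "class" not in table.columns:
        # fall back to positional two-column format without header
        table = pd.read_csv(path, header=None, names=["variant_id", "class"])
    return {str(r.variant_id): int(r["class"]) for _, r in table.iterrows()}


def load_ensemble(
    topology_file,
    trajectory_files: Mapping[str, Sequence],
    variant_class_table,
    stride: int | None = None,
) -> EnsembleDataset:
    """Load variant trajectories, keeping C/CA/CB/N atoms in topology order.

    Parameters
    ----------
    topology_file : PDB file also serving as the reference structure.
    trajectory_files : mapping variant id -> trajectory path(s) (DCD/XTC/PDB).
    variant_class_table : mapping variant id -> class, or a delimited-text
        file with columns (variant_id, class).
    stride : keep every ``stride``-th frame (the conventional subsampling for
        large MD datasets); ``None`` keeps every frame.
    """
    import mdtraj as md

    if isinstance(variant_class_table, (str, Path)):
        classes = read_variant_class_table(variant_class_table)
    else:
        classes = {str(k): int(v) for k, v in variant_class_table.items()}
    unknown = set(map(str, trajectory_files)) - set(classes)
    if unknown:
        raise ValidationError(f"variants not in class table: {sorted(unknown)}")

    ref = md.load(str(topology_file))
    sel = ref.topology.select(" or ".join(f"name {n}" for n in BACKBONE_ATOM_NAMES))
    if sel.size == 0:
        raise FormatError("topology contains no C/CA/CB/N atoms")
    top_atoms = [ref.topology.atom(int(i)) for i in sel]
    atoms = pd.DataFrame(
        {
            "residue_index": [a.residue.index for a in top_atoms],
            "residue_name": [a.residue.name for a in top_atoms],
            "atom_name": [a.name for a in top_atoms],
        }
    )

    chunks, variants = [], []
    for variant, paths in trajectory_files.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for path in paths:
            try:
                traj = md.load(str(path), top=str(topology_file), stride=stride)
            except Exception as exc:  # mdtraj raises assorted IO errors
                raise FormatError(f"could not read trajectory {path}: {exc}") from exc
            if traj.n_frames == 0:
                raise FormatError(f"trajectory {path} contains no frames")
            if traj.n_atoms != ref.n_atoms:
                raise FormatError(
                    f"trajectory {path} has {traj.n_atoms} atoms, "
                    f"topology has {ref.n_atoms}"
                )
            chunks.append(traj.xyz[:, sel, :].astype(np.float64))
            variants.extend([str(variant)] * traj.n_frames)

    if not chunks:
        raise FormatError("no trajectories given")
    return EnsembleDataset(
        coords=np.concatenate(chunks, axis=0),
        frame_variants=np.array(variants, dtype=object),
        variant_classes=classes,
        atoms=atoms,
        reference=ref.xyz[0, sel, :].astype(np.float64),
    )


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def _kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal (least-squares, proper) rotation aligning centered mobile
    coordinates onto centered target coordinates."""
    h = mobile.T @ target
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "coordinates are collinear or coincident; rotation is ill-defined"
        )
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def align_to_reference(dataset: EnsembleDataset) -> EnsembleDataset:
    """Superpose every frame onto the origin-centered reference.

    Uses the standard SVD solution of the orthogonal Procrustes problem with
    uniform weights over all selected backbone atoms. Idempotent.
    """
    ref = dataset.reference - dataset.reference.mean(axis=0)
    aligned = np.empty_like(dataset.coords)
    for i, frame in enumerate(dataset.coords):
        centered = frame - frame.mean(axis=0)
        rot = _kabsch_rotation(centered, ref)
        aligned[i] = centered @ rot
    return replace(dataset, coords=aligned, reference=ref)


# ---------------------------------------------------------------------------
# Whitening (mean shift + inverse square root of the pooled covariance)
# ---------------------------------------------------------------------------

@dataclass
class WhiteningTransform:
    """Mean vector and (un)whitening matrices fit on pooled training frames.

    ``whitening_matrix`` is :math:`C_{00}^{-1/2}` and ``unwhitening_matrix``
    :math:`C_{00}^{1/2}`, both symmetric PSD, computed by eigendecomposition
    with eigenvalues below ``eigenvalue_floor`` excluded (pseudo-inverse on
    the retained subspace).
    """

    mean_vector: np.ndarray
    covariance: np.ndarray
    whitening_matrix: np.ndarray
    unwhitening_matrix: np.ndarray
    retained_rank: int
    eigenvalue_floor: float

    @property
    def n_dim(self) -> int:
        return self.mean_vector.size

    @classmethod
    def from_moments(
        cls, mean: np.ndarray, cov: np.ndarray, eigenvalue_floor: float = 1e-8
    ) -> "WhiteningTransform":
        evals, evecs = np.linalg.eigh(cov)
        keep = evals > eigenvalue_floor
        v = evecs[:, keep]
        inv_sqrt = (v / np.sqrt(evals[keep])) @ v.T
        sqrt = (v * np.sqrt(evals[keep])) @ v.T
        return cls(
            mean_vector=np.asarray(mean, dtype=np.float64),
            covariance=np.asarray(cov, dtype=np.float64),
            whitening_matrix=inv_sqrt,
            unwhitening_matrix=sqrt,
            retained_rank=int(keep.sum()),
            eigenvalue_floor=float(eigenvalue_floor),
        )

    def restrict(self, coord_indices: np.ndarray) -> "WhiteningTransform":
        """Whitening of the marginal distribution of a coordinate subset.

        The sub-transform is refit from the principal submatrix of the pooled
        covariance so the restricted whitened features again have identity
        covariance (a submatrix of the full inverse square root would not).
        """
        idx = np.asarray(coord_indices, dtype=int)
        return WhiteningTransform.from_moments(
            self.mean_vector[idx],
            self.covariance[np.ix_(idx, idx)],
            self.eigenvalue_floor,
        )

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.n_dim:
            raise ValidationError(
                f"expected {self.n_dim} coordinates, got {x.shape[-1]}"
            )
        return (x - self.mean_vector) @ self.whitening_matrix

    def inverse(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[-1] != self.n_dim:
            raise ValidationError(
                f"expected {self.n_dim} features, got {features.shape[-1]}"
            )
        return features @ self.unwhitening_matrix + self.mean_vector

    def save(self, path) -> None:
        path = Path(path)
        np.savez(
            path,
            mean_vector=self.mean_vector,
            covariance=self.covariance,
            whitening_matrix=self.whitening_matrix,
            unwhitening_matrix=self.unwhitening_matrix,
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "units": "nm",
                    "retained_rank": self.retained_rank,
                    "eigenvalue_floor": self.eigenvalue_floor,
                    "n_dim": int(self.n_dim),
                }
            )
        )

    @classmethod
    def load(cls, path) -> "WhiteningTransform":
        path = Path(path)
        arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            mean_vector=arrays["mean_vector"],
            covariance=arrays["covariance"],
            whitening_matrix=arrays["whitening_matrix"],
            unwhitening_matrix=arrays["unwhitening_matrix"],
            retained_rank=int(meta["retained_rank"]),
            eigenvalue_floor=float(meta["eigenvalue_floor"]),
        )


def fit_whitening(
    dataset_or_features, eigenvalue_floor: float = 1e-8
) -> WhiteningTransform:
    """Fit mean + covariance inverse square root on pooled frames.

    Fitting always pools frames across all training variants so that every
    variant shares one coordinate embedding. Rank deficiency (fewer frames
    than coordinates) is handled by the eigenvalue floor.
    """
    if isinstance(dataset_or_features, EnsembleDataset):
        x = dataset_or_features.flat_coords()
    else:
        x = np.asarray(dataset_or_features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("whitening requires at least 2 frames")
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / x.shape[0]
    return WhiteningTransform.from_moments(mean, cov, eigenvalue_floor)


def apply_whitening(transform: WhiteningTransform, coordinates: np.ndarray) -> np.ndarray:
    return transform.apply(coordinates)


def unwhiten(transform: WhiteningTransform, features: np.ndarray) -> np.ndarray:
    return transform.inverse(features)


# ---------------------------------------------------------------------------
# Region split for the two-encoder architecture
# ---------------------------------------------------------------------------

@dataclass
class RegionSplit:
    """Partition of atoms into a supervised region (A) and the remainder (B)."""

    encoder_a_atoms: np.ndarray
    encoder_b_atoms: np.ndarray
    target_residue: int
    cutoff: float

    def __post_init__(self) -> None:
        self.encoder_a_atoms = np.asarray(self.encoder_a_atoms, dtype=int)
        self.encoder_b_atoms = np.asarray(self.encoder_b_atoms, dtype=int)
        if self.encoder_a_atoms.size == 0:
            raise ValidationError("encoder A atom set is empty")
        if np.intersect1d(self.encoder_a_atoms, self.encoder_b_atoms).size:
            raise ValidationError("encoder atom sets must be disjoint")


def split_region(
    dataset: EnsembleDataset, target_residue: int, cutoff: float = 1.0
) -> RegionSplit:
    """Assign atoms within ``cutoff`` (nm) of the target residue to encoder A.

    Distance is measured on the reference structure between each atom and the
    nearest atom of ``target_residue``. The remainder goes to encoder B; an
    empty encoder B indicates the cutoff swallowed the whole molecule, in
    which case the unsplit architecture is the right choice.
    """
    resmask = dataset.atoms["residue_index"].to_numpy() == target_residue
    if not resmask.any():
        raise ValidationError(f"residue {target_residue} not present in topology")
    target_xyz = dataset.reference[resmask]
    d = np.linalg.norm(
        dataset.reference[:, None, :] - target_xyz[None, :, :], axis=2
    ).min(axis=1)
    a = np.flatnonzero(d <= cutoff)
    b = np.flatnonzero(d > cutoff)
    if b.size == 0:
        raise ValidationError(
            "encoder B atom set is empty: cutoff exceeds the molecule size; "
            "use the unsplit (single-encoder) architecture instead"
        )
    return RegionSplit(a, b, target_residue, float(cutoff))


# ---------------------------------------------------------------------------
# Feature persistence
# ---------------------------------------------------------------------------

def write_features(
    directory, dataset: EnsembleDataset, transform: WhiteningTransform
) -> dict:
    """Write whitened features, transform and atom metadata under a directory.

    Returns a manifest of written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    features = transform.apply(dataset.flat_coords())
    np.save(directory / "whitened_features.npy", features)
    transform.save(directory / "whitening_transform.npz")
    dataset.atoms.to_csv(directory / "atoms.csv", index=False)
    pd.DataFrame(
        {
            "frame": np.arange(dataset.n_frames),
            "variant": dataset.frame_variants,
            "class": dataset.frame_classes,
        }
    ).to_csv(directory / "frames.csv", index=False)
    meta = {
        "units": "nm (whitened: dimensionless)",
        "n_frames": int(dataset.n_frames),
        "n_atoms": int(dataset.n_atoms),
        "retained_rank": transform.retained_rank,
    }
    (directory / "features.json").write_text(json.dumps(meta, indent=2))
    return {
        "features": str(directory / "whitened_features.npy"),
        "transform": str(directory / "whitening_transform.npz"),
        "atoms": str(directory / "atoms.csv"),
        "frames": str(directory / "frames.csv"),
        "meta": str(directory / "features.json"),
    }
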
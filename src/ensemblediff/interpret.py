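"""Post-hoc analyses of a trained model.

Covers the standard interpretation workflow: frozen-latent ROC comparison
(how separable two structural states are in a fixed latent space),
conformational clustering followed by a distance-correlation scan (which
atom-pair distances track the model's output label across cluster centers),
label-binned distance profiles, hydrogen-bond-based compact/extended state
labeling, and prediction on ensembles of variants not seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from . import model as model_mod
from .exceptions import ValidationError
from .featurize import EnsembleDataset, align_to_reference
from .model import ModelParams

# ---------------------------------------------------------------------------
# Structural state labels
# ---------------------------------------------------------------------------

def label_compact_state(hbond_distances, threshold: float = 4.2) -> str:
    """Label a helix compact iff all donor-acceptor distances are below the
    threshold (Ångstroms; strict inequality).

    The canonical pair list is the backbone N of residue i+4 to the carbonyl
    O of residue i for three consecutive helix turns; the caller supplies
    whichever distances define the feature in their system.
    """
    d = np.asarray(hbond_distances, dtype=np.float64)
    if np.any(d < 0):
        raise ValidationError("distances must be nonnegative")
    return "compact" if bool(np.all(d < threshold)) else "extended"


# ---------------------------------------------------------------------------
# Frozen-latent ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    curves: list  # per fold: (fpr array, tpr array)
    fold_aucs: np.ndarray
    mean_auc: float
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fold, (fpr, tpr) in enumerate(self.curves):
            for f, t in zip(fpr, tpr):
                rows.append({"fold": fold, "fpr": f, "tpr": t})
        return pd.DataFrame(rows)


def frozen_latent_roc(
    latents: np.ndarray,
    binary_state_labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> RocResult:
    """Hold the latent space constant and train a logistic-regression
    classifier on it, scoring each held-out fold with ROC/AUC.

    Folds are stratified and seeded. This quantifies how well a fixed
    latent representation separates two structural states.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import auc, roc_curve
    from sklearn.model_selection import StratifiedKFold

    z = np.atleast_2d(np.asarray(latents, dtype=np.float64))
    if z.shape[0] != len(binary_state_labels):
        raise ValidationError("one label required per latent vector")
    y = np.asarray(binary_state_labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValidationError("need at least 2 instances of each state")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    curves, aucs = [], []
    for train_ix, test_ix in skf.split(z, y):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(z[train_ix], y[train_ix])
        scores = clf.decision_function(z[test_ix])
        fpr, tpr, _ = roc_curve(y[test_ix], scores)
        curves.append((fpr, tpr))
        aucs.append(auc(fpr, tpr))
    aucs = np.asarray(aucs)
    return RocResult(curves=curves, fold_aucs=aucs, mean_auc=float(aucs.mean()),
                     n_folds=n_folds)


def encoder_a_latents(params: ModelParams, coordinates: np.ndarray) -> np.ndarray:
    """The supervised sub-latent (encoder A when split, full latent
    otherwise) for a batch of aligned coordinates."""
    z = model_mod.encode(params, coordinates)
    return z[:, params.latent_slices[0]] if params.spec.split else z


# ---------------------------------------------------------------------------
# Clustering (hybrid k-centers + k-medoids)
# ---------------------------------------------------------------------------

def _nearest(x: np.ndarray, centers: np.ndarray, chunk: int = 2048):
    """Index of the nearest center and that distance, chunked over frames."""
    assign = np.empty(x.shape[0], dtype=int)
    dist = np.empty(x.shape[0])
    for s in range(0, x.shape[0], chunk):
        d = cdist(x[s : s + chunk], centers)
        assign[s : s + chunk] = d.argmin(axis=1)
        dist[s : s + chunk] = d[np.arange(d.shape[0]), assign[s : s + chunk]]
    return assign, dist


def cluster_conformations(
    features: np.ndarray, k: int | None = None, seed: int = 0,
    n_medoid_sweeps: int = 5,
):
    """Greedy k-centers (farthest-point) seeding plus k-medoids refinement.

    Centers are actual frames. The default k scales down with dataset size,
    ``min(2000, n_frames // 10)``, so desk-scale fixtures stay tractable.

    Returns ``(center_indices, assignments)``.
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = x.shape[0]
    if k is None:
        k = max(1, min(2000, n // 10))
    if k > n:
        raise ValidationError(f"k={k} exceeds n_frames={n}")
    rng = np.random.default_rng(seed)

    centers = [int(rng.integers(n))]
    dist = np.linalg.norm(x - x[centers[0]], axis=1)
    assign = np.zeros(n, dtype=int)
    while len(centers) < k:
        nxt = int(dist.argmax())
        centers.append(nxt)
        d = np.linalg.norm(x - x[nxt], axis=1)
        closer = d < dist
        dist[closer] = d[closer]
        assign[closer] = len(centers) - 1

    centers = np.asarray(centers)
    for _ in range(n_medoid_sweeps):
        new_centers = centers.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size <= 2:
                continue
            if members.size <= 2048:
                colsum = squareform(pdist(x[members])).sum(axis=0)
            else:  # avoid an m x m matrix for very large clusters
                colsum = np.zeros(members.size)
                for s in range(0, members.size, 2048):
                    colsum += cdist(x[members[s : s + 2048]], x[members]).sum(axis=0)
            new_centers[c] = members[int(colsum.argmin())]
        if np.array_equal(new_centers, centers):
            break
        centers = new_centers
        assign, _ = _nearest(x, x[centers])
    return centers, assign


# ---------------------------------------------------------------------------
# Distance-correlation attribution
# ---------------------------------------------------------------------------

@dataclass
class DistanceCorrelationReport:
    """Atom-pair distances ranked by |Pearson r| against the output label.

    ``records`` holds the selected pairs sorted by |r| descending with a
    direction column: "contracting" (atoms approach as the label rises,
    negative slope) or "expanding" (positive slope).
    """

    records: pd.DataFrame
    selection: tuple
    n_pairs_enumerated: int
    n_pairs_skipped: int

    @property
    def n_pairs_scored(self) -> int:
        return self.n_pairs_enumerated - self.n_pairs_skipped


def distance_correlation_scan(
    center_coords: np.ndarray,
    atom_subset: np.ndarray,
    labels_at_centers: np.ndarray,
    selection: tuple = ("top_percent", 1.0),
    atoms: pd.DataFrame | None = None,
) -> DistanceCorrelationReport:
    """Correlate every atom-pair distance in a subset with the output label.

    For each unordered pair of atoms in ``atom_subset`` (pairs within the
    same residue are excluded as trivially rigid when ``atoms`` metadata is
    given), computes the Pearson correlation between the pairwise distance
    across cluster centers and the label of each center, then keeps the
    top percentile (or top n) by |r|. Zero-variance distances are skipped
    and counted in the report metadata; the percentile denominator is the
    number of non-skipped pairs.
    """
    coords = np.asarray(center_coords, dtype=np.float64)
    subset = np.asarray(atom_subset, dtype=int)
    y = np.asarray(labels_at_centers, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[0] != y.size:
        raise ValidationError("need (n_centers, n_atoms, 3) coords and one label each")
    if coords.shape[0] < 3:
        raise ValidationError("need at least 3 cluster centers")
    if subset.size < 2:
        raise ValidationError("need at least 2 atoms in the subset")

    ii, jj = np.triu_indices(subset.size, k=1)
    ai, aj = subset[ii], subset[jj]
    if atoms is not None:
        res = atoms["residue_index"].to_numpy()
        keep = res[ai] != res[aj]
        ai, aj = ai[keep], aj[keep]
    n_enumerated = ai.size

    d = np.linalg.norm(coords[:, ai, :] - coords[:, aj, :], axis=2)  # (k, pairs)
    d_c = d - d.mean(axis=0)
    y_c = y - y.mean()
    sd = np.sqrt((d_c * d_c).mean(axis=0))
    sy = np.sqrt((y_c * y_c).mean())
    if sy <= 0:
        raise ValidationError("labels at centers have zero variance")
    nonzero = sd > 1e-12
    n_skipped = int((~nonzero).sum())
    r = np.full(ai.size, np.nan)
    r[nonzero] = (d_c[:, nonzero] * y_c[:, None]).mean(axis=0) / (sd[nonzero] * sy)

    order = np.argsort(np.where(nonzero, -np.abs(r), np.inf))
    scored = order[: int(nonzero.sum())]
    mode, value = selection
    if mode == "top_percent":
        n_sel = max(1, int(np.ceil(value / 100.0 * scored.size)))
    elif mode == "top_n":
        n_sel = min(int(value), scored.size)
    else:
        raise ValidationError("selection mode must be top_percent or top_n")
    sel = scored[:n_sel]

    records = pd.DataFrame(
        {
            "atom_i": ai[sel],
            "atom_j": aj[sel],
            "pearson_r": r[sel],
            "direction": np.where(r[sel] < 0, "contracting", "expanding"),
        }
    )
    if atoms is not None:
        for side in ("i", "j"):
            a = records[f"atom_{side}"].to_numpy()
            records[f"residue_{side}"] = atoms["residue_index"].to_numpy()[a]
            records[f"name_{side}"] = atoms["atom_name"].to_numpy()[a]
    records["rank"] = np.arange(1, len(records) + 1)
    return DistanceCorrelationReport(
        records=records,
        selection=selection,
        n_pairs_enumerated=n_enumerated,
        n_pairs_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Label-binned profiles
# ---------------------------------------------------------------------------

def label_binned_profile(
    labels: np.ndarray, distances: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Mean distance per output-label bin (equal-width bins over [0, 1],
    last bin right-closed). Empty bins are reported with NaN, not zero."""
    y = np.asarray(labels, dtype=np.float64)
    d = np.asarray(distances, dtype=np.float64)
    if y.min() < 0 or y.max() > 1:
        raise ValidationError("labels must lie in [0, 1]")
    idx = np.minimum((y * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = d[idx == b]
        rows.append(
            {
                "bin": b,
                "label_low": b / n_bins,
                "label_high": (b + 1) / n_bins,
                "count": sel.size,
                "mean_distance": sel.mean() if sel.size else np.nan,
                "sem_distance": (
                    sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction on held-out variants
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    labels: np.ndarray  # per-frame output labels in (0, 1)
    extrapolating: np.ndarray  # per-frame flag: outside training feature range
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.labels.size),
                "label": self.labels,
                "extrapolating": self.extrapolating.astype(int),
            }
        )


def predict_new_variant(
    params_or_checkpoint, new_ensemble: EnsembleDataset
) -> PredictionReport:
    """Apply a trained model to an ensemble not seen in training.

    The new ensemble must share the training atom set. Frames are aligned to
    the checkpoint's stored reference, whitened with the stored transforms,
    and scored; frames whose whitened features fall outside the training
    range are flagged as extrapolating (autoencoders are unreliable far
    from their training data), and the summary carries a dominant-warning
    when more than half the frames extrapolate.
    """
    if isinstance(params_or_checkpoint, ModelParams):
        params = params_or_checkpoint
    else:
        params = model_mod.load_checkpoint(params_or_checkpoint)
    if new_ensemble.n_atoms != params.n_atoms:
        raise ValidationError(
            f"ensemble has {new_ensemble.n_atoms} atoms, model expects {params.n_atoms}"
        )
    if params.reference is not None:
        new_ensemble = replace(new_ensemble, reference=params.reference)
    aligned = align_to_reference(new_ensemble)

    xw_parts = model_mod.whiten_inputs(params, aligned.coords)
    cache = model_mod._forward_core(params, xw_parts)
    y = cache["y_hat"]

    flags = np.zeros(y.size, dtype=bool)
    if params.feature_range is not None:
        for part, (lo, hi) in zip(xw_parts, params.feature_range):
            flags |= np.any((part < lo) | (part > hi), axis=1)

    hist, edges = np.histogram(y, bins=10, range=(0.0, 1.0))
    frac_ex = float(flags.mean()) if flags.size else 0.0
    summary = {
        "mean_label": float(y.mean()),
        "std_label": float(y.std()),
        "histogram": hist.tolist(),
        "histogram_edges": edges.tolist(),
        "fraction_extrapolating": frac_ex,
        "extrapolation_warning": frac_ex > 0.5,
    }
    return PredictionReport(labels=y, extrapolating=flags, summary=summary)
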
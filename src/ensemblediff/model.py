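"""The supervised split autoencoder.

The network maps raw aligned XYZ coordinates through a frozen whitening
layer, one or two encoders (input -> reduction -> latent, each affine +
nonlinearity), concatenates the per-encoder sub-latents, and decodes
(latent -> expansion -> whitened output, final layer linear) through a
frozen unwhitening layer back to coordinates. A logistic classification
head reads the supervised sub-latent (encoder A's latent when split, the
full latent otherwise) post-nonlinearity and produces an output label in
(0, 1).

Depth is exactly input -> reduction -> latent -> expansion -> output, with a
four-fold reduction of variables at the reduction layer. The whitening
layers are routed per region: each encoder whitens only its own atoms'
coordinates, using the inverse square root of that region's block of the
pooled covariance, so encoder A's sub-latent and the output label depend
only on encoder-A atoms.

Weights are initialized from a seeded uniform distribution scaled by
fan-in. Gradients are analytic (hand-written backprop); the tiny
architecture makes this exact, fast, and fully deterministic.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import CheckpointError, ValidationError
from .featurize import RegionSplit, WhiteningTransform, atom_coord_indices
from . import losses

CHECKPOINT_FORMAT_VERSION = 1

_ACTIVATIONS = {
    "logistic": (lambda x: 1.0 / (1.0 + np.exp(-x)), lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def allocate_latent(total: int, atom_counts: Sequence[int]) -> list:
    """Split a total latent budget proportionally to per-encoder atom counts,
    largest-remainder rounding, minimum 1 per encoder."""
    counts = np.asarray(atom_counts, dtype=float)
    if total < len(counts):
        raise ValidationError("total latent must be >= number of encoders")
    quotas = total * counts / counts.sum()
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    for i in np.argsort(-remainder)[: total - base.sum()]:
        base[i] += 1
    # enforce a minimum of one latent variable per encoder
    while (base < 1).any():
        base[np.argmin(base)] += 1
        base[np.argmax(base)] -= 1
    return [int(b) for b in base]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer widths and latent allocation of the (possibly split) network."""

    split: bool
    input_dims: tuple
    reduction_dims: tuple
    latent_dims: tuple
    classification_source: str  # "encoder_a" | "full"
    hidden_activation: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        n_enc = 2 if self.split else 1
        for name in ("input_dims", "reduction_dims", "latent_dims"):
            if len(getattr(self, name)) != n_enc:
                raise ValidationError(f"{name} must have one entry per encoder")
        for i, r in zip(self.input_dims, self.reduction_dims):
            if r != math.ceil(i / 4):
                raise ValidationError(
                    "reduction_dim must be ceil(input_dim / 4) per encoder"
                )
        if min(self.input_dims) < 1 or min(self.latent_dims) < 1:
            raise ValidationError("all layer dims must be >= 1")
        if self.classification_source not in ("encoder_a", "full"):
            raise ValidationError("classification_source must be encoder_a|full")
        if self.split and self.classification_source != "encoder_a":
            raise ValidationError("split architecture classifies from encoder A")
        if not self.split and self.classification_source != "full":
            raise ValidationError("unsplit architecture classifies from full latent")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValidationError(
                f"unknown activation {self.hidden_activation!r}; "
                f"choose from {sorted(_ACTIVATIONS)}"
            )

    @property
    def n_encoders(self) -> int:
        return 2 if self.split else 1

    @property
    def total_latent(self) -> int:
        return int(sum(self.latent_dims))

    @property
    def total_reduction(self) -> int:
        return int(sum(self.reduction_dims))

    @property
    def total_input(self) -> int:
        return int(sum(self.input_dims))

    @classmethod
    def for_split(
        cls,
        region: RegionSplit,
        total_latent: int,
        seed: int = 0,
        hidden_activation: str = "logistic",
    ) -> "ArchitectureSpec":
        na, nb = region.encoder_a_atoms.size, region.encoder_b_atoms.size
        lat = allocate_latent(total_latent, [na, nb])
        return cls(
            split=True,
            input_dims=(3 * na, 3 * nb),
            reduction_dims=(math.ceil(3 * na / 4), math.ceil(3 * nb / 4)),
            latent_dims=tuple(lat),
            classification_source="encoder_a",
            hidden_activation=hidden_activation,
            seed=seed,
        )

    @classmethod
    def for_unsplit(
        cls,
        n_atoms: int,
        total_latent: int,
        seed: int = 0,
        hidden_activation: str = "logistic",
    ) -> "ArchitectureSpec":
        return cls(
            split=False,
            input_dims=(3 * n_atoms,),
            reduction_dims=(math.ceil(3 * n_atoms / 4),),
            latent_dims=(int(total_latent),),
            classification_source="full",
            hidden_activation=hidden_activation,
            seed=seed,
        )


@dataclass
class ModelParams:
    """Trainable weights plus frozen whitening layers and routing metadata.

    ``weights`` maps layer names to arrays; ``trainable`` flags which layers
    the current training stage may update. The whitening transforms are not
    in ``weights`` and are therefore structurally untrainable.
    """

    spec: ArchitectureSpec
    encoder_atoms: tuple  # per-encoder atom index arrays (full-topology order)
    transforms: tuple  # per-encoder WhiteningTransform
    weights: dict
    trainable: dict
    reference: np.ndarray | None = None
    region: RegionSplit | None = None
    feature_range: tuple | None = None  # per-encoder (min, max) whitened features

    @property
    def n_atoms(self) -> int:
        return int(sum(a.size for a in self.encoder_atoms))

    @property
    def latent_slices(self) -> list:
        """Index ranges of each encoder's sub-latent in the concatenated z."""
        out, start = [], 0
        for d in self.spec.latent_dims:
            out.append(slice(start, start + d))
            start += d
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            spec=self.spec,
            encoder_atoms=self.encoder_atoms,
            transforms=self.transforms,
            weights={k: v.copy() for k, v in self.weights.items()},
            trainable=dict(self.trainable),
            reference=self.reference,
            region=self.region,
            feature_range=self.feature_range,
        )

    def set_trainable(self, **by_prefix) -> None:
        """Set trainable flags for all layers matching a name prefix,
        e.g. ``set_trainable(enc_reduction=False)``."""
        for prefix, flag in by_prefix.items():
            hit = False
            for name in self.trainable:
                if name.startswith(prefix):
                    self.trainable[name] = bool(flag)
                    hit = True
            if not hit:
                raise ValidationError(f"no layers match prefix {prefix!r}")


def _init_affine(rng, n_in: int, n_out: int):
    scale = 1.0 / math.sqrt(n_in)
    w = rng.uniform(-scale, scale, size=(n_in, n_out))
    b = rng.uniform(-scale, scale, size=n_out)
    return w, b


def build_model(
    spec: ArchitectureSpec,
    transform: WhiteningTransform,
    region: RegionSplit | None = None,
    reference: np.ndarray | None = None,
) -> ModelParams:
    """Instantiate seeded random weights and route the frozen whitening.

    ``transform`` must be fit on the full coordinate vector; per-encoder
    sub-transforms are derived from its pooled covariance blocks.
    """
    if spec.split:
        if region is None:
            raise ValidationError("split architecture requires a RegionSplit")
        encoder_atoms = (region.encoder_a_atoms, region.encoder_b_atoms)
    else:
        n_atoms = spec.total_input // 3
        encoder_atoms = (np.arange(n_atoms),)
    total_dim = 3 * sum(a.size for a in encoder_atoms)
    if transform.n_dim != total_dim:
        raise ValidationError(
            f"whitening transform dimension {transform.n_dim} != "
            f"total input dimension {total_dim}"
        )
    for atoms, d_in in zip(encoder_atoms, spec.input_dims):
        if 3 * atoms.size != d_in:
            raise ValidationError("region atom counts inconsistent with spec input_dims")

    transforms = tuple(
        transform.restrict(atom_coord_indices(atoms)) for atoms in encoder_atoms
    )
    rng = np.random.default_rng(spec.seed)
    weights, trainable = {}, {}

    def add(name, w, b, prefix):
        weights[f"{prefix}{name}_W"], weights[f"{prefix}{name}_b"] = w, b
        trainable[f"{prefix}{name}_W"] = trainable[f"{prefix}{name}_b"] = True

    for e in range(spec.n_encoders):
        add("reduction", *_init_affine(rng, spec.input_dims[e], spec.reduction_dims[e]), f"enc{e}_")
        add("latent", *_init_affine(rng, spec.reduction_dims[e], spec.latent_dims[e]), f"enc{e}_")
    add("expansion", *_init_affine(rng, spec.total_latent, spec.total_reduction), "dec_")
    add("output", *_init_affine(rng, spec.total_reduction, spec.total_input), "dec_")
    cls_dim = spec.latent_dims[0] if spec.split else spec.total_latent
    add("head", *_init_affine(rng, cls_dim, 1), "cls_")

    return ModelParams(
        spec=spec,
        encoder_atoms=encoder_atoms,
        transforms=transforms,
        weights=weights,
        trainable=trainable,
        reference=None if reference is None else np.asarray(reference, float),
        region=region,
    )


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def whiten_inputs(params: ModelParams, coordinates: np.ndarray) -> list:
    """Raw aligned coordinates -> per-encoder whitened feature blocks.

    Accepts ``(n, atoms, 3)`` or flattened ``(n, 3 * atoms)`` arrays.
    """
    x = np.asarray(coordinates, dtype=np.float64)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.ndim == 1:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValidationError("coordinates must be finite")
    if x.shape[1] != 3 * params.n_atoms:
        raise ValidationError(
            f"expected {3 * params.n_atoms} coordinates, got {x.shape[1]}"
        )
    return [
        t.apply(x[:, atom_coord_indices(atoms)])
        for atoms, t in zip(params.encoder_atoms, params.transforms)
    ]


def _forward_core(params: ModelParams, xw_parts: list) -> dict:
    act, _ = _ACTIVATIONS[params.spec.hidden_activation]
    w = params.weights
    hs, zs = [], []
    for e in range(params.spec.n_encoders):
        h = act(xw_parts[e] @ w[f"enc{e}_reduction_W"] + w[f"enc{e}_reduction_b"])
        z = act(h @ w[f"enc{e}_latent_W"] + w[f"enc{e}_latent_b"])
        hs.append(h)
        zs.append(z)
    z = np.concatenate(zs, axis=1)
    z_cls = zs[0] if params.spec.split else z
    logit = (z_cls @ w["cls_head_W"]).ravel() + w["cls_head_b"][0]
    y_hat = _sigmoid(logit)
    expansion = act(z @ w["dec_expansion_W"] + w["dec_expansion_b"])
    xhat_w = expansion @ w["dec_output_W"] + w["dec_output_b"]
    return {
        "xw_parts": xw_parts,
        "h": hs,
        "z_parts": zs,
        "z": z,
        "logit": logit,
        "y_hat": y_hat,
        "expansion": expansion,
        "xhat_w": xhat_w,
    }


def _unwhiten_output(params: ModelParams, xhat_w: np.ndarray) -> np.ndarray:
    """Whitened network output -> full-coordinate reconstruction (n, atoms, 3)."""
    n = xhat_w.shape[0]
    out = np.empty((n, 3 * params.n_atoms))
    start = 0
    for atoms, t in zip(params.encoder_atoms, params.transforms):
        dim = 3 * atoms.size
        out[:, atom_coord_indices(atoms)] = t.inverse(xhat_w[:, start : start + dim])
        start += dim
    return out.reshape(n, params.n_atoms, 3)


def encode(params: ModelParams, coordinates: np.ndarray) -> np.ndarray:
    """Raw aligned coordinates -> concatenated latent vector(s), A then B."""
    return _forward_core(params, whiten_inputs(params, coordinates))["z"]


def decode(params: ModelParams, z: np.ndarray) -> np.ndarray:
    """Latent vector(s) -> reconstructed coordinates in nm."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != params.spec.total_latent:
        raise ValidationError(
            f"latent length {z.shape[1]} != {params.spec.total_latent}"
        )
    act, _ = _ACTIVATIONS[params.spec.hidden_activation]
    w = params.weights
    expansion = act(z @ w["dec_expansion_W"] + w["dec_expansion_b"])
    xhat_w = expansion @ w["dec_output_W"] + w["dec_output_b"]
    return _unwhiten_output(params, xhat_w)


def classify(params: ModelParams, z: np.ndarray) -> np.ndarray:
    """Latent vector(s) -> output label in (0, 1) (logistic of an affine map
    of the supervised sub-latent)."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != params.spec.total_latent:
        raise ValidationError(
            f"latent length {z.shape[1]} != {params.spec.total_latent}"
        )
    z_cls = z[:, params.latent_slices[0]] if params.spec.split else z
    logit = (z_cls @ params.weights["cls_head_W"]).ravel() + params.weights["cls_head_b"][0]
    return np.clip(_sigmoid(logit), 1e-15, 1.0 - 1e-15)


def forward(params: ModelParams, coordinates: np.ndarray):
    """Single shared pass: (reconstructed coordinates, latent, output label)."""
    cache = _forward_core(params, whiten_inputs(params, coordinates))
    recon = _unwhiten_output(params, cache["xhat_w"])
    return recon, cache["z"], cache["y_hat"]


# ---------------------------------------------------------------------------
# Backward pass (full model)
# ---------------------------------------------------------------------------

def forward_backward(
    params: ModelParams,
    xw_parts: list,
    labels: np.ndarray | None,
    weights: losses.LossWeights,
    include_class: bool,
):
    """Loss components and gradients for one batch of whitened inputs.

    Returns ``(components, grads)`` where components is a dict with keys
    recon/classify/corr/total and grads maps weight names to arrays.
    """
    _, dact = _ACTIVATIONS[params.spec.hidden_activation]
    w = params.weights
    cache = _forward_core(params, xw_parts)
    target = np.concatenate(xw_parts, axis=1)
    n = target.shape[0]

    l_recon = losses.recon_loss(target, cache["xhat_w"])
    l_corr = losses.corr_loss(cache["z"]) if n >= 2 else 0.0
    if include_class:
        l_class = losses.class_loss(labels, cache["y_hat"])
    else:
        l_class = 0.0
    total = (
        weights.recon * l_recon
        + weights.corr * l_corr
        + (weights.classify * l_class if include_class else 0.0)
    )

    grads = {}
    # reconstruction path
    d_xhat = weights.recon * losses.recon_loss_grad(target, cache["xhat_w"])
    grads["dec_output_W"] = cache["expansion"].T @ d_xhat
    grads["dec_output_b"] = d_xhat.sum(axis=0)
    d_exp = (d_xhat @ w["dec_output_W"].T) * dact(cache["expansion"])
    grads["dec_expansion_W"] = cache["z"].T @ d_exp
    grads["dec_expansion_b"] = d_exp.sum(axis=0)
    d_z = d_exp @ w["dec_expansion_W"].T

    # latent decorrelation path
    if n >= 2 and weights.corr > 0:
        d_z = d_z + weights.corr * losses.corr_loss_grad(cache["z"])

    # classification path
    if include_class:
        d_logit = weights.classify * losses.class_loss_grad_logit(
            labels, cache["y_hat"]
        )
        z_cls = (
            cache["z_parts"][0] if params.spec.split else cache["z"]
        )
        grads["cls_head_W"] = z_cls.T @ d_logit[:, None]
        grads["cls_head_b"] = np.array([d_logit.sum()])
        d_cls = d_logit[:, None] * w["cls_head_W"].ravel()[None, :]
        if params.spec.split:
            d_z[:, params.latent_slices[0]] += d_cls
        else:
            d_z = d_z + d_cls
    else:
        grads["cls_head_W"] = np.zeros_like(w["cls_head_W"])
        grads["cls_head_b"] = np.zeros_like(w["cls_head_b"])

    # encoders
    for e, sl in enumerate(params.latent_slices):
        z_e, h_e = cache["z_parts"][e], cache["h"][e]
        d_zpre = d_z[:, sl] * dact(z_e)
        grads[f"enc{e}_latent_W"] = h_e.T @ d_zpre
        grads[f"enc{e}_latent_b"] = d_zpre.sum(axis=0)
        d_h = d_zpre @ w[f"enc{e}_latent_W"].T
        d_hpre = d_h * dact(h_e)
        grads[f"enc{e}_reduction_W"] = xw_parts[e].T @ d_hpre
        grads[f"enc{e}_reduction_b"] = d_hpre.sum(axis=0)

    components = {
        "recon": l_recon,
        "classify": l_class,
        "corr": l_corr,
        "total": total,
    }
    return components, grads, cache


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: ModelParams, path) -> None:
    """Self-sufficient inference container: weights, architecture, region
    split, whitening transforms, reference structure, format version."""
    path = Path(path)
    arrays = {f"weight__{k}": v for k, v in params.weights.items()}
    for e, t in enumerate(params.transforms):
        arrays[f"transform{e}__mean"] = t.mean_vector
        arrays[f"transform{e}__cov"] = t.covariance
        arrays[f"encoder_atoms__{e}"] = params.encoder_atoms[e]
    if params.reference is not None:
        arrays["reference"] = params.reference
    if params.feature_range is not None:
        for e, (lo, hi) in enumerate(params.feature_range):
            arrays[f"feature_range{e}__lo"] = lo
            arrays[f"feature_range{e}__hi"] = hi
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "spec": {
            "split": params.spec.split,
            "input_dims": list(params.spec.input_dims),
            "reduction_dims": list(params.spec.reduction_dims),
            "latent_dims": list(params.spec.latent_dims),
            "classification_source": params.spec.classification_source,
            "hidden_activation": params.spec.hidden_activation,
            "seed": params.spec.seed,
        },
        "eigenvalue_floor": [t.eigenvalue_floor for t in params.transforms],
        "region": None
        if params.region is None
        else {
            "target_residue": int(params.region.target_residue),
            "cutoff": float(params.region.cutoff),
        },
        "trainable": params.trainable,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelParams:
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint not found: {path}")
    data = np.load(path, allow_pickle=False)
    if "meta_json" not in data:
        raise CheckpointError(f"{path} is not a model checkpoint")
    meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"unsupported checkpoint format version {meta.get('format_version')!r}"
        )
    spec = ArchitectureSpec(
        split=meta["spec"]["split"],
        input_dims=tuple(meta["spec"]["input_dims"]),
        reduction_dims=tuple(meta["spec"]["reduction_dims"]),
        latent_dims=tuple(meta["spec"]["latent_dims"]),
        classification_source=meta["spec"]["classification_source"],
        hidden_activation=meta["spec"]["hidden_activation"],
        seed=meta["spec"]["seed"],
    )
    n_enc = spec.n_encoders
    encoder_atoms = tuple(data[f"encoder_atoms__{e}"] for e in range(n_enc))
    transforms = tuple(
        WhiteningTransform.from_moments(
            data[f"transform{e}__mean"],
            data[f"transform{e}__cov"],
            meta["eigenvalue_floor"][e],
        )
        for e in range(n_enc)
    )
    weights = {
        k[len("weight__") :]: data[k] for k in data.files if k.startswith("weight__")
    }
    region = None
    if meta["region"] is not None and n_enc == 2:
        region = RegionSplit(
            encoder_a_atoms=encoder_atoms[0],
            encoder_b_atoms=encoder_atoms[1],
            target_residue=meta["region"]["target_residue"],
            cutoff=meta["region"]["cutoff"],
        )
    feature_range = None
    if f"feature_range0__lo" in data.files:
        feature_range = tuple(
            (data[f"feature_range{e}__lo"], data[f"feature_range{e}__hi"])
            for e in range(n_enc)
        )
    return ModelParams(
        spec=spec,
        encoder_atoms=encoder_atoms,
        transforms=transforms,
        weights=weights,
        trainable={k: bool(v) for k, v in meta["trainable"].items()},
        reference=data["reference"] if "reference" in data.files else None,
        region=region,
        feature_range=feature_range,
    )
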
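"""Three-stage progressive training with optional EM self-supervision.

Stage 1 trains a shallow autoencoder (input -> reduction -> output, no
bottleneck) to obtain priors for the reduction layer; stage 2 freezes those
priors and trains the bottleneck, decoder and classifier head; stage 3
unfreezes everything and polishes all weights. Each stage runs a fixed
number of epochs with the Adam optimizer (state reset at stage boundaries),
and in the self-supervised setting an EM E-step refines the per-frame
labels after every epoch of every stage. A per-variant-stratified
validation split is held out of both gradient updates and EM batches; the
returned model is the full-model epoch checkpoint with the lowest
validation reconstruction loss (ties broken by earliest epoch).

During stage 1 there is no latent layer, so the shallow model carries a
temporary classification head on encoder A's reduction layer (discarded
with the temporary decoder) which lets the classification loss and EM
updates run uniformly across all stages.

The unsupervised-autoencoder baseline is the same procedure with the
classification weight at zero and EM disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses, model as model_mod
from .em import EMBounds, LabelState, em_step
from .exceptions import EnsembleDiffError, ValidationError
from .featurize import EnsembleDataset, WhiteningTransform, fit_whitening
from .model import ArchitectureSpec, ModelParams, _ACTIVATIONS, _sigmoid


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs_per_stage: int = 20
    validation_fraction: float = 0.10
    subsample_stride: int = 10  # loader-level option; featurize applies it
    em_enabled: bool = False
    em_bounds: EMBounds = field(default_factory=EMBounds)
    em_batch_size: int | None = None  # defaults to batch_size
    loss_weights: losses.LossWeights = field(default_factory=losses.LossWeights)
    init_seed: int = 0
    shuffle_seed: int = 1
    em_seed: int = 2
    eigenvalue_floor: float = 1e-8

    def validate(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValidationError("validation_fraction must be in (0, 1)")
        for name in ("batch_size", "subsample_stride"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.epochs_per_stage < 0:
            raise ValidationError("epochs_per_stage must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.em_enabled and self.loss_weights.classify == 0:
            raise ValidationError(
                "EM self-supervision requires a nonzero classification weight"
            )

    @property
    def baseline_mode(self) -> bool:
        """Unsupervised-autoencoder mode: no classification, no EM."""
        return self.loss_weights.classify == 0 and not self.em_enabled


class Adam:
    """Standard Adam over a dict of weight arrays (state per weight name)."""

    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, weights: dict, grads: dict, trainable: dict) -> None:
        self.t += 1
        for name, g in grads.items():
            if not trainable.get(name, False):
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            weights[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Stage-1 shallow model
# ---------------------------------------------------------------------------

def _init_stage1_temp(params: ModelParams, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    spec = params.spec
    w_out, b_out = model_mod._init_affine(rng, spec.total_reduction, spec.total_input)
    head_dim = spec.reduction_dims[0] if spec.split else spec.total_reduction
    w_head, b_head = model_mod._init_affine(rng, head_dim, 1)
    return {
        "stage1_output_W": w_out,
        "stage1_output_b": b_out,
        "stage1_head_W": w_head,
        "stage1_head_b": b_head,
    }


def _stage1_forward(params: ModelParams, temp: dict, xw_parts: list) -> dict:
    act, _ = _ACTIVATIONS[params.spec.hidden_activation]
    w = params.weights
    hs = [
        act(xw_parts[e] @ w[f"enc{e}_reduction_W"] + w[f"enc{e}_reduction_b"])
        for e in range(params.spec.n_encoders)
    ]
    h = np.concatenate(hs, axis=1)
    h_cls = hs[0] if params.spec.split else h
    logit = (h_cls @ temp["stage1_head_W"]).ravel() + temp["stage1_head_b"][0]
    return {
        "h_parts": hs,
        "h": h,
        "y_hat": _sigmoid(logit),
        "xhat_w": h @ temp["stage1_output_W"] + temp["stage1_output_b"],
    }


def _stage1_forward_backward(params, temp, xw_parts, labels, weights, include_class):
    _, dact = _ACTIVATIONS[params.spec.hidden_activation]
    w = params.weights
    cache = _stage1_forward(params, temp, xw_parts)
    target = np.concatenate(xw_parts, axis=1)

    l_recon = losses.recon_loss(target, cache["xhat_w"])
    l_class = losses.class_loss(labels, cache["y_hat"]) if include_class else 0.0
    total = weights.recon * l_recon + (weights.classify * l_class if include_class else 0.0)

    grads = {}
    d_xhat = weights.recon * losses.recon_loss_grad(target, cache["xhat_w"])
    grads["stage1_output_W"] = cache["h"].T @ d_xhat
    grads["stage1_output_b"] = d_xhat.sum(axis=0)
    d_h = d_xhat @ temp["stage1_output_W"].T
    if include_class:
        d_logit = weights.classify * losses.class_loss_grad_logit(labels, cache["y_hat"])
        h_cls = cache["h_parts"][0] if params.spec.split else cache["h"]
        grads["stage1_head_W"] = h_cls.T @ d_logit[:, None]
        grads["stage1_head_b"] = np.array([d_logit.sum()])
        d_cls = d_logit[:, None] * temp["stage1_head_W"].ravel()[None, :]
        if params.spec.split:
            d_h[:, : params.spec.reduction_dims[0]] += d_cls
        else:
            d_h = d_h + d_cls
    start = 0
    for e in range(params.spec.n_encoders):
        dim = params.spec.reduction_dims[e]
        d_hpre = d_h[:, start : start + dim] * dact(cache["h_parts"][e])
        grads[f"enc{e}_reduction_W"] = xw_parts[e].T @ d_hpre
        grads[f"enc{e}_reduction_b"] = d_hpre.sum(axis=0)
        start += dim
    components = {"recon": l_recon, "classify": l_class, "corr": 0.0, "total": total}
    return components, grads, cache


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    params: ModelParams
    selected_stage: int
    selected_epoch: int
    loss_history: pd.DataFrame
    label_history: list  # [(global_epoch, labels array)], empty in baseline mode
    labels: LabelState
    train_indices: np.ndarray
    val_indices: np.ndarray
    transform: WhiteningTransform
    checkpoints: list  # [{"stage", "epoch", "val_recon", "params"}]


def validation_split(dataset: EnsembleDataset, fraction: float, seed: int):
    """Seeded per-variant-stratified frame split -> (train_idx, val_idx)."""
    rng = np.random.default_rng(seed)
    train, val = [], []
    for variant in dict.fromkeys(dataset.frame_variants):
        idx = np.flatnonzero(dataset.frame_variants == variant)
        idx = rng.permutation(idx)
        n_val = int(round(fraction * idx.size))
        if idx.size >= 2:
            n_val = min(max(n_val, 1), idx.size - 1)
        else:
            n_val = 0
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


class Trainer:
    """Holds the featurized data and model state across the three stages."""

    def __init__(
        self,
        dataset: EnsembleDataset,
        spec: ArchitectureSpec,
        config: TrainingConfig,
        region=None,
        transform: WhiteningTransform | None = None,
        initial_labels: np.ndarray | None = None,
        params: ModelParams | None = None,
    ):
        config.validate()
        self.dataset = dataset
        self.spec = spec
        self.config = config
        self.train_idx, self.val_idx = validation_split(
            dataset, config.validation_fraction, config.shuffle_seed
        )
        if transform is None:
            transform = fit_whitening(
                dataset.flat_coords()[self.train_idx], config.eigenvalue_floor
            )
        self.transform = transform
        self.params = params or model_mod.build_model(
            spec, transform, region=region, reference=dataset.reference
        )
        # whitening is frozen, so whiten the whole dataset once up front
        self.xw_all = model_mod.whiten_inputs(self.params, dataset.coords)
        labels0 = (
            np.asarray(initial_labels, dtype=np.float64)
            if initial_labels is not None
            else dataset.frame_classes.astype(np.float64)
        )
        self.label_state = LabelState(labels0, dataset.frame_variants)
        self.frame_classes = dataset.frame_classes
        self.rows: list = []
        self.label_history: list = []
        self.checkpoints: list = []
        self.global_epoch = 0
        self.stage1_temp = _init_stage1_temp(self.params, config.init_seed)

    # -- helpers ----------------------------------------------------------

    def _batches(self, stage: int, epoch: int):
        rng = np.random.default_rng([self.config.shuffle_seed, stage, epoch])
        perm = rng.permutation(self.train_idx)
        bs = self.config.batch_size
        batches = [perm[s : s + bs] for s in range(0, perm.size, bs)]
        if len(batches) > 1 and batches[-1].size < 2:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches.pop()
        return batches

    def _xw(self, idx):
        return [part[idx] for part in self.xw_all]

    def _classifier_outputs(self, stage: int) -> np.ndarray:
        if stage == 1:
            return _stage1_forward(self.params, self.stage1_temp, self.xw_all)["y_hat"]
        return model_mod._forward_core(self.params, self.xw_all)["y_hat"]

    def _val_recon(self, stage: int) -> float:
        xw = self._xw(self.val_idx)
        if stage == 1:
            xhat = _stage1_forward(self.params, self.stage1_temp, xw)["xhat_w"]
        else:
            xhat = model_mod._forward_core(self.params, xw)["xhat_w"]
        return losses.recon_loss(np.concatenate(xw, axis=1), xhat)

    def _run_stage(self, stage: int) -> None:
        cfg = self.config
        include_class = cfg.loss_weights.classify > 0
        trainable = dict(self.params.trainable)
        if stage == 1:
            trainable = {k: k.startswith("enc") and "reduction" in k for k in trainable}
            temp_trainable = {k: True for k in self.stage1_temp}
        elif stage == 2:
            trainable = {k: not ("reduction" in k) for k in trainable}
        else:
            trainable = {k: True for k in trainable}
        self.params.trainable = trainable
        opt = Adam(cfg.learning_rate)  # optimizer state resets at each stage

        frozen_check = None
        if stage == 2:
            frozen_check = {
                k: v.copy() for k, v in self.params.weights.items() if "reduction" in k
            }

        train_mask = np.zeros(self.dataset.n_frames, dtype=bool)
        train_mask[self.train_idx] = True

        for epoch in range(cfg.epochs_per_stage):
            sums = {"recon": 0.0, "classify": 0.0, "corr": 0.0, "total": 0.0}
            batches = self._batches(stage, epoch)
            for b, idx in enumerate(batches):
                xw = self._xw(idx)
                y = self.label_state.labels[idx]
                if stage == 1:
                    comp, grads, _ = _stage1_forward_backward(
                        self.params, self.stage1_temp, xw, y,
                        cfg.loss_weights, include_class,
                    )
                    # one optimizer step over model + temporary weights;
                    # in-place -= mutates the shared arrays
                    opt.step(
                        {**self.params.weights, **self.stage1_temp},
                        grads,
                        {**trainable, **temp_trainable},
                    )
                else:
                    comp, grads, _ = model_mod.forward_backward(
                        self.params, xw, y, cfg.loss_weights, include_class
                    )
                    opt.step(self.params.weights, grads, trainable)
                if not np.isfinite(comp["total"]):
                    raise EnsembleDiffError(
                        f"non-finite loss in stage {stage}, epoch {epoch}, batch {b}"
                    )
                for k in sums:
                    sums[k] += comp[k]
            nb = max(len(batches), 1)
            if cfg.em_enabled:
                self.label_state = em_step(
                    self.label_state,
                    self._classifier_outputs(stage),
                    self.frame_classes,
                    cfg.em_bounds,
                    cfg.em_batch_size or cfg.batch_size,
                    seed=[cfg.em_seed, self.global_epoch],
                    frame_mask=train_mask,
                )
                self.label_history.append(
                    (self.global_epoch, self.label_state.labels.copy())
                )
            val_recon = self._val_recon(stage)
            self.rows.append(
                {
                    "epoch": self.global_epoch,
                    "stage": stage,
                    "recon": sums["recon"] / nb,
                    "classify": sums["classify"] / nb,
                    "corr": sums["corr"] / nb,
                    "total": sums["total"] / nb,
                    "val_recon": val_recon,
                }
            )
            if stage >= 2:
                self.checkpoints.append(
                    {
                        "stage": stage,
                        "epoch": self.global_epoch,
                        "val_recon": val_recon,
                        "params": self.params.copy(),
                    }
                )
            self.global_epoch += 1

        if frozen_check is not None:
            for k, v in frozen_check.items():
                if not np.array_equal(self.params.weights[k], v):
                    raise EnsembleDiffError(
                        f"stage-2 freeze contract violated for layer {k}"
                    )

    # -- public API -------------------------------------------------------

    def run(self) -> TrainingResult:
        for stage in (1, 2, 3):
            self._run_stage(stage)
        history = pd.DataFrame(
            self.rows,
            columns=["epoch", "stage", "recon", "classify", "corr", "total", "val_recon"],
        )
        if self.config.baseline_mode and "classify" in history.columns:
            history = history.drop(columns=["classify"])
        if self.checkpoints:
            best = min(self.checkpoints, key=lambda c: (c["val_recon"], c["epoch"]))
            selected = best["params"].copy()
            selected_stage, selected_epoch = best["stage"], best["epoch"]
        else:  # epochs_per_stage == 0
            selected, selected_stage, selected_epoch = self.params.copy(), 0, -1
        selected.feature_range = tuple(
            (part[self.train_idx].min(axis=0), part[self.train_idx].max(axis=0))
            for part in self.xw_all
        )
        return TrainingResult(
            params=selected,
            selected_stage=selected_stage,
            selected_epoch=selected_epoch,
            loss_history=history,
            label_history=self.label_history,
            labels=self.label_state,
            train_indices=self.train_idx,
            val_indices=self.val_idx,
            transform=self.transform,
            checkpoints=self.checkpoints,
        )


def run_training(
    dataset: EnsembleDataset,
    spec: ArchitectureSpec,
    config: TrainingConfig,
    region=None,
    transform: WhiteningTransform | None = None,
    initial_labels: np.ndarray | None = None,
) -> TrainingResult:
    """Full pipeline: stages 1-3 with optional EM, returning the checkpoint
    minimizing validation reconstruction loss.

    ``initial_labels`` defaults to the frame's variant class. With
    ``config.loss_weights.classify == 0`` and EM disabled this trains the
    matched unsupervised-autoencoder baseline (empty label history).
    """
    return Trainer(
        dataset, spec, config, region=region, transform=transform,
        initial_labels=initial_labels,
    ).run()


def stage1_pretrain(
    dataset, spec, config, region=None, transform=None, initial_labels=None
):
    """Train only the shallow input->reduction->output autoencoder; returns
    ``(params, stage1_temp, history)`` where params carries the trained
    reduction-layer priors."""
    t = Trainer(dataset, spec, config, region=region, transform=transform,
                initial_labels=initial_labels)
    t._run_stage(1)
    return t.params, t.stage1_temp, pd.DataFrame(t.rows)


def stage2_pretrain(params, dataset, config, initial_labels=None):
    """Freeze the stage-1 priors and train bottleneck/decoder/classifier."""
    t = Trainer(dataset, params.spec, config, transform=None, params=params,
                initial_labels=initial_labels)
    t._run_stage(2)
    return t.params, pd.DataFrame(t.rows)


def stage3_finetune(params, dataset, config, initial_labels=None):
    """Unfreeze everything and polish all non-whitening weights."""
    t = Trainer(dataset, params.spec, config, transform=None, params=params,
                initial_labels=initial_labels)
    t._run_stage(3)
    return t.params, pd.DataFrame(t.rows)
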
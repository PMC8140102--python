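"""The three-term training objective.

The total loss is the unweighted sum (weights configurable) of

* a reconstruction term: mean over the batch of the mean over output nodes
  of ``|x - x_hat| + (x - x_hat)^2`` — L1 to funnel reconstructions toward
  the target, L2 to discourage outliers; computed in whitened coordinates,
  where the frozen (un)whitening layers make residuals dimensionless;
* a classification term: binary cross-entropy between the classifier output
  and the (possibly fractional, EM-refined) per-frame label;
* a latent decorrelation term: the sum over ordered pairs ``i != j`` of the
  squared sample covariance between latent variables, discouraging redundant
  latent dimensions.

Analytic gradients for each term live next to the term; the sample
covariance uses the biased (1/N_b) normalizer, a documented constant that
does not move the minimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

CLASSIFIER_EPS = 1e-7


@dataclass
class LossWeights:
    recon: float = 1.0
    classify: float = 1.0
    corr: float = 1.0

    def __post_init__(self) -> None:
        if min(self.recon, self.classify, self.corr) < 0:
            raise ValidationError("loss weights must be nonnegative")


@dataclass
class Batch:
    """One training batch: whitened-space targets and model outputs."""

    inputs: np.ndarray  # (N_b, N_n) whitened targets
    reconstructions: np.ndarray  # (N_b, N_n)
    labels: np.ndarray  # (N_b,) in [0, 1]
    classifier_outputs: np.ndarray  # (N_b,) in (0, 1)
    latents: np.ndarray  # (N_b, latent_dims)

    def __post_init__(self) -> None:
        n = self.inputs.shape[0]
        for name in ("reconstructions", "labels", "classifier_outputs", "latents"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"batch member {name} has inconsistent size")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 1):
            raise ValidationError("labels must lie in [0, 1]")


def recon_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    if x.shape != x_hat.shape:
        raise ValidationError("input and reconstruction shapes differ")
    r = x - x_hat
    return float(np.mean(np.abs(r) + r * r))


def recon_loss_grad(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """Gradient of :func:`recon_loss` with respect to the reconstruction."""
    r = x - x_hat
    return -(np.sign(r) + 2.0 * r) / r.size


def class_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy; supports fractional (EM-refined) targets.

    Classifier outputs exactly at 0 or 1 are clamped to
    ``[eps, 1 - eps]`` with eps = 1e-7 and the clamp is logged.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValidationError("label and prediction shapes differ")
    if np.any((y_hat <= 0) | (y_hat >= 1)):
        logger.warning("classifier outputs at {0,1} clamped to [eps, 1-eps]")
        y_hat = np.clip(y_hat, CLASSIFIER_EPS, 1.0 - CLASSIFIER_EPS)
    return float(np.mean(-(y * np.log(y_hat) + (1.0 - y) * np.log1p(-y_hat))))


def class_loss_grad_logit(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Gradient of :func:`class_loss` with respect to the classifier logit
    (pre-sigmoid), the numerically stable composition."""
    return (y_hat - y) / y.size


def _offdiag_cov(z: np.ndarray) -> np.ndarray:
    zc = z - z.mean(axis=0)
    c = zc.T @ zc / z.shape[0]
    np.fill_diagonal(c, 0.0)
    return c


def corr_loss(z: np.ndarray) -> float:
    """Sum over ordered pairs i != j of squared latent sample covariances."""
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValidationError("corr_loss requires a batch of at least 2 frames")
    c = _offdiag_cov(z)
    return float(np.sum(c * c))


def corr_loss_grad(z: np.ndarray) -> np.ndarray:
    """Gradient of :func:`corr_loss` with respect to the latent batch."""
    n = z.shape[0]
    zc = z - z.mean(axis=0)
    c = _offdiag_cov(z)
    g = zc @ (4.0 * c) / n
    return g - g.mean(axis=0)


def total_loss(
    batch: Batch, weights: LossWeights | None = None, include_class: bool = True
) -> float:
    """Weighted sum of the three terms; the classification term is omitted
    entirely in the unsupervised-autoencoder baseline mode."""
    w = weights or LossWeights()
    total = w.recon * recon_loss(batch.inputs, batch.reconstructions)
    total += w.corr * corr_loss(batch.latents)
    if include_class:
        total += w.classify * class_loss(batch.labels, batch.classifier_outputs)
    return float(total)
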
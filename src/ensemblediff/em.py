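"""Self-supervised label refinement by expectation maximization.

Per-frame training labels K in [0, 1] start as the frame's variant-level
binary class. After each training epoch (M-step: fit the network to the
current labels), an E-step replaces each label with the conditional
expectation of its binary realization given bag-level bounds on how many
frames in its batch carry the property:

    y_i = E[y^_i | S_L <= y^_r <= S_U]
        = y^_i * P(S_L - 1 <= y^_r - y^_i <= S_U - 1) / P(S_L <= y^_r <= S_U)

where y^ are classifier outputs treated as independent Bernoulli
parameters, y^_r is the batch's count of successes (a Poisson-binomial
random variable), and (S_L, S_U) are class-specific count bounds obtained
from user-supplied fractions. The numerator uses the leave-one-out count
distribution (the batch without frame i).

The Poisson-binomial laws are computed exactly by sequential convolution;
leave-one-out distributions come from prefix/suffix convolutions, which is
exact and cheap at the default batch size of 32.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleConstraintError, ValidationError

PROB_EPS = 1e-7


@dataclass(frozen=True)
class EMBounds:
    """Per-class (lower, upper) fractions of frames carrying the property.

    The defaults mirror a setting where 0-30% of negative-class frames and
    60-90% of positive-class frames are expected to carry the property,
    allowing ensemble overlap while keeping a clear class signal. An
    alternative preset for weaker separation is (0.10, 0.40) / (0.60, 0.90).
    """

    negative: tuple = (0.0, 0.30)
    positive: tuple = (0.60, 0.90)

    def __post_init__(self) -> None:
        for name, (lo, up) in (("negative", self.negative), ("positive", self.positive)):
            if not 0.0 <= lo < up <= 1.0:
                raise ValidationError(
                    f"{name} bounds must satisfy 0 <= lower < upper <= 1"
                )
        if self.positive[0] < self.negative[0] or self.positive[1] < self.negative[1]:
            raise ValidationError(
                "positive-class bounds must be >= negative-class bounds elementwise"
            )

    def for_class(self, label: int) -> tuple:
        return self.positive if label == 1 else self.negative


@dataclass
class LabelState:
    """Per-frame labels K in [0, 1] plus provenance and an iteration counter."""

    labels: np.ndarray
    frame_variants: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 1):
            raise ValidationError("labels must lie in [0, 1]")
        if len(self.frame_variants) != self.labels.size:
            raise ValidationError("one variant id required per label")

    @classmethod
    def from_classes(cls, frame_classes: np.ndarray, frame_variants: np.ndarray):
        """Initialize labels to the variant's binary class (all 1s for
        positive-class frames, all 0s for negative-class frames)."""
        return cls(
            labels=np.asarray(frame_classes, dtype=np.float64),
            frame_variants=np.asarray(frame_variants),
            iteration=0,
        )


def count_distribution(probabilities: np.ndarray) -> np.ndarray:
    """Poisson-binomial law of the success count of independent Bernoullis.

    Computed by sequential convolution; exact up to float rounding and
    normalized to sum to 1 within 1e-12.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.size == 0:
        raise ValidationError("count_distribution requires at least one probability")
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    dist = np.array([1.0])
    for pi in p:
        nxt = np.empty(dist.size + 1)
        nxt[:-1] = dist * (1.0 - pi)
        nxt[-1] = 0.0
        nxt[1:] += dist * pi
        dist = nxt
    return dist


def _window_sum(dist: np.ndarray, lo: int, hi: int) -> float:
    lo = max(lo, 0)
    hi = min(hi, dist.size - 1)
    if hi < lo:
        return 0.0
    return float(dist[lo : hi + 1].sum())


def expectation_update(y_hat: np.ndarray, s_l: int, s_u: int) -> np.ndarray:
    """Conditional expectation of each frame's binary label given count bounds.

    Satisfies the conservation property: the updated labels sum to
    ``E[count | S_L <= count <= S_U]``, which lies in ``[S_L, S_U]``.
    """
    p = np.clip(np.asarray(y_hat, dtype=np.float64), PROB_EPS, 1.0 - PROB_EPS)
    n = p.size
    if n == 0:
        raise ValidationError("expectation_update requires a nonempty batch")
    if not 0 <= s_l <= s_u <= n:
        raise ValidationError(f"require 0 <= S_L <= S_U <= n; got ({s_l}, {s_u}, n={n})")

    # prefix[i]: law of the count over p[:i]; suffix[i]: over p[i:]
    prefix = [np.array([1.0])]
    for pi in p:
        d = prefix[-1]
        nxt = np.empty(d.size + 1)
        nxt[:-1] = d * (1.0 - pi)
        nxt[-1] = 0.0
        nxt[1:] += d * pi
        prefix.append(nxt)
    suffix = [np.array([1.0])]
    for pi in p[::-1]:
        d = suffix[-1]
        nxt = np.empty(d.size + 1)
        nxt[:-1] = d * (1.0 - pi)
        nxt[-1] = 0.0
        nxt[1:] += d * pi
        suffix.append(nxt)
    suffix = suffix[::-1]  # suffix[i] is now the law over p[i:]

    denom = _window_sum(prefix[n], s_l, s_u)
    if denom <= 0.0:
        raise InfeasibleConstraintError(
            f"count window [{s_l}, {s_u}] has zero probability for this batch"
        )
    y = np.empty(n)
    for i in range(n):
        loo = np.convolve(prefix[i], suffix[i + 1])
        y[i] = p[i] * _window_sum(loo, s_l - 1, s_u - 1) / denom
    return np.clip(y, 0.0, 1.0)


def fractions_to_counts(lower: float, upper: float, n: int) -> tuple:
    """Fraction bounds -> integer count bounds for a batch of size n:
    S_L = ceil(f_L * n), S_U = floor(f_U * n), then S_L = min(S_L, S_U)."""
    s_l = math.ceil(lower * n - 1e-9)
    s_u = math.floor(upper * n + 1e-9)
    return min(s_l, s_u), s_u


def em_step(
    state: LabelState,
    classifier_outputs: np.ndarray,
    frame_classes: np.ndarray,
    bounds: EMBounds,
    em_batch_size: int = 32,
    seed: int = 0,
    frame_mask: np.ndarray | None = None,
) -> LabelState:
    """One E-step over all (unmasked) frames.

    Frames are grouped by variant class, shuffled with a seeded generator,
    and partitioned into batches of ``em_batch_size`` (a trailing batch of
    fewer than 2 frames is merged into the previous batch). Each batch's
    fraction bounds are converted to counts and :func:`expectation_update`
    replaces the labels. Frames excluded by ``frame_mask`` (e.g. validation
    frames) keep their previous labels.
    """
    y_hat = np.asarray(classifier_outputs, dtype=np.float64)
    frame_classes = np.asarray(frame_classes)
    if y_hat.size != state.labels.size or frame_classes.size != state.labels.size:
        raise ValidationError("classifier outputs required for every frame")
    if em_batch_size < 2:
        raise ValidationError("em_batch_size must be >= 2")
    rng = np.random.default_rng(seed)
    new_labels = state.labels.copy()
    for cls in (0, 1):
        idx = np.flatnonzero(frame_classes == cls)
        if frame_mask is not None:
            idx = idx[np.asarray(frame_mask)[idx]]
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        batches = [idx[s : s + em_batch_size] for s in range(0, idx.size, em_batch_size)]
        if len(batches) > 1 and batches[-1].size < 2:
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches.pop()
        lo, up = bounds.for_class(cls)
        for b, batch in enumerate(batches):
            if batch.size < 2:
                continue  # a lone frame with no batch to merge into
            s_l, s_u = fractions_to_counts(lo, up, batch.size)
            try:
                new_labels[batch] = expectation_update(y_hat[batch], s_l, s_u)
            except InfeasibleConstraintError as exc:
                raise InfeasibleConstraintError(
                    f"class {cls}, batch {b}: {exc}"
                ) from exc
    return LabelState(
        labels=new_labels,
        frame_variants=state.frame_variants,
        iteration=state.iteration + 1,
    )
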
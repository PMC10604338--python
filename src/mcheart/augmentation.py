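"""Spectrogram-level training-time augmentation: mixup and cutout.

Mixup draws a single lambda ~ Beta(alpha, alpha) per batch and blends each
sample with a permutation partner, blending the (one-hot or soft) labels
identically, so labels stay on the probability simplex. Cutout zeroes one
axis-aligned rectangle at a uniform position, at the same location across a
sample's channels. The ``*_prob`` coefficients are per-batch application
probabilities. Both transforms are for the training path only; evaluation
must see unaugmented features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "mixup", "cutout", "augment_batch"]


@dataclass(frozen=True)
class AugmentConfig:
    mixup_alpha: float = 0.5
    mixup_prob: float = 0.7
    cutout_prob: float = 0.8
    cutout_frac: tuple[float, float] = (0.25, 0.25)

    def __post_init__(self) -> None:
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be > 0")
        for p in (self.mixup_prob, self.cutout_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        fh, fw = self.cutout_frac
        if not (0.0 <= fh <= 1.0 and 0.0 <= fw <= 1.0):
            raise ValueError("cutout fractions must lie in [0, 1]")


def mixup(
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    lam: float | None = None,
    scalars: np.ndarray | None = None,
):
    """Convex-combine each sample with a random permutation partner.

    Returns ``(mixed_x, mixed_y)`` (plus mixed scalars when given). A batch
    of one is returned unchanged. ``lam`` overrides the Beta draw, which is
    useful for deterministic checks.
    """
    n = batch_x.shape[0]
    if n < 2:
        return (batch_x, batch_y) if scalars is None else (batch_x, batch_y, scalars)
    if lam is None:
        lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
    perm = rng.permutation(n)
    mixed_x = lam * batch_x + (1.0 - lam) * batch_x[perm]
    mixed_y = lam * batch_y + (1.0 - lam) * batch_y[perm]
    if scalars is None:
        return mixed_x, mixed_y
    return mixed_x, mixed_y, lam * scalars + (1.0 - lam) * scalars[perm]


def cutout(
    x: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Zero one uniform-position rectangle across all channels of a sample.

    ``x`` has shape (channels, height, width); the rectangle spans
    ``floor(frac * dim)`` cells per axis (clipped to the channel), and every
    entry outside it is returned unchanged.
    """
    c, height, width = x.shape
    h = min(int(np.floor(cfg.cutout_frac[0] * height)), height)
    w = min(int(np.floor(cfg.cutout_frac[1] * width)), width)
    if h == 0 or w == 0:
        return x.copy()
    top = int(rng.integers(0, height - h + 1))
    left = int(rng.integers(0, width - w + 1))
    out = x.copy()
    out[:, top : top + h, left : left + w] = 0.0
    return out


def augment_batch(
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    scalars: np.ndarray | None = None,
):
    """Training-batch augmentation: mixup first, then cutout, each fired by a
    per-batch Bernoulli draw at its configured probability."""
    if rng.random() < cfg.mixup_prob:
        if scalars is None:
            batch_x, batch_y = mixup(batch_x, batch_y, cfg, rng)
        else:
            batch_x, batch_y, scalars = mixup(batch_x, batch_y, cfg, rng, scalars=scalars)
    if rng.random() < cfg.cutout_prob:
        batch_x = np.stack([cutout(x, cfg, rng) for x in batch_x])
    if scalars is None:
        return batch_x, batch_y
    return batch_x, batch_y, scalars
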
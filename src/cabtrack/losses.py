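"""Classification loss for imbalanced transplant-state detection.

The three transplant states are heavily imbalanced (normal seedlings dominate
the field), so plain cross-entropy lets the frequent, easy class swamp the
gradient. The quality-focal loss

    L_QFL(y, s) = -alpha_t * |y - s|^gamma * [(1 - y) log(1 - s) + y log(s)]
    alpha_t     = y * alpha + (1 - y) * (1 - alpha)

down-weights well-classified examples through the |y - s|^gamma modulating
factor and re-balances positives/negatives through alpha_t. Because the
focal term can concentrate weight on noisy or mislabeled samples, it is
blended with plain binary cross-entropy:

    L_cls = j * L_QFL + k * L_BCE

Defaults gamma = 1.5, alpha = 0.3, j = k = 0.5. With gamma = 0 the focal
term collapses to alpha_t * BCE (an identity the tests pin down).
All functions are vectorized numpy; batch losses reduce by the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SIGMA_EPS = 1e-7  # probability clip for log stability


@dataclass(frozen=True)
class LossParams:
    gamma: float = 1.5
    alpha: float = 0.3
    j: float = 0.5
    k: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.j < 0 or self.k < 0:
            raise ValueError("combination weights must be >= 0")


def alpha_t(y, alpha: float):
    """Class-balance weight: alpha for positives (y=1), 1-alpha for negatives."""
    y = np.asarray(y, dtype=float)
    return y * alpha + (1.0 - y) * (1.0 - alpha)


def _check_sigma(sigma):
    sigma = np.asarray(sigma, dtype=float)
    if np.any((sigma < 0.0) | (sigma > 1.0)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return np.clip(sigma, SIGMA_EPS, 1.0 - SIGMA_EPS)


def bce(y, sigma):
    """Elementwise binary cross-entropy, probabilities clipped for stability."""
    y = np.asarray(y, dtype=float)
    s = _check_sigma(sigma)
    return -(y * np.log(s) + (1.0 - y) * np.log(1.0 - s))


def qfocal_loss(y, sigma, params: LossParams = LossParams()):
    """Elementwise quality-focal loss; reduces to alpha_t * BCE at gamma = 0."""
    y = np.asarray(y, dtype=float)
    s = _check_sigma(sigma)
    mod = np.abs(y - np.asarray(sigma, dtype=float)) ** params.gamma
    return alpha_t(y, params.alpha) * mod * bce(y, sigma)


def combined_cls_loss(y, sigma, params: LossParams = LossParams()) -> float:
    """Batch classification loss: mean of j * QFL + k * BCE over (y, sigma) pairs."""
    per_elem = params.j * qfocal_loss(y, sigma, params) + params.k * bce(y, sigma)
    return float(np.mean(per_elem))
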
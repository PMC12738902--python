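"""Triplet-attention forward computation on C x H x W feature tensors.

Three parallel branches re-weight the input without learnable per-channel
parameters beyond one small convolution each:

* branch 1 rotates the tensor so channel and height swap roles, capturing
  channel-height interaction;
* branch 2 swaps channel and width;
* branch 3 operates on the tensor as-is (pure spatial attention).

Each branch compresses its (rotated) tensor with a Z-pool — per-position
max and mean over the leading axis, stacked into two channels — convolves
that 2-channel map down to one attention map, squashes it with a sigmoid,
multiplies the rotated tensor by the map, and rotates back. The module
output is the plain average of the three branches, so its shape always
equals the input shape. Rotation is implemented as axis transposition (each
swap is its own inverse), and batch normalization is modeled as the
identity so the forward math is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d


def z_pool(t: np.ndarray) -> np.ndarray:
    """Compress the leading axis to 2 channels: [max over axis 0, mean over axis 0]."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 3:
        raise ValueError(f"expected a 3-d tensor, got shape {t.shape}")
    return np.stack([t.max(axis=0), t.mean(axis=0)])


@dataclass
class AttentionKernels:
    """Per-branch conv weights: three (2, k, k) kernels plus scalar biases."""

    kernels: tuple[np.ndarray, np.ndarray, np.ndarray]
    biases: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ks = []
        for w in self.kernels:
            w = np.asarray(w, dtype=float)
            if w.ndim != 3 or w.shape[0] != 2 or w.shape[1] != w.shape[2]:
                raise ValueError(f"kernel must have shape (2, k, k), got {w.shape}")
            if w.shape[1] % 2 == 0:
                raise ValueError(f"kernel size must be odd, got {w.shape[1]}")
            ks.append(w)
        self.kernels = tuple(ks)

    @classmethod
    def zeros(cls, k: int = 7) -> "AttentionKernels":
        z = np.zeros((2, k, k))
        return cls((z.copy(), z.copy(), z.copy()))

    @classmethod
    def random(cls, k: int = 7, seed: int = 0, scale: float = 0.1) -> "AttentionKernels":
        rng = np.random.default_rng(seed)
        ws = tuple(rng.normal(0.0, scale, size=(2, k, k)) for _ in range(3))
        return cls(ws, tuple(rng.normal(0.0, scale, size=3)))


def _conv2(zmap: np.ndarray, kernel: np.ndarray, bias: float) -> np.ndarray:
    # 2-in/1-out cross-correlation, zero-padded to 'same' spatial size
    out = sum(
        correlate2d(zmap[c], kernel[c], mode="same", boundary="fill", fillvalue=0.0)
        for c in range(2)
    )
    return out + bias


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _branch(t: np.ndarray, kernel: np.ndarray, bias: float) -> np.ndarray:
    att = _sigmoid(_conv2(z_pool(t), kernel, bias))
    return t * att[None, :, :]


def triplet_attention(t: np.ndarray, kernels: AttentionKernels) -> np.ndarray:
    """Average of the three attention branches; output shape equals input shape.

    With all-zero kernels and biases every attention map is sigmoid(0) = 0.5,
    so the output is exactly half the input — a convenient algebraic anchor.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 3:
        raise ValueError(f"expected a (C, H, W) tensor, got shape {t.shape}")
    # branch 1: swap channel and height axes (rotation about the W axis)
    b1 = _branch(t.transpose(1, 0, 2), kernels.kernels[0], kernels.biases[0]
                 ).transpose(1, 0, 2)
    # branch 2: swap channel and width axes (rotation about the H axis)
    b2 = _branch(t.transpose(2, 1, 0), kernels.kernels[1], kernels.biases[1]
                 ).transpose(2, 1, 0)
    # branch 3: identity orientation (spatial attention)
    b3 = _branch(t, kernels.kernels[2], kernels.biases[2])
    return (b1 + b2 + b3) / 3.0
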
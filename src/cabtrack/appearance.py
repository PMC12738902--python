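"""Re-identification crop preprocessing and the embedding-provider contract.

Seedling crops are standardized the way the appearance network expects them:
the detector box is cut from the frame, padded with white to a 1:1 aspect
(seedling boxes cluster near square, unlike the 1:2 pedestrian convention),
and resampled to 128x128. Any callable ``(image, box) -> unit vector`` or
per-identity provider can stand behind the tracker; the synthetic embedder
here is the deterministic stand-in used by the simulator and the tests.
"""

from __future__ import annotations

import hashlib

import numpy as np
from PIL import Image

from .formats import BoundingBox

PATCH_SIZE = 128
EMBED_DIM = 128


def square_pad_crop(
    image: np.ndarray, box: BoundingBox, size: int = PATCH_SIZE
) -> np.ndarray:
    """Cut ``box`` from ``image`` and standardize it to a white-padded square patch.

    The box is clipped to the image extent, the shorter axis is padded
    symmetrically with intensity 255 until the crop is square (odd remainders
    pad one extra pixel on the right/bottom), and the result is resampled to
    ``size`` x ``size`` with bilinear interpolation. Content aspect is
    preserved. Raises ``ValueError`` if the box lies fully outside the image.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    h, w = image.shape[:2]
    x1 = int(np.floor(max(box.x1, 0)))
    y1 = int(np.floor(max(box.y1, 0)))
    x2 = int(np.ceil(min(box.x2, w)))
    y2 = int(np.ceil(min(box.y2, h)))
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"box {box} lies outside the {w}x{h} image extent")
    crop = np.asarray(image[y1:y2, x1:x2], dtype=np.uint8)

    ch, cw = crop.shape[:2]
    side = max(ch, cw)
    pad_y, pad_x = side - ch, side - cw
    crop = np.pad(
        crop,
        ((pad_y // 2, pad_y - pad_y // 2), (pad_x // 2, pad_x - pad_x // 2), (0, 0)),
        mode="constant",
        constant_values=255,
    )
    if crop.shape[0] == size:
        return crop
    resized = Image.fromarray(crop).resize((size, size), Image.BILINEAR)
    return np.asarray(resized, dtype=np.uint8)


def _identity_rng(identity: int, seed: int) -> np.random.Generator:
    # stable across processes: hash the pair instead of relying on Python's hash()
    digest = hashlib.sha256(f"{identity}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def synthetic_embedder(
    identity: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    dim: int = EMBED_DIM,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-norm appearance embedding for a synthetic identity.

    Each identity owns a fixed base direction derived from ``(identity, seed)``;
    a draw is ``normalize(base + N(0, noise_sd))``. With the default ``rng=None``
    the noise stream is also derived from ``(identity, seed)``, so repeated
    calls are identical; pass a generator to obtain independent noisy views of
    the same identity (what the simulator does frame by frame).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    base_rng = _identity_rng(identity, seed)
    base = base_rng.standard_normal(dim)
    base /= np.linalg.norm(base)
    if noise_sd > 0.0:
        noise_rng = rng if rng is not None else base_rng
        base = base + noise_rng.normal(0.0, noise_sd, size=dim)
        base /= np.linalg.norm(base)
    return base


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b) for unit vectors: 0 for identical direction, 2 for opposite."""
    return float(1.0 - np.dot(np.asarray(a), np.asarray(b)))
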
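"""Student-noising augmentation: contrast jitter and head rescaling.

Two families, mirroring the noisy-student recipe for head images:

* photometric — each sample is pushed through a power-law (gamma)
  transform, a logarithmic correction, or left unchanged, each drawn with
  probability 1/3 by default.  Photometric noise touches the image only.
* geometric — head length and width are rescaled independently about the
  image center.  Geometry is applied congruently to image and mask
  (nearest-neighbor for the mask so label states stay discrete).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale as _sk_rescale

__all__ = [
    "AugmentConfig",
    "power_law",
    "log_correction",
    "sample_contrast_mode",
    "rescale_head",
    "augment_sample",
]

MODES = ("power", "log", "none")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation strengths.

    ``mode_probs`` are the selection probabilities for (power-law, log,
    none).  ``gamma_range`` bounds the power-law exponent; ``gain`` scales
    the log correction (gain 1 maps [0,1] onto itself).  ``scale_x_range``
    and ``scale_y_range`` bound the independent width/length rescaling.
    """

    mode_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    gamma_range: tuple[float, float] = (0.7, 1.3)
    gain: float = 1.0
    scale_x_range: tuple[float, float] = (0.85, 1.15)
    scale_y_range: tuple[float, float] = (0.85, 1.15)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.mode_probs), 1.0):
            raise ValueError("mode_probs must sum to 1")
        if any(p < 0 for p in self.mode_probs):
            raise ValueError("mode_probs must be non-negative")
        for name in ("gamma_range", "scale_x_range", "scale_y_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def power_law(image: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise ``image**gamma`` (gamma correction)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.power(image, gamma)


def log_correction(image: np.ndarray, gain: float = 1.0) -> np.ndarray:
    """``gain * log2(1 + image)``; with gain 1 this fixes 0 and 1."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return gain * np.log2(1.0 + image)


def sample_contrast_mode(config: AugmentConfig, rng: np.random.Generator) -> str:
    """Draw one of ``{"power", "log", "none"}`` per ``config.mode_probs``."""
    return str(rng.choice(MODES, p=np.asarray(config.mode_probs, dtype=float)))


def _center_fit(arr: np.ndarray, shape: tuple[int, int], fill: float) -> np.ndarray:
    """Center-crop/pad ``arr`` to ``shape``."""
    out = np.full(shape, fill, dtype=arr.dtype)
    sy = (arr.shape[0] - shape[0]) // 2
    sx = (arr.shape[1] - shape[1]) // 2
    ty = max(0, -sy)
    tx = max(0, -sx)
    cy = max(0, sy)
    cx = max(0, sx)
    h = min(arr.shape[0] - cy, shape[0] - ty)
    w = min(arr.shape[1] - cx, shape[1] - tx)
    out[ty : ty + h, tx : tx + w] = arr[cy : cy + h, cx : cx + w]
    return out


def rescale_head(
    image: np.ndarray, mask: np.ndarray, sx: float, sy: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale content by (sy, sx) about the center, back to original shape.

    The image is interpolated bilinearly; the mask with nearest neighbor so
    it keeps its discrete label values.  Enlarged content is center-cropped,
    shrunken content is padded with the image's background (its minimum) and
    mask zeros.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError("scales must be positive")
    if sx == 1.0 and sy == 1.0:
        return image.copy(), mask.copy()
    img2 = _sk_rescale(image, (sy, sx), order=1, preserve_range=True, anti_aliasing=False)
    msk2 = _sk_rescale(
        mask.astype(np.uint8), (sy, sx), order=0, preserve_range=True, anti_aliasing=False
    ).astype(mask.dtype)
    img_out = _center_fit(img2.astype(image.dtype), image.shape, fill=float(image.min()))
    msk_out = _center_fit(msk2, mask.shape, fill=0)
    return img_out, msk_out


def augment_sample(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One noisy-student draw: contrast jitter on the image, then a
    congruent geometric rescale of image and mask."""
    mode = sample_contrast_mode(config, rng)
    if mode == "power":
        image = power_law(image, rng.uniform(*config.gamma_range))
    elif mode == "log":
        image = log_correction(image, config.gain)
    else:
        image = image.copy()
    sx = rng.uniform(*config.scale_x_range)
    sy = rng.uniform(*config.scale_y_range)
    return rescale_head(image, mask, sx, sy)
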
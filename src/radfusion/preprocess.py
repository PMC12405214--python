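"""Preprocessing: LoG filtering, patch preparation, and mask utilities.

Two consumers sit downstream. The radiomics extractor works on the full
slice (original plus three Laplacian-of-Gaussian scales) restricted to the
ROI mask; the networks consume a 32x32 crop centered on the mask centroid,
bicubically upscaled to 224x224 and min-max rescaled per patch.

The three LoG scales are named fine / medium / coarse with in-plane kernel
sizes 3 / 5 / 7; the Gaussian sigma of each scale is chosen so that the
kernel's support covers about 3 sigma (0.5, 1.0, 1.5 px by default). All
operations here are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantom import RoiSample


@dataclass(frozen=True)
class LogScale:
    """One Laplacian-of-Gaussian scale (name, odd kernel size, sigma in px)."""

    name: str
    kernel_size: int
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ValueError("kernel_size must be odd and >= 3")


#: The three standard scales: fine 3px/0.5, medium 5px/1.0, coarse 7px/1.5.
DEFAULT_LOG_SCALES = (
    LogScale("fine", 3, 0.5),
    LogScale("medium", 5, 1.0),
    LogScale("coarse", 7, 1.5),
)


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Mean (row, col) of foreground pixel coordinates."""
    if not mask.any():
        raise ValueError("empty mask")
    rr, cc = np.nonzero(mask)
    return float(rr.mean()), float(cc.mean())


def crop_patch(sample: RoiSample, size: int = 32) -> np.ndarray:
    """size x size window centered on the mask centroid, edge-padded.

    The window start is ``round(centroid) - size // 2`` per axis, so a
    centroid at (64, 64) with size 32 yields rows/cols [48, 80).
    """
    img = sample.image
    r, c = mask_centroid(sample.mask)
    r0 = int(np.rint(r)) - size // 2
    c0 = int(np.rint(c)) - size // 2
    pad = size  # always enough for any overhang of one window
    padded = np.pad(img, pad, mode="edge")
    out = padded[r0 + pad : r0 + pad + size, c0 + pad : c0 + pad + size]
    assert out.shape == (size, size)
    return out


def resize_bicubic(patch: np.ndarray, target: int = 224) -> np.ndarray:
    """Bicubic upscaling of a square patch to target x target."""
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square 2D")
    return _sk_resize(
        patch, (target, target), order=3, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def log_filter(image: np.ndarray, scale: LogScale) -> np.ndarray:
    """Laplacian-of-Gaussian response: Gaussian smoothing then Laplacian.

    The Gaussian is truncated so its support equals ``scale.kernel_size``;
    borders are edge-replicated, so constants map to zero everywhere.
    """
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    radius = scale.kernel_size // 2
    truncate = radius / scale.sigma
    smoothed = ndimage.gaussian_filter(
        image.astype(np.float64), scale.sigma, mode="nearest",
        truncate=truncate,
    )
    return ndimage.laplace(smoothed, mode="nearest")


def log_images(image: np.ndarray, scales=DEFAULT_LOG_SCALES) -> dict[str, np.ndarray]:
    """Apply every LoG scale; keys are ``log_<name>``."""
    return {f"log_{s.name}": log_filter(image, s) for s in scales}


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have equal shapes")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def standardize_patch(patch: np.ndarray, channels: int = 3) -> np.ndarray:
    """Min-max rescale to [0, 1] and replicate to ``channels`` (HWC).

    A constant patch maps to all zeros. Backbones here are trained from
    scratch, so no dataset-specific normalization applies.
    """
    lo = patch.min()
    rng = patch.max() - lo
    scaled = (patch - lo) / rng if rng > 0 else np.zeros_like(patch)
    return np.repeat(scaled[..., None], channels, axis=-1)


@dataclass
class PatchPair:
    """Network inputs derived from one ROI: 32x32 crop and 224x224 resize."""

    crop32: np.ndarray
    resized224: np.ndarray
    source: RoiSample


def make_patch_pair(sample: RoiSample, crop_size: int = 32,
                    target: int = 224) -> PatchPair:
    crop = crop_patch(sample, crop_size)
    return PatchPair(crop, resize_bicubic(crop, target), sample)
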
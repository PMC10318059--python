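"""Per-frame tissue / medium partition of a chamber ROI.

The analyzer segments each frame into the tissue (the FITC-filled gut
fragment, bright in the green channel) plus a safety margin, and the
extraintestinal medium (everything else). Steps per frame: green channel →
Gaussian denoise (σ=2) → Otsu threshold → keep the largest 8-connected
bright component → expand it by 8 px in every direction. Only the medium
pixels are quantified downstream, so the margin guards the medium mean
against blurred tissue edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    gaussian_sigma : std. dev. of the denoising Gaussian, pixels.
    expand_pixels : margin added around the tissue component, pixels.
    min/max_tissue_fraction : plausibility band for the expanded tissue as a
        fraction of the ROI; a frame outside the band falls back to the
        previous frame's mask (late frames can lose contrast as the medium
        brightens toward the lumen intensity).
    expand_shape : "disk" (isotropic, Euclidean distance ≤ expand_pixels) or
        "square" (Chebyshev; the literal 8-px-in-each-direction reading).
    measure_denoised : quantify medium MFI on the denoised rather than the
        raw green channel.
    """

    gaussian_sigma: float = 2.0
    expand_pixels: int = 8
    min_tissue_fraction: float = 0.02
    max_tissue_fraction: float = 0.90
    expand_shape: str = "disk"
    measure_denoised: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.expand_pixels < 0:
            raise ValueError("expand_pixels must be >= 0")
        if not 0 <= self.min_tissue_fraction < self.max_tissue_fraction <= 1:
            raise ValueError("need 0 <= min_tissue_fraction < max_tissue_fraction <= 1")
        if self.expand_shape not in ("disk", "square"):
            raise ValueError("expand_shape must be 'disk' or 'square'")


@dataclass
class TissueMask:
    """Boolean tissue(+margin) mask for one frame."""

    mask: np.ndarray
    frame_index: int = 0
    otsu_threshold: int = 0
    fallback_used: bool = False

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


def extract_green(frame: np.ndarray) -> np.ndarray:
    """Green plane of an RGB frame; grayscale frames pass through unchanged."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame[..., 1]
    raise ValueError(f"expected (H,W) or (H,W,3) frame, got shape {frame.shape}")


def denoise(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")


def quantize_levels(image: np.ndarray) -> np.ndarray:
    """8-bit grey levels used for histogram thresholds: uint8 images pass
    through; float images are clipped to [0, 255] and floored. Foreground
    membership (level > t) is defined on these levels so that thresholding
    a float image agrees exactly with its histogram."""
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.int64)
    return np.floor(np.clip(image, 0, 255)).astype(np.int64)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold on the 256-bin 8-bit histogram.

    Returns the grey level t in [0, 255] maximizing the between-class
    variance; foreground is defined as pixels strictly above t. Ties pick
    the smallest t. Float input is binned by its floor after clipping to
    [0, 255]. Raises on constant images (degenerate histogram).
    """
    hist = np.bincount(quantize_levels(image).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single grey level")
    omega = np.cumsum(hist) / total                     # P(level <= t)
    mu = np.cumsum(hist * np.arange(256)) / total       # partial mean
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer


def _largest_component(foreground: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(foreground, structure=_EIGHT_CONNECTED)
    if n == 0:
        return np.zeros_like(foreground)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))

def expand_mask(mask: np.ndarray, pixels: int, shape: str = "disk") -> np.ndarray:
    """Grow a boolean mask by ``pixels`` in every direction.

    "disk" adds every pixel within Euclidean distance ``pixels`` of the mask
    (computed with an exact distance transform, identical to dilation by a
    disk structuring element of that radius); "square" uses the Chebyshev
    distance (dilation by a (2r+1)² square).
    """
    if pixels == 0 or not mask.any():
        return mask.copy()
    if shape == "square":
        return ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool), iterations=pixels
        )
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= pixels


def segment_tissue(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    previous: TissueMask | None = None,
    frame_index: int = 0,
) -> TissueMask:
    """Segment one denoised green-channel frame into tissue(+margin).

    Otsu foreground → largest 8-connected component → expansion by
    ``expand_pixels``. If the expanded tissue fraction leaves
    [min_tissue_fraction, max_tissue_fraction], the previous frame's mask is
    reused (``fallback_used=True``); without a previous mask this is a
    segmentation failure.
    """
    image = np.asarray(image)
    try:
        t = otsu_threshold(image)
    except ValueError:
        return _fallback(previous, frame_index, "degenerate histogram")
    foreground = quantize_levels(image) > t
    tissue = _largest_component(foreground)
    expanded = expand_mask(tissue, params.expand_pixels, params.expand_shape)
    fraction = float(expanded.mean())
    if not params.min_tissue_fraction <= fraction <= params.max_tissue_fraction:
        return _fallback(
            previous,
            frame_index,
            f"tissue fraction {fraction:.3f} outside "
            f"[{params.min_tissue_fraction}, {params.max_tissue_fraction}]",
        )
    return TissueMask(
        mask=expanded, frame_index=frame_index, otsu_threshold=t, fallback_used=False
    )


def _fallback(previous: TissueMask | None, frame_index: int, reason: str) -> TissueMask:
    if previous is None:
        raise ValueError(f"segmentation failure at frame {frame_index}: {reason}")
    logger.warning("frame %d: %s; reusing previous mask", frame_index, reason)
    return TissueMask(
        mask=previous.mask.copy(),
        frame_index=frame_index,
        otsu_threshold=previous.otsu_threshold,
        fallback_used=True,
    )


def medium_mask(roi_shape: tuple[int, int], tissue: TissueMask) -> np.ndarray:
    """Extraintestinal medium = complement of the expanded tissue mask."""
    if tuple(tissue.mask.shape) != tuple(roi_shape):
        raise ValueError(
            f"shape mismatch: tissue {tissue.mask.shape} vs ROI {roi_shape}"
        )
    return ~tissue.mask
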
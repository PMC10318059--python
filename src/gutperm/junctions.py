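"""ZO-1 tight-junction intensity quantification.

Two workflows are implemented. For tissue sections, ZO-1 lives at the
epithelial periphery, so the epithelium is segmented on the E-cadherin
channel (percentile auto-threshold), holes are filled, and an edge band —
the dilated mask minus the eroded mask — isolates the crypt boundary where
mean ZO-1 (Cy3) intensity is measured. For cultured monolayers the ZO-1
channel itself is smoothed, background-subtracted with a rolling ball, Otsu
segmented, and the mean processed intensity inside the foreground reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

from .segmentation import denoise, expand_mask, otsu_threshold, quantize_levels


@dataclass(frozen=True)
class SectionParams:
    """Edge-band macro parameters (pixel counts were tuned per experiment
    type in practice and held constant within it; defaults here are the
    package's own)."""

    gaussian_sigma: float = 2.0
    percentile_p: float = 0.5
    erode_px: int = 3
    dilate_px: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.percentile_p < 1:
            raise ValueError("percentile_p must be in (0, 1)")
        if self.erode_px < 1 or self.dilate_px < 1:
            raise ValueError("erode_px and dilate_px must be >= 1")


@dataclass(frozen=True)
class CellParams:
    gaussian_sigma: float = 1.0
    rolling_ball_radius: int = 10

    def __post_init__(self) -> None:
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")


@dataclass
class BandROI:
    """Edge band: dilated segmentation AND NOT eroded segmentation."""

    band: np.ndarray

    @property
    def area_px(self) -> int:
        return int(self.band.sum())


def percentile_threshold(image: np.ndarray, p: float = 0.5) -> int:
    """Percentile auto-threshold: smallest grey level t in [0, 255] such
    that the foreground fraction (pixels > t) is <= p.

    Since the foreground fraction is non-increasing in t, this picks the
    foreground fraction closest to p from below. Raises on constant images.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    hist = np.bincount(quantize_levels(image).ravel(), minlength=256)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: percentile threshold undefined")
    n = int(hist.sum())
    count_above = n - np.cumsum(hist)  # pixels with level > t
    return int(np.argmax(count_above <= p * n))


def make_edge_band(
    ecad_image: np.ndarray, params: SectionParams = SectionParams()
) -> BandROI:
    """Edge band of the epithelium from the E-cadherin channel.

    Smooth(σ) → percentile threshold → fill holes → keep the largest
    component → band = dilate(mask, dilate_px) AND NOT erode(mask, erode_px)
    with disk structuring elements.
    """
    smooth = denoise(np.asarray(ecad_image, dtype=np.float64), params.gaussian_sigma)
    t = percentile_threshold(smooth, params.percentile_p)
    seg = quantize_levels(smooth) > t
    if not seg.any():
        raise ValueError("no tissue detected in E-cadherin segmentation")
    filled = ndimage.binary_fill_holes(seg)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3), bool))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    # disk-element dilation/erosion via the exact Euclidean distance
    # transform (erosion is the dual of dilating the complement)
    dilated = expand_mask(mask, params.dilate_px, "disk")
    eroded = ~expand_mask(~mask, params.erode_px, "disk")
    band = dilated & ~eroded
    if not band.any():
        raise ValueError("empty edge band")
    return BandROI(band=band)


def zo1_section_intensity(zo1_image: np.ndarray, band: BandROI) -> float:
    """Mean ZO-1 (Cy3) intensity over the edge-band pixels."""
    if not band.band.any():
        raise ValueError("empty band ROI")
    return float(np.asarray(zo1_image, dtype=np.float64)[band.band].mean())


def rolling_ball_subtract(image: np.ndarray, radius: int = 10) -> np.ndarray:
    """Rolling-ball background subtraction (Sternberg's sliding ball).

    The background is the surface traced by a ball of the given radius
    rolling under the intensity landscape — a grayscale opening with a
    ball-shaped element — and is subtracted from the image, clipped at 0.
    The output is everywhere >= 0 and <= the input.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    background = rolling_ball(image, radius=radius)
    return np.clip(image - background, 0, None)


def zo1_cell_intensity(
    zo1_image: np.ndarray, params: CellParams = CellParams()
) -> float:
    """Cultured-cell ZO-1 workflow: smooth(σ=1) → rolling-ball(10) → Otsu →
    mean processed intensity within the foreground.

    The rolling-ball step removes any constant (or slowly varying)
    background, so the result is invariant to a uniform offset of the
    input. Raises on images that are featureless after preprocessing.
    """
    smooth = denoise(np.asarray(zo1_image, dtype=np.float64), params.gaussian_sigma)
    processed = rolling_ball_subtract(smooth, params.rolling_ball_radius)
    try:
        t = otsu_threshold(processed)
    except ValueError as exc:
        raise ValueError("degenerate ZO-1 image after preprocessing") from exc
    mask = quantize_levels(processed) > t
    if not mask.any():
        raise ValueError("empty ZO-1 foreground")
    return float(processed[mask].mean())
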
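"""Permeability read-outs from chamber movies.

The assay's dynamic readout is the mean fluorescence intensity (MFI) of the
extraintestinal medium over time: tracer crossing the epithelial barrier
brightens the medium, and the fitted linear slope m of the normalized MFI
trace (fold change over the t=0 frame, per hour) is the permeability rate.
Endpoint MFI and fluorometer concentrations are compared as treated/control
ratios; a spatial profile along the tissue's major axis screens for tracer
leaking at the input/output ports rather than across the barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import TimeLapseStack
from .segmentation import (
    SegmentationParams,
    TissueMask,
    denoise,
    extract_green,
    medium_mask,
    segment_tissue,
)


@dataclass
class PermeabilityTrace:
    """Normalized medium-MFI time trace for one chamber."""

    chamber_id: str
    condition: str
    times_hours: np.ndarray
    raw_mfi: np.ndarray
    n_fallback_frames: int = 0
    final_tissue: TissueMask | None = None  # mask of the last analyzed frame

    def __post_init__(self) -> None:
        self.times_hours = np.asarray(self.times_hours, dtype=float)
        self.raw_mfi = np.asarray(self.raw_mfi, dtype=float)
        if self.times_hours.shape != self.raw_mfi.shape:
            raise ValueError("times and MFI must have equal length")
        if self.raw_mfi.size and self.raw_mfi[0] <= 0:
            raise ValueError("baseline (t=0) MFI must be positive for normalization")

    @property
    def normalized_mfi(self) -> np.ndarray:
        """Fold change over the t=0 frame; element 0 is exactly 1."""
        return self.raw_mfi / self.raw_mfi[0]


@dataclass(frozen=True)
class SlopeFit:
    """OLS line of normalized MFI vs time; m is in normalized MFI per hour."""

    m: float
    intercept: float
    r_squared: float
    n_frames: int


@dataclass(frozen=True)
class EndpointSummary:
    """Treated/control ratios of endpoint image MFI and fluorometer O.D."""

    mfi_ratio: float
    od_ratio: float


@dataclass(frozen=True)
class LeakReport:
    """Axial MFI profile of the final frame and the port-leak verdict."""

    n_bins: int
    bin_mfi: np.ndarray
    leak_flag: bool
    leak_bin: int | None
    threshold_factor: float


def frame_mfi(image: np.ndarray, medium: np.ndarray) -> float:
    """Mean green intensity over the medium pixels of one frame."""
    medium = np.asarray(medium, dtype=bool)
    if not medium.any():
        raise ValueError("no medium pixels in mask")
    return float(np.asarray(image, dtype=np.float64)[medium].mean())


def compute_trace(
    stack: TimeLapseStack,
    params: SegmentationParams = SegmentationParams(),
) -> PermeabilityTrace:
    """Full per-frame chain: green → denoise → segment → medium mask → MFI.

    Segmentation runs on the denoised image; the MFI is measured on the raw
    green channel (or the denoised one if ``params.measure_denoised``).
    Frames whose segmentation is implausible reuse the previous frame's
    mask; failure on frame 0 aborts since there is no baseline to fall
    back on.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames")
    mfis = []
    previous: TissueMask | None = None
    n_fallback = 0
    for k in range(stack.n_frames):
        green = extract_green(stack.frame(k)).astype(np.float64)
        smooth = denoise(green, params.gaussian_sigma)
        try:
            tissue = segment_tissue(smooth, params, previous=previous, frame_index=k)
        except ValueError as exc:
            if k == 0:
                raise ValueError(f"baseline segmentation failed: {exc}") from exc
            raise
        medium = medium_mask(green.shape, tissue)
        measured = smooth if params.measure_denoised else green
        mfis.append(frame_mfi(measured, medium))
        n_fallback += int(tissue.fallback_used)
        previous = tissue
    return PermeabilityTrace(
        chamber_id=stack.chamber_id,
        condition=stack.condition,
        times_hours=stack.times_hours,
        raw_mfi=np.array(mfis),
        n_fallback_frames=n_fallback,
        final_tissue=previous,
    )


def fit_slope(trace: PermeabilityTrace) -> SlopeFit:
    """Unweighted OLS of normalized MFI against time (hours)."""
    y = trace.normalized_mfi
    t = trace.times_hours
    if t.size < 3:
        raise ValueError("insufficient frames: need >= 3 time points")
    if np.ptp(y) == 0:  # perfectly flat trace: zero slope, zero residuals
        return SlopeFit(m=0.0, intercept=float(y[0]), r_squared=1.0, n_frames=t.size)
    res = stats.linregress(t, y)
    return SlopeFit(
        m=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_frames=t.size,
    )


def summarize_condition(fits: list[SlopeFit]) -> tuple[float, float]:
    """Mean and sample SD of m across replicate chambers; SD=0 at n=1."""
    if not fits:
        raise ValueError("no slope fits to summarize")
    slopes = np.array([f.m for f in fits])
    if slopes.size == 1:
        warnings.warn("single replicate: SD undefined, reporting 0", stacklevel=2)
        return float(slopes[0]), 0.0
    return float(slopes.mean()), float(slopes.std(ddof=1))


def endpoint_ratios(
    treated_final_mfi_norm: float,
    ctrl_final_mfi_norm: float,
    treated_conc: float,
    ctrl_conc: float,
) -> EndpointSummary:
    """Treated-over-control endpoint ratios (image MFI and fluorometer µg/mL)."""
    if ctrl_final_mfi_norm <= 0 or ctrl_conc <= 0:
        raise ValueError("control values must be positive")
    return EndpointSummary(
        mfi_ratio=treated_final_mfi_norm / ctrl_final_mfi_norm,
        od_ratio=treated_conc / ctrl_conc,
    )


def _principal_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Unit major axis of a boolean mask from PCA of its pixel coordinates.

    Returns (centroid, unit axis, eigenvalue ratio major/minor).
    """
    coords = np.argwhere(mask).astype(np.float64)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axis = evecs[:, -1]
    minor = max(evals[0], 1e-12)
    return centroid, axis, float(evals[-1] / minor)


def leak_profile(
    stack: TimeLapseStack,
    final_tissue: TissueMask,
    n_bins: int = 10,
    threshold_factor: float = 2.0,
) -> LeakReport:
    """Bin the final frame's medium MFI along the tissue's major axis.

    Tracer entering through a port pools at one tissue end, so a genuine
    transepithelial signal is axially flat while a port leak spikes in an
    end bin. ``leak_flag`` is raised when an end bin exceeds
    ``threshold_factor`` times the median bin MFI. A near-isotropic tissue
    mask (axis undefined) falls back to the ROI's long side.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    final = extract_green(stack.frame(stack.n_frames - 1)).astype(np.float64)
    medium = medium_mask(final.shape, final_tissue)
    if final_tissue.mask.any():
        centroid, axis, elongation = _principal_axis(final_tissue.mask)
    else:
        elongation = 1.0
    if not final_tissue.mask.any() or elongation < 1.5:
        warnings.warn(
            "near-circular tissue mask: using the ROI's long side as axis",
            stacklevel=2,
        )
        h, w = final.shape
        axis = np.array([0.0, 1.0]) if w >= h else np.array([1.0, 0.0])
        centroid = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    coords = np.argwhere(medium).astype(np.float64)
    proj = (coords - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    # right-closed bins; the top edge folds into the last bin
    idx = np.clip(((proj - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    values = final[medium]
    bin_mfi = np.array(
        [values[idx == b].mean() if np.any(idx == b) else np.nan for b in range(n_bins)]
    )
    median = float(np.nanmedian(bin_mfi))
    leak_flag = False
    leak_bin: int | None = None
    for end in (0, n_bins - 1):
        if np.isfinite(bin_mfi[end]) and bin_mfi[end] > threshold_factor * median:
            if leak_bin is None or bin_mfi[end] > bin_mfi[leak_bin]:
                leak_flag, leak_bin = True, end
    return LeakReport(
        n_bins=n_bins,
        bin_mfi=bin_mfi,
        leak_flag=leak_flag,
        leak_bin=leak_bin,
        threshold_factor=threshold_factor,
    )
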
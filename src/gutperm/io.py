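"""Reading and writing of time-lapse stacks and tabular inputs.

A chamber movie is an ordered sequence of 8-bit frames (grayscale or RGB)
acquired at a fixed interval. Movies arrive either as a multi-page TIFF or
as a directory of single-frame PNG/TIFF files; frame order is page order or
a natural (zero-padding aware) filename sort.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}

FLUOROMETER_COLUMNS = ["sample_id", "condition", "concentration_ug_per_ml"]
TEER_COLUMNS = ["time_min", "well", "z_1khz_ohm", "z_41khz_ohm", "condition"]


@dataclass(frozen=True)
class ChamberROI:
    """Half-open rectangle [row0, row0+height) x [col0, col0+width), 0-based."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive height and width")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


@dataclass
class TimeLapseStack:
    """Ordered frames for one chamber with a fixed acquisition interval.

    ``frames`` has shape (T, H, W) for grayscale or (T, H, W, 3) for RGB.
    Values lie in [0, 255]; the dtype is uint8 for real acquisitions but may
    be float for synthetic phantoms that carry sub-grey-level precision.
    """

    frames: np.ndarray
    interval_minutes: float
    chamber_id: str = ""
    source_path: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (T,H,W,3)")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError("colour frames must have exactly 3 planes")
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")
        fmin = float(self.frames.min()) if self.frames.size else 0.0
        fmax = float(self.frames.max()) if self.frames.size else 0.0
        if fmin < 0 or fmax > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times_hours(self) -> np.ndarray:
        """Acquisition times in hours; frame k is at k*interval/60, starting at 0."""
        return np.arange(self.n_frames) * (self.interval_minutes / 60.0)

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return tuple(self.frames.shape[1:])

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


def _natural_key(name: str) -> tuple:
    """Lexicographic sort key with zero-padding-aware numeric runs."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_uint8(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    logger.warning("rescaling non-8-bit input (%s, dtype=%s) to 8-bit", source, arr.dtype)
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def load_stack(
    path: str | Path, interval_minutes: float, chamber_id: str = ""
) -> TimeLapseStack:
    """Load a movie from a multi-page TIFF or a directory of frame files.

    Frames are ordered by TIFF page order, or by a natural filename sort for
    directories. Non-8-bit input is min-max rescaled to 8-bit with a logged
    warning. Raises ``ValueError`` on empty input ("no frames") or frames of
    differing geometry ("geometry mismatch").
    """
    path = Path(path)
    frames: list[np.ndarray]
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in _FRAME_SUFFIXES),
            key=lambda f: _natural_key(f.name),
        )
        frames = [np.asarray(iio.imread(f)) for f in files]
    elif path.is_file():
        frames = _read_tiff_pages(path)
    else:
        raise FileNotFoundError(f"no such input: {path}")
    if not frames:
        raise ValueError(f"no frames found in {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"geometry mismatch across frames in {path}: {sorted(shapes)}")
    stacked = np.stack([_to_uint8(f, str(path)) for f in frames])
    # RGBA from PNG loaders: drop the alpha plane
    if stacked.ndim == 4 and stacked.shape[-1] == 4:
        stacked = stacked[..., :3]
    return TimeLapseStack(
        frames=stacked,
        interval_minutes=interval_minutes,
        chamber_id=chamber_id,
        source_path=str(path),
    )


def _read_tiff_pages(path: Path) -> list[np.ndarray]:
    with tifffile.TiffFile(path) as tf:
        return [page.asarray() for page in tf.pages]


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a stack as a multi-page 8-bit TIFF (lossless round trip)."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint8:
        frames = np.round(np.clip(frames, 0, 255)).astype(np.uint8)
    photometric = "rgb" if frames.ndim == 4 else "minisblack"
    tifffile.imwrite(path, frames, photometric=photometric)
    return path


def crop_chamber(
    stack: TimeLapseStack, roi: ChamberROI, chamber_id: str = ""
) -> TimeLapseStack:
    """Crop every frame to ``roi``; two disjoint ROIs split a camera field
    into its two chambers. Raises ``ValueError`` if the ROI leaves the frame.
    """
    h, w = stack.frames.shape[1:3]
    if roi.row0 + roi.height > h or roi.col0 + roi.width > w:
        raise ValueError(
            f"ROI out of frame: roi={roi} vs frame {h}x{w}"
        )
    rs, cs = roi.slices
    return replace(
        stack,
        frames=stack.frames[:, rs, cs].copy(),
        chamber_id=chamber_id or stack.chamber_id,
    )


def read_fluorometer_csv(path: str | Path) -> pd.DataFrame:
    """Endpoint fluorometer table: sample_id, condition, concentration_ug_per_ml."""
    df = pd.read_csv(path)
    missing = [c for c in FLUOROMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fluorometer table missing columns: {missing}")
    return df


def read_teer_csv(path: str | Path) -> pd.DataFrame:
    """Two-frequency impedance table: time_min, well, z_1khz_ohm, z_41khz_ohm, condition."""
    df = pd.read_csv(path)
    missing = [c for c in TEER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TEER table missing columns: {missing}")
    return df


def read_config(path: str | Path) -> dict:
    """Load a run configuration from YAML or JSON (YAML is a JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config must be a mapping: {path}")
    return cfg
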
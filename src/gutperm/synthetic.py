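"""Phantom generators with known ground truth for every analysis stage.

The permeability phantom emulates what the camera sees in a culture
chamber: a bright capsule-shaped tissue (FITC-filled lumen) lying on a dim
medium whose green intensity rises linearly in time as tracer crosses the
barrier — medium(t) = baseline · (1 + m·t) — plus Gaussian camera noise and
an optional port-leak blob growing at one tissue end. Section and TEER
phantoms follow the same pattern: a parametric scene plus the exact truth
the analyzers should recover.

All randomness flows from the explicit seed in each spec; the same spec
generates bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import TimeLapseStack


@dataclass(frozen=True)
class Capsule:
    """Stadium-shaped tissue: a segment of half-length ``half_length`` along
    the row ``center_row``, thickened to ``radius``."""

    center_row: int = 120
    center_col: int = 240
    half_length: int = 180
    radius: int = 40


@dataclass(frozen=True)
class PortLeak:
    """Tracer pooling at a luminal port: an anisotropic Gaussian pool just
    beyond one tissue end (end 0 = low-column, 1 = high-column), growing
    linearly in time to ``amplitude`` grey levels. The pool is narrow along
    the tissue axis and spread perpendicular to it, the way liquid collects
    against the chamber end wall."""

    end: int = 1
    amplitude: float = 60.0
    sigma_axial_px: float = 20.0
    sigma_lateral_px: float = 80.0
    offset_px: float = 10.0


@dataclass(frozen=True)
class MovieSpec:
    """Parametric description of one synthetic chamber movie.

    Defaults give a 240x480 px chamber whose 8-bit histogram Otsu separates
    cleanly at t=0 (medium 20 vs lumen 220) with headroom below 255 for an
    8-h ramp at the steepest rates of interest. ``quantize=False`` keeps
    float frames (still clipped to [0, 255]) for noiseless exactness tests.
    """

    height: int = 240
    width: int = 480
    duration_hours: float = 8.0
    interval_minutes: float = 15.0
    capsule: Capsule = field(default_factory=Capsule)
    lumen_intensity: float = 220.0
    medium_baseline: float = 20.0
    true_slope_per_hour: float = 0.0
    noise_sigma: float = 2.0
    port_leak: PortLeak | None = None
    seed: int = 0
    rgb: bool = True
    quantize: bool = True
    allow_clipping: bool = False


@dataclass
class GroundTruth:
    """What the analyzers should recover from a phantom."""

    true_medium_mean: np.ndarray
    true_slope_per_hour: float
    leak_end: int | None = None
    clipped: bool = False


def _capsule_mask(spec: MovieSpec) -> np.ndarray:
    cap = spec.capsule
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    dcol = np.clip(np.abs(cols - cap.center_col) - cap.half_length, 0, None)
    drow = rows - cap.center_row
    return dcol**2 + drow**2 <= cap.radius**2


def _leak_center(spec: MovieSpec, leak: PortLeak) -> tuple[float, float]:
    cap = spec.capsule
    reach = cap.half_length + cap.radius + leak.offset_px
    col = cap.center_col - reach if leak.end == 0 else cap.center_col + reach
    return float(cap.center_row), float(col)


def generate_movie(spec: MovieSpec) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a phantom movie and its ground truth.

    Medium pixels follow baseline·(1 + m·t_hours); the capsule holds the
    lumen intensity; noise is additive Gaussian per pixel; frames are
    clipped to [0, 255] and, by default, rounded to 8 bits. A spec whose
    noiseless medium would exceed 255 raises "dynamic-range overflow"
    unless ``allow_clipping`` is set (the truth then records the clipping).
    """
    if spec.medium_baseline <= 0:
        raise ValueError("medium_baseline must be positive")
    n_frames = int(round(spec.duration_hours * 60.0 / spec.interval_minutes)) + 1
    times = np.arange(n_frames) * spec.interval_minutes / 60.0
    final_medium = spec.medium_baseline * (1.0 + spec.true_slope_per_hour * times[-1])
    would_clip = final_medium > 255 or spec.lumen_intensity > 255
    if would_clip and not spec.allow_clipping:
        raise ValueError(
            f"dynamic-range overflow: noiseless medium reaches {final_medium:.1f} "
            "grey levels (set allow_clipping to generate anyway)"
        )
    capsule = _capsule_mask(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.port_leak is not None:
        lr, lc = _leak_center(spec, spec.port_leak)
        rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
        leak_shape = np.exp(
            -((cols - lc) ** 2) / (2.0 * spec.port_leak.sigma_axial_px**2)
            - ((rows - lr) ** 2) / (2.0 * spec.port_leak.sigma_lateral_px**2)
        )
    frames = np.empty(
        (n_frames, spec.height, spec.width, 3) if spec.rgb else (n_frames, spec.height, spec.width),
        dtype=np.uint8 if spec.quantize else np.float64,
    )
    true_medium = spec.medium_baseline * (1.0 + spec.true_slope_per_hour * times)
    for k, t in enumerate(times):
        green = np.where(capsule, spec.lumen_intensity, true_medium[k]).astype(np.float64)
        if spec.port_leak is not None and spec.duration_hours > 0:
            green += spec.port_leak.amplitude * (t / spec.duration_hours) * leak_shape
        if spec.noise_sigma > 0:
            green += rng.normal(0.0, spec.noise_sigma, size=green.shape)
        green = np.clip(green, 0.0, 255.0)
        if spec.quantize:
            green = np.round(green)
        if spec.rgb:
            frames[k] = 0
            frames[k, ..., 1] = green
        else:
            frames[k] = green
    truth = GroundTruth(
        true_medium_mean=true_medium,
        true_slope_per_hour=spec.true_slope_per_hour,
        leak_end=spec.port_leak.end if spec.port_leak else None,
        clipped=bool(would_clip),
    )
    stack = TimeLapseStack(
        frames=frames,
        interval_minutes=spec.interval_minutes,
        chamber_id=f"phantom-seed{spec.seed}",
        source_path="synthetic",
    )
    return stack, truth


def generate_dose_series(
    base: MovieSpec, slopes: list[float]
) -> list[tuple[TimeLapseStack, GroundTruth]]:
    """One movie per programmed slope, sharing geometry and noise level;
    replicate k uses seed base.seed + k."""
    if any(s < 0 for s in slopes):
        raise ValueError("slopes must be non-negative")
    return [
        generate_movie(replace(base, true_slope_per_hour=m, seed=base.seed + k))
        for k, m in enumerate(slopes)
    ]


@dataclass(frozen=True)
class SectionSpec:
    """Synthetic crypt cross-section: an E-cadherin-filled body (disk, or
    ring with a lumen hole) with ZO-1 confined to a thin boundary shell."""

    height: int = 160
    width: int = 160
    geometry: str = "disk"  # or "ring"
    radius: int = 50
    inner_radius: int = 25  # ring lumen radius
    zo1_amplitude: float = 100.0
    shell_width: int = 2
    ecad_intensity: float = 120.0
    background: float = 5.0  # E-cadherin off-tissue level
    zo1_background: float = 0.0  # ZO-1 is absent away from junctions
    noise_sigma: float = 0.0
    seed: int = 0
    quantize: bool = True


@dataclass
class SectionTruth:
    boundary_mask: np.ndarray
    zo1_amplitude: float
    body_fraction: float  # epithelium area fraction; the percentile target
    outer_radius: float
    center: tuple[float, float]


def generate_section_image(
    spec: SectionSpec,
) -> tuple[np.ndarray, np.ndarray, SectionTruth]:
    """Returns (zo1_image, ecad_image, truth).

    ZO-1 sits on the shell of pixels within ``shell_width`` inside the outer
    boundary; E-cadherin fills the body. The ring geometry leaves a lumen
    hole in the E-cadherin channel (the section macro is expected to fill
    it and band only the outer contour).
    """
    if spec.geometry not in ("disk", "ring"):
        raise ValueError("geometry must be 'disk' or 'ring'")
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width]
    cr, cc = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    d = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
    body = d <= spec.radius
    if spec.geometry == "ring":
        body &= d > spec.inner_radius
    shell = (d <= spec.radius) & (d > spec.radius - spec.shell_width)
    rng = np.random.default_rng(spec.seed)
    ecad = np.where(body, spec.ecad_intensity, spec.background).astype(np.float64)
    zo1 = np.where(
        shell, spec.zo1_background + spec.zo1_amplitude, spec.zo1_background
    ).astype(np.float64)
    if spec.noise_sigma > 0:
        ecad += rng.normal(0, spec.noise_sigma, ecad.shape)
        zo1 += rng.normal(0, spec.noise_sigma, zo1.shape)
    ecad = np.clip(ecad, 0, 255)
    zo1 = np.clip(zo1, 0, 255)
    if spec.quantize:
        ecad = np.round(ecad).astype(np.uint8)
        zo1 = np.round(zo1).astype(np.uint8)
    truth = SectionTruth(
        boundary_mask=shell,
        zo1_amplitude=spec.zo1_amplitude,
        body_fraction=float(body.mean()),
        outer_radius=float(spec.radius),
        center=(cr, cc),
    )
    return zo1, ecad, truth


@dataclass(frozen=True)
class TeerSpec:
    """Synthetic two-frequency impedance experiment.

    Stimulated wells' barrier index declines linearly from ``onset_min``
    to ``drop_fraction`` below baseline at the end of the recording;
    impedances carry multiplicative Gaussian noise of ``noise_cv``.
    """

    n_control: int = 3
    n_stimulated: int = 3
    duration_min: int = 240
    interval_min: int = 1
    baseline_index: float = 2.0
    z_high_ohm: float = 500.0
    drop_fraction: float = 0.5
    onset_min: int = 60
    noise_cv: float = 0.005
    seed: int = 0


@dataclass
class TeerTruth:
    drop_fraction: float
    onset_min: int
    control_wells: list[str]
    stimulated_wells: list[str]


def generate_teer_table(spec: TeerSpec) -> tuple[pd.DataFrame, TeerTruth]:
    """Tidy two-frequency impedance table plus its programmed truth."""
    if not 0 <= spec.drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0, spec.duration_min + 1, spec.interval_min, dtype=float)
    ctrl_wells = [f"C{i + 1}" for i in range(spec.n_control)]
    stim_wells = [f"S{i + 1}" for i in range(spec.n_stimulated)]
    span = max(times[-1] - spec.onset_min, 1.0)
    decline = 1.0 - spec.drop_fraction * np.clip(times - spec.onset_min, 0, None) / span
    rows = []
    for well, stimulated in [(w, False) for w in ctrl_wells] + [
        (w, True) for w in stim_wells
    ]:
        index = spec.baseline_index * (decline if stimulated else np.ones_like(times))
        z_high = spec.z_high_ohm * (1 + rng.normal(0, spec.noise_cv, times.size))
        z_low = index * spec.z_high_ohm * (1 + rng.normal(0, spec.noise_cv, times.size))
        rows.append(
            pd.DataFrame(
                {
                    "time_min": times,
                    "well": well,
                    "z_1khz_ohm": z_low,
                    "z_41khz_ohm": z_high,
                    "condition": "stimulated" if stimulated else "unstimulated",
                }
            )
        )
    truth = TeerTruth(
        drop_fraction=spec.drop_fraction,
        onset_min=spec.onset_min,
        control_wells=ctrl_wells,
        stimulated_wells=stim_wells,
    )
    return pd.concat(rows, ignore_index=True), truth


def generate_endpoint_series(
    concentrations_ug_per_ml: np.ndarray,
    ctrl_concentration: float = 10.0,
    grey_per_ug_per_ml: float = 1.0,
    duration_hours: float = 2.0,
    interval_minutes: float = 15.0,
    noise_sigma: float = 2.0,
    od_noise_cv: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Movies whose endpoint medium maps to known tracer concentrations.

    Each movie's medium ramps from the baseline to baseline +
    gain·concentration at the final frame; a simulated fluorometer reads
    the true endpoint concentration with multiplicative Gaussian noise.
    Returns one row per movie (plus the control) with the spec, the stack
    index, the true concentration and the noisy fluorometer reading —
    callers run the image analyzer on the stacks to obtain MFI ratios.
    """
    rng = np.random.default_rng(seed)
    concs = np.asarray(concentrations_ug_per_ml, dtype=float)
    rows = []
    for i, conc in enumerate(np.concatenate([[ctrl_concentration], concs])):
        baseline = 20.0
        final_grey = baseline + grey_per_ug_per_ml * conc
        slope = (final_grey / baseline - 1.0) / duration_hours
        spec = MovieSpec(
            duration_hours=duration_hours,
            interval_minutes=interval_minutes,
            medium_baseline=baseline,
            true_slope_per_hour=slope,
            noise_sigma=noise_sigma,
            seed=seed + i,
        )
        stack, truth = generate_movie(spec)
        rows.append(
            {
                "role": "control" if i == 0 else "sample",
                "true_concentration_ug_per_ml": conc,
                "fluorometer_ug_per_ml": conc * (1 + rng.normal(0, od_noise_cv)),
                "stack": stack,
                "truth": truth,
            }
        )
    return pd.DataFrame(rows)
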
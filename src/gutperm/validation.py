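"""Closed-loop recovery experiments: generator → analyzer → ground truth.

The assay's real readouts (condition slopes, endpoint-ratio correlation)
come from ex vivo tissue and cannot be recomputed from code alone, so the
package validates itself by programming those readouts into phantoms and
checking that the full analysis chain recovers them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calibration import correlate_endpoints
from .permeability import compute_trace, fit_slope, summarize_condition
from .synthetic import MovieSpec, generate_endpoint_series, generate_movie


def recover_slope(
    true_slope_per_hour: float,
    duration_hours: float,
    interval_minutes: float,
    seeds: list[int],
    noise_sigma: float = 2.0,
) -> tuple[float, float, list[float]]:
    """Mean and SD of the fitted slope over seeded replicate phantom movies.

    Each replicate renders a default-geometry chamber movie with the given
    ramp rate, runs segmentation, trace extraction and OLS fitting, and the
    fits are pooled like replicate chambers of one condition.
    """
    fits = []
    for seed in seeds:
        spec = MovieSpec(
            duration_hours=duration_hours,
            interval_minutes=interval_minutes,
            true_slope_per_hour=true_slope_per_hour,
            noise_sigma=noise_sigma,
            seed=seed,
        )
        stack, _ = generate_movie(spec)
        fits.append(fit_slope(compute_trace(stack)))
    mean, sd = summarize_condition(fits)
    return mean, sd, [f.m for f in fits]


def recover_dose_series(
    slopes: list[float],
    duration_hours: float = 4.0,
    interval_minutes: float = 10.0,
    seed: int = 0,
    noise_sigma: float = 2.0,
) -> list[float]:
    """Recovered slope for each member of a programmed dose series."""
    from .synthetic import generate_dose_series

    base = MovieSpec(
        duration_hours=duration_hours,
        interval_minutes=interval_minutes,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return [
        fit_slope(compute_trace(stack)).m
        for stack, _ in generate_dose_series(base, slopes)
    ]


def endpoint_ratio_correlation(
    n_samples: int = 12,
    conc_low: float = 1.0,
    conc_high: float = 100.0,
    od_noise_cv: float = 0.02,
    seed: int = 42,
) -> float:
    """R² between image MFI ratios and fluorometer O.D ratios.

    Simulates movies whose endpoint medium maps to concentrations
    log-spaced over the assay's dynamic range, plus a control movie; the
    image route measures final normalized MFI ratios against the control,
    the fluorometer route reads the true concentrations with multiplicative
    noise, and the two ratio series are correlated.
    """
    concs = np.geomspace(conc_low, conc_high, n_samples)
    table = generate_endpoint_series(concs, od_noise_cv=od_noise_cv, seed=seed)
    final_norm = []
    for stack in table["stack"]:
        trace = compute_trace(stack)
        final_norm.append(trace.normalized_mfi[-1])
    final_norm = np.asarray(final_norm)
    ctrl = table["role"] == "control"
    mfi_ratios = final_norm[~ctrl.to_numpy()] / final_norm[ctrl.to_numpy()][0]
    od = table["fluorometer_ug_per_ml"].to_numpy()
    od_ratios = od[~ctrl.to_numpy()] / od[ctrl.to_numpy()][0]
    return correlate_endpoints(mfi_ratios, od_ratios)
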
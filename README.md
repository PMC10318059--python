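# gutperm

Quantification of intestinal barrier function in ex vivo gut organ
cultures, for labs that perfuse a fluorescent tracer (FITC-dextran) into
the lumen of an intact cultured gut fragment and watch the surrounding
medium brighten as tracer crosses the epithelium.

The package reimplements, as a tested Python library plus CLI, the three
quantification workflows such experiments need:

1. **Time-lapse permeability analysis.** Each chamber movie is reduced to
   a mean-fluorescence-intensity (MFI) trace of the *extraintestinal
   medium*: per frame, the green channel is Gaussian-denoised (σ = 2),
   the tissue is segmented by Otsu's threshold, the largest connected
   component is expanded by 8 px as a safety margin, and the mean grey
   value of the remaining medium pixels is recorded. Traces are
   normalized to their t = 0 value and summarized by the ordinary
   least-squares slope

   &nbsp;&nbsp;&nbsp;&nbsp;MFI(t)/MFI(0) ≈ 1 + m·t,

   where the permeability rate *m* (per hour) is the assay's dynamic
   readout. Endpoint MFI and fluorometer concentrations are compared as
   treated/control ratios; a profile of the final frame's medium MFI
   along the tissue's major axis screens for tracer leaking at the
   input/output ports rather than across the barrier. A linear standard
   curve maps MFI to concentration over the assay's 1–100 µg/mL dynamic
   range.

2. **ZO-1 tight-junction intensity.** For tissue sections, the
   epithelium is segmented on an E-cadherin channel (percentile
   auto-threshold), holes are filled, and an edge band — the dilated
   mask minus the eroded mask — isolates the crypt periphery where mean
   ZO-1 intensity is measured. For cultured monolayers, the ZO-1 channel
   is smoothed (σ = 1), rolling-ball background-subtracted (radius 10),
   Otsu-segmented, and the masked mean reported.

3. **TEER barrier index.** From two-frequency impedance tables, the
   barrier index z(1 kHz)/z(41 kHz) is normalized to its t = 0 baseline
   and then to the mean of the unstimulated control wells.

Because real tissue readouts cannot be regenerated from code, the package
ships a first-class synthetic phantom generator (`gutperm.synthetic`):
chamber movies with a capsule-shaped "tissue" on a medium whose intensity
ramps linearly at a programmed rate *m*, with camera noise, port-leak
artifacts and multi-chamber layouts; crypt-section images with
edge-localized junction signal; and two-frequency impedance tables with a
programmed barrier drop. Every analyzer is validated closed-loop against
these ground truths.

## Worked example

```python
from gutperm import MovieSpec, generate_movie, compute_trace, fit_slope

# a 2-h movie at 5-min frames whose medium brightens at m = 0.75/h
spec = MovieSpec(true_slope_per_hour=0.75, duration_hours=2.0,
                 interval_minutes=5.0, noise_sigma=2.0, seed=1)
stack, truth = generate_movie(spec)

trace = compute_trace(stack)          # green -> denoise -> Otsu -> medium MFI
fit = fit_slope(trace)                # OLS of normalized MFI vs hours
print(f"frames: {stack.n_frames}, baseline MFI: {trace.raw_mfi[0]:.2f}")
print(f"final normalized MFI: {trace.normalized_mfi[-1]:.3f}")
print(f"fitted slope m = {fit.m:.4f} per hour (R^2 = {fit.r_squared:.4f})")
```

prints

```
frames: 25, baseline MFI: 19.99
final normalized MFI: 2.501
fitted slope m = 0.7505 per hour (R^2 = 1.0000)
```

i.e. the analyzer recovers the programmed permeability rate (0.75/h) from
the noisy 8-bit movie to within half a percent; the medium has risen
2.5-fold over two hours.

The CLI mirrors the library: `gutperm analyze run.yaml` processes a whole
six-chamber device from a config mapping camera movies to chamber ROIs
and conditions; `gutperm simulate` writes phantoms; `gutperm calibrate`,
`gutperm zo1` and `gutperm teer` run the standard-curve, junction and
impedance workflows.

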
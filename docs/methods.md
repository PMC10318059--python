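# Methods

## Time-lapse permeability analysis

### Model

A gut fragment is tied over luminal ports inside a culture chamber and
perfused with FITC-dextran; the chamber is imaged from above at a fixed
interval (5-min frames for 2-h experiments, 10-min for 4-h, 15-min for
8-h; six chambers per device, two chambers per camera field). Tracer that
crosses the epithelial barrier accumulates in the surrounding
(extraintestinal) medium, so the medium's mean green intensity is a
proxy for cumulative permeation. Over the durations of interest the
observed traces are close to linear, and the analysis model is purely
phenomenological:

    MFI(t) / MFI(0) = 1 + m·t + ε(t)

with t in hours. The fitted slope m ("permeability rate", per hour) is
the readout; no diffusion mechanism is modelled.

### Per-frame segmentation

Each frame is reduced to a tissue/medium partition:

1. green channel of the RGB frame (grayscale input is taken as the green
   channel directly);
2. Gaussian denoise, σ = 2 px, reflective boundaries;
3. Otsu threshold on the 256-bin 8-bit histogram (ties broken toward the
   smallest threshold; float images are binned by their floored clipped
   value, and foreground membership is defined on those same quantized
   levels so that thresholding agrees exactly with the histogram);
4. largest 8-connected above-threshold component = tissue;
5. expansion by 8 px: implemented as an exact Euclidean distance
   transform (equivalent to dilation by a disk of radius 8), with the
   literal "8 px in each direction" Chebyshev reading available via
   `expand_shape="square"`;
6. medium = complement of the expanded tissue.

Segmentation is recomputed per frame. The tissue is taken as the bright
Otsu class, correct early in the experiment when the FITC-filled lumen
dominates; in late frames of strongly leaking preparations the medium
can approach the lumen intensity and the Otsu split becomes meaningless.
A plausibility band on the expanded tissue fraction (default 2–90 % of
the ROI) catches this: an implausible frame reuses the previous frame's
mask and is flagged (`fallback_used`). A failure on frame 0 aborts the
chamber, since normalization needs a trustworthy baseline.

MFI is measured on the **raw** green channel; the denoised image is used
only to segment. Measuring on the denoised image would blend a small,
time-constant fraction of lumen intensity into the medium mean near the
mask boundary; the margin makes the effect tiny, but on raw pixels the
noiseless closed loop is exact to machine precision, which the test
suite exploits. A `measure_denoised` switch restores the alternative.

### Traces, slopes, ratios

Traces are normalized by their t = 0 MFI (fold change); slopes are
unweighted OLS over all frames, in normalized MFI per hour. Replicate
chambers of one condition are summarized by mean ± sample SD. Endpoint
comparisons divide a treated chamber's final normalized MFI (and its
fluorometer concentration) by the mean over control chambers of the same
device. A perfectly flat trace gets r² = 1 by convention (the fit has
zero residual); the slope is exactly 0.

### Port-leak screening

Tracer entering through a port pools at one tissue end rather than
rising uniformly. The screen bins the final frame's medium pixels by
their coordinate along the tissue's major axis (principal axis of the
mask's pixel coordinates; if the mask is nearly isotropic — eigenvalue
ratio < 1.5 — the ROI's long side is used with a warning), computes the
mean MFI of each of the 10 bins, and flags a leak when an end bin
exceeds 2× the median bin. Both parameters are package defaults chosen
for the default chamber geometry and are configurable.

### Calibration

Image MFI is linear in tracer concentration across the assay's dynamic
range (1–100 µg/mL), so the standard curve is an OLS line MFI = a·c + b;
inversion flags extrapolation outside the range. Agreement between
image ratios and fluorometer ratios is summarized as squared Pearson
correlation.

## ZO-1 quantification

**Sections.** The epithelium is segmented on the E-cadherin channel:
Gaussian smooth (σ = 2), percentile auto-threshold (smallest grey level
whose foreground fraction drops to the target p, the classic
50 %-foreground rule by default), binary hole filling, largest-component
selection. The edge band is `dilate(mask, 3 px) AND NOT erode(mask, 3 px)`
with disk elements (erosion computed as the dual of dilating the
complement, so both use the same exact distance transform); mean ZO-1
intensity over the band is reported together with the band area. The
erode/dilate counts — like the originals, which were tuned per
experiment type and then frozen — are configurable; 3/3 are package
defaults. On phantoms, the percentile target is set to the phantom's
known epithelium area fraction (recorded in the generator's ground
truth); with a uniform-intensity body, a mismatched target shifts the
threshold to the background level and the segmented contour onto the
smoothing halo a few pixels outside the true boundary.

**Cultured cells.** Gaussian smooth (σ = 1) → rolling-ball background
subtraction (radius 10) → Otsu → mean of the processed image over the
foreground. The rolling-ball background is the classic sliding-ball
estimate (grayscale opening with a ball-shaped element, via
scikit-image); ImageJ's paraboloid approximation is deliberately not
replicated bit-for-bit. Because all three steps commute with a constant
offset (until clipping), the readout is invariant to uniform background
shifts, which the tests assert.

## TEER barrier index

The barrier index is z(1 kHz)/z(41 kHz) per well and timestamp. Each
well's trace is divided by its own t = 0 value, then pointwise by the
mean self-normalized trace of all unstimulated wells (the control
correction uses the mean because no pairing is defined). Timestamps must
match exactly — the instrument exports a regular 1-min grid — and no
resampling is attempted.

## Synthetic phantoms

The movie phantom is what the analysis chain assumes the camera sees,
not an optics simulation: a stadium-shaped "tissue" (default 240×480 px
frame, capsule half-length 180 px, radius 40 px, lumen grey 220) on a
medium of baseline grey 20 whose value follows baseline·(1 + m·t), plus
per-pixel additive Gaussian noise (default σ = 2 grey levels), clipped
to [0, 255] and rounded to 8 bits. Defaults were chosen so Otsu
separates the classes cleanly at t = 0 and an 8-h ramp at the steepest
rates of interest stays below saturation; a spec that would saturate
raises an error unless clipping is explicitly requested. With
`quantize=False` frames stay float (still clipped), which makes the
noiseless generator→analyzer loop exact: 8-bit rounding alone would
floor-bias intermediate medium values. With noise on, the noise dithers
the quantization and slope recovery is unbiased in the mean.

The port-leak artifact is an anisotropic Gaussian pool just beyond one
tissue end (σ 20 px along the axis, 80 px across, amplitude growing
linearly to 60 grey levels), the way liquid collects against the chamber
end wall; an isotropic blob at the tip hides most of its mass under the
expanded tissue mask and does not represent a detectable leak. The
section phantom is a disk or ring (lumen hole) of uniform E-cadherin
signal with ZO-1 on the 2-px boundary shell and zero elsewhere. The TEER
phantom programs a linear decline of the stimulated wells' barrier index
to a chosen fraction after an onset time, with 0.5 % multiplicative
impedance noise (typical sub-percent repeatability of impedance plate
readers; note that noise on the t = 0 sample propagates wholly through
baseline normalization, so this choice sets the floor on recovery
accuracy).

What the phantoms do **not** emulate: optical point-spread, tissue
texture and motion, photobleaching, uneven illumination, autofluorescence
drift, and any real diffusion physics (the linear ramp is imposed, not
derived). Passing the closed-loop tests therefore demonstrates that the
analysis chain is correct and unbiased for data matching its model
assumptions — not that segmentation is robust to every real-world
artifact; the fraction-band fallback and leak screen are the only
robustness mechanisms exercised.

## Problem sizes and reproducibility

Closed-loop slope validation uses 10 replicate movies per condition at
the full default chamber geometry and the condition's acquisition
protocol; the endpoint-correlation check uses 12 sample movies plus one
control at 2 h / 15-min frames; leak screening is validated on 20
no-leak seeds and one phantom per port end. All generators draw from
`numpy.random.default_rng` seeded explicitly; analysis itself contains
no randomness, so identical inputs give bit-identical outputs.

## Known limitations

- Chamber ROIs are manual (config-supplied); no automatic chamber
  detection.
- Two-point-in-time contrast inversions are handled by mask fallback,
  not by tracking; a chamber whose very first frame segments poorly
  fails outright.
- The percentile rule assumes the foreground fraction is a meaningful
  target; images whose epithelium fraction differs grossly from the
  target p will band the wrong contour (see above).
- Calibration is linear only; saturation above 100 µg/mL is out of
  scope.
- TEER traces are matched on exact timestamps; irregular exports must be
  resampled upstream.
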
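# Methods

This note documents the models, conventions, and numerical choices behind
`puffoct`, and what its synthetic experiments do and do not establish about
real instrument data.

## Measurement model

A single swept-source OCT A-scan stream samples nine corneal spots
simultaneously: one central (SC) and eight peripheral (S1…S8) at radius
1.1 mm and 45° spacing. Depth encoding assigns each beam a path-length
offset ΔLᵢ so its interference signal occupies a private depth window of
the common A-scan; an M-scan image is therefore (axial pixels × time) with
nine stacked channel windows. Native sampling is one A-scan per 10 µs
(100 kHz sweep rate); the default axial pixel pitch is 8.6 µm/px.

Spot azimuths are measured counter-clockwise from the +x axis of the
instrument view, with S1 anchored at 0° by default. The anchor is
configurable (`SpotLayout.anchor_azimuth_deg`) because the mapping to
anatomical directions (nasal/temporal/superior) is an acquisition
convention, not a property of the analysis. Signed azimuths in (−180°, 180°]
are reported alongside [0°, 360°) for comparison with clinical map
conventions.

## Synthetic acquisition generator

No public air-puff OCT recordings exist, so all quantitative testing runs
against a generator whose ground truth is known exactly.

**Stimulus.** The air-puff pressure pulse is a Gaussian with 8 ms temporal
FWHM and a configurable peak, centred at `onset_time_ms` (default 15 ms into
a 45 ms record). An optional delayed secondary lobe (< 25% of the main
peak) reproduces the occasional weak secondary pressure peak; it is
deliberately excluded from the displacement response, since by its arrival
the cornea has essentially recovered. The spatial FWHM (default 4 mm,
a spatially broadened stimulus) is metadata only: spatial broadening is what
elicits the dual-indentation response, but no quantitative law linking it to
the response shape is available, so the response model keeps its own free
parameters.

**Tissue response.** The displacement law is phenomenological, not
mechanistic — parameter-recovery testing only requires a *known* truth:

    d_s(t) = C(s) · P · [(1−w)·L₁(t) + w·L₂(t)]

where P is the stimulus peak pressure, L₁, L₂ are unit-peak temporal lobes
(FWHM 6 ms, second lobe delayed by 10 ms), and w ∈ [0, 1] is the
dual-indentation weight (default 0.35, clearly bimodal; w = 0 gives the
classic single-indentation response). Lobes are Gaussians *clipped to
compact support* (±1.5 FWHM, rescaled to unit peak) so the true deformation
onset is a well-defined first nonzero sample. The per-spot compliance is

    C(s) = C₀ · (1 + ε·g(θ_s − θ_c)) · (1 + scatter)

with C₀ = 450 µm per pressure unit (displacements of order 10²–10³ µm),
ε the cone excess, and g a wrapped-Gaussian angular weight (FWHM 60°, a
typical focal cone extent) centred on the cone azimuth θ_c. The central
spot, which never enters the asymmetry statistic, uses a configurable
constant weight instead of g. Two optional per-spot jitters emulate healthy
inter-spot variability: a fractional compliance scatter and a timing shift
of the whole response (`timing_scatter_ms`). The timing scatter matters for
the down-sampling experiment: if every spot shared one temporal shape,
coarse sampling would rescale all amplitudes identically and could never
rotate the asymmetry vector.

Ground-truth descriptors (DA₁–DA₃, latencies, area) are read directly off
each generated series with a plain local-extrema scan, so they are
consistent with the series by construction and independent of the
measurement-path extractor.

**Rendering.** Each channel draws a Gaussian bright ridge (FWHM 6 px, peak
1000 counts) at depth `ΔLᵢ/pitch + d(t)/pitch` inside its window, then
additive Gaussian intensity noise is applied and the image quantized to
16 bits. Pre-onset columns are constant — the beams are stationary, so
pre-deformation signals are speckle-free. Speckle itself is not modelled;
the noise model is additive only. A fixed seed yields bit-identical images.
Channel windows are cut contiguously between neighbouring resting rows
(15% of the gap above, 85% below, where indentation goes); rendering
refuses configurations whose displacement would leave its window.

## Surface tracking

Two routes produce a per-channel boundary (surface row vs time):

* **Mask workflow** — an operator paints the anterior surface on an overlay
  (red curve for RGB masks, any nonzero pixel for grayscale) exported as
  PNG at M-scan resolution. Where a column holds several marked pixels the
  *topmost* is kept: the anterior surface is the first interface the beam
  meets. Unmarked columns are linearly interpolated. The exact mask dialect
  of manual image-editor workflows varies; this one is documented and
  self-consistent.
* **Automatic tracker** — per column, the intensity-weighted centroid of
  pixels above `median + 5·MAD` of the channel window, with
  background-subtracted weights (exact invariance to constant intensity
  offsets) and the centroid confined to ±4 ridge widths around the column
  maximum (isolated noise pixels elsewhere cannot drag it). Columns without
  suprathreshold signal are interpolated; a channel fails if more than 20%
  of its columns do.

Displacement is `(boundary − baseline mean) × pitch` with indentation
(surface receding from the probe, i.e. down the image) positive; the
baseline is the pre-onset window (default first 2 ms, ≥ 20 samples), whose
standard deviation is carried as `baseline_sigma` for later thresholds.

## Deformation parameters

Onset is the first sample exceeding `5·baseline_sigma` sustained for
0.1 ms. The sustain criterion is physical time, not a sample count, so it
survives down-sampling (0.1 ms = 10 samples at the native grid); an
explicit sample count can be passed instead. A 1e-9-relative floor on the
threshold guards float rounding on noise-free data.

Extrema are searched on a 5-sample moving average with prominence
`3·baseline_sigma`, but the reported amplitudes are raw values at the
located indices. DA₁ = first prominent maximum, DA₃ = second, DA₂ = the
minimum between them; one pre-onset sample is included in the search so a
maximum or plateau starting exactly at onset is still a local maximum.
Single-peak profiles flag DA₂/DA₃ (and hence mean and ratio) absent. The
area integrates displacement (trapezoid rule) from onset until it first
falls back below the onset threshold after DA₁, or the record ends.

## Asymmetry vector

Each opposite-spot pair contributes a meridional vector of length
`|v_a − v_b|` pointing toward the higher-valued spot (ties give a
zero-magnitude vector with the first label's azimuth — direction
immaterial); the asymmetry vector is their planar sum. DA₁ is the default
source parameter; any per-spot scalar works. Because the meridional vector
equals `(v_a − v_b)·û_a`, the statistic is linear, so the pre/post
difference vector can be computed both as the vector of per-spot
differences and as the difference of vectors; both paths are computed and
cross-checked on every call. A zero-magnitude vector reports azimuth 0 with
an explicit flag.

## Temporal down-sampling analysis

`downsample` emulates slower instruments: integer rate factors decimate at
matching indices; non-integer factors (33.3 µs from a 10 µs grid) linearly
interpolate at the coarse timestamps. `worst_case_error` re-detects onset
and re-extracts DA₁ on the down-sampled profiles for *every* temporal
offset of the coarse grid (all multiples of the native period within one
coarse period — also for non-integer factors), recomputes the asymmetry
vector, and reports magnitude error as a percentage of the native-resolution
reference magnitude plus absolute azimuth error, per offset and as worst
cases. A spot whose coarse profile yields no detectable onset or peak
contributes DA₁ = 0 at that offset — the coarse grid genuinely missed the
event, and erroring out would understate the worst case. A zero-magnitude
reference flags the percentage as undefined while azimuth errors are still
reported.

The packaged cohort experiment uses 13 eyes (10 near-symmetric with 3%
compliance scatter and 0.3 ms timing scatter, 3 with a 50% cone at random
azimuths; per-eye sub-seeds from one base seed) and targets 20 µs, 250 µs,
and 1 ms. On this cohort the worst-case errors are identically zero at the
native resolution and grow monotonically with the target period for every
eye — negligible at 20 µs, percent-level at 250 µs, tens of percent and
tens of degrees at 1 ms. These sizes were chosen to run in seconds; only
the qualitative degradation pattern, not any particular error value, is a
claim about real eyes, whose deformation waveforms this generator only
caricatures.

## Repeatability

Repeated asymmetry vectors of one eye are summarized by the component-wise
mean vector, the circular standard deviation of azimuths (azimuths are
periodic; a linear SD fails across the 0/360 seam), the sample SD of
magnitudes (also normalized by the mean magnitude, and in axial pixels when
a pitch is supplied). The circular SD is √(−2 ln R̄); for two vectors at
±10° it gives 10.03°, which the tests assert against the formula itself.

## Optical design calculators

All closed forms with defaults pinned to the clinical prototype:
dₛ = f₁·tan α with f₁ = 30 mm (1.1 mm ring ⇒ α = 2.10°); k-clock Nyquist
depth = MZI delay / 4 (44 mm ⇒ 11 mm), doubled by dual-edge sampling
(22 mm), against the 9 × 2 mm channel span; minimum channel offset =
corneal thickness × n (600 µm × 1.337 = 802 µm, rounded up to ~2 mm in
practice); spherical-cap sag R − √(R² − r²) (R = 7.8 mm, r = 1.1 mm ⇒
78.0 µm — instrument documentation tends to quote ≈79 µm; the difference is
rounding-convention noise and both sit an order of magnitude under the
depth of focus); Gaussian DOF = 2× Rayleigh range = 2π(d/2)²/λ (25 µm at
1310 nm ⇒ 0.749 mm; quoted values around 0.72 mm fall between the common
0.69–0.75 mm conventions, so the figure is not chased further). The safety
budget averages the central beam power over the standardized 1 mm limiting
aperture (0.00785 cm²); the exposure time has no default because it is an
acquisition choice — 50 ms reproduces the reference radiant exposure of
22.9 mJ/cm² and an ~11.5× margin against the 265 mJ/cm² MPE. The coupler
excess for a split s into n ways is 100·(s/n − (1−s))/(1−s): +12.5% for
90/10 into 8.

## Reporting

The heat ring is a *periodic* cubic spline over azimuth — the only boundary
condition without a seam artifact at 0/360 — resampled at 1°/sample; it
passes exactly through all 8 knots. Cubic interpolation can overshoot
between knots, so the ring's colour maximum need not coincide with the
asymmetry-vector azimuth (it does when the maximum knot's neighbours are
symmetric). Figures are rendered deterministically (pinned SVG hash salt,
no embedded timestamps); vector overlays are drawn in data units with
colour bounds defaulting to the displayed value range.

## Known limitations

* The response law is a two-lobe caricature: no viscoelastic relaxation,
  whole-eye retraction, tear-film dynamics, or stimulus–response coupling.
  Passing round-trip tests demonstrates the *pipeline's* correctness, not
  that real corneal waveforms are recovered this accurately.
* Noise is additive Gaussian intensity noise; OCT speckle, sensitivity
  roll-off, and fringe-level effects are out of scope.
* Curvature/refraction correction of OCT geometry is not applied; the
  analysis tracks fixed lateral positions in time only.
* The asymmetry vector is a summary statistic of deformation, not an
  estimate of intrinsic stiffness or modulus; no diagnostic thresholds are
  provided.
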
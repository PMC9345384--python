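# Methods

## Self-gating signal model

A rotational microCT acquisition records frames `i = 0 … N−1` at times
`t_i = i·T/(N−1)` and angles `α_i = i·R/N` (endpoint-exclusive, so frames
`i` and `i+N/2` of a two-rotation scan share their projection angle
exactly — the property the gating pairing requires). The raw trace is the
arithmetic ROI mean of each frame's transmitted intensity; it decomposes
into (i) the angular projection of the static anatomy, periodic in 180°,
(ii) a slow multiplicative tube drift, not periodic in a rotation, and
(iii) the breathing/cardiac modulation of interest, one to two orders of
magnitude smaller than (i).

**Mirror-extension background removal.** The trace of length N is extended
to 2N by appending its reversal; the extension is even-symmetric, hence
periodic regardless of endpoint mismatch, and the operation equals a
DCT-II. The background is the inverse transform of the first K
coefficients (DC counted as the first, conjugate partners implicit);
`corrected = raw − background`. K = 20 for the 1028-frame protocol keeps
everything below ≈ 0.28 Hz in the background: the anatomy fundamental
(0.235 Hz) and first harmonic are removed while the 0.7 Hz breathing band
is untouched. The operator is linear and idempotent. Two artifacts are
inherent and drive the margin rules below: imprecision at the acquisition
ends, and ringing at the truncation edge excited by spectral leakage of
the breathing pulses.

**Margins, normalization, events.** Frames with angle inside 90° of either
end are discarded (planar series: the equivalent 90/720 time fraction per
end). The corrected trace is scaled to [0, 1] by its extrema over the
valid range; each maximal run of `normalized ≥ 0.3` at least 2 frames long
is one breathing event, its peak at the run argmax. Runs that touch the
valid-range boundary are truncated breaths: they are dropped from fitting
but still truncate their neighbours' expirations, as do sub-threshold-width
noise blips.

**Phase segmentation and the pooled expiration fit.** The inspiration
onset is the maximum of the second central difference of a 5-point
moving-average-smoothed trace, searched from the previous event's end (or
the valid start) to two samples before the peak — the most convex point,
which for a piecewise-linear pulse is the foot of the rising flank. The
expiration runs from the peak to the next breath's onset. All expirations
are overlaid at τ = 0 and fitted by bounded least squares with

    f(τ) = I0 · exp(−k · τ²) + c ,   I0, k > 0,  c free,

initialized from the last-τ-decile mean (c), the near-peak mean (I0) and
the half-decay time of τ-binned means (k = ln 2 / τ½²); tolerance
xtol = 1e−8. Because τ = 0 is anchored at the highest *sampled* frame, it
lags the true peak by up to one frame period (33 ms at 30 fps), which
systematically inflates k — worst for slow decays, where the peak is flat
over many samples. The fit therefore carries one global time-shift
nuisance bounded to ±1.5 frame periods; the reported model stays the
three-parameter decay. Normalization is affine, so k is invariant to it.

**Spectral rates.** Periodogram of the Hann-tapered, mean-subtracted valid
segment, normalized to unit peak (no taper is mandated by the protocol;
Hann is the conventional low-leakage choice). Breathing frequency:
argmax below 2 Hz. Heart rate: argmax inside 300–700 bpm — a band
bracketing murine rates — after masking bins within ±0.1 Hz of the first
8 integer multiples of the breathing frequency. The harmonic cap matters:
±0.1 Hz windows around *all* multiples of a ~0.7 Hz breathing rate would
blank ~29 % of the cardiac band and, at the default operating point,
the 470 bpm peak itself (7.83 Hz lies < 0.03 Hz from the 11th multiple),
while breathing harmonics above order ~8 are below the noise floor anyway.
Ties in any argmax resolve to the lowest frequency.

**Gating, reconstruction, segmentation.** Frame selection uses the
corrected trace rescaled over its *valid-range* extrema but evaluated at
every frame: margin frames must be selectable, yet letting their edge
artifacts set the scale shifts the 0.1/0.3 levels. Per angle: lower-valued
frame wins; both below 0.1 → average (halves the photon noise variance);
no candidate below 0.3 → counted unreliable but still reconstructed
(flagged, configurable). FBP converts intensities to line integrals with
`−log(I/flat)` — flat from the simulator's stored tube intensity, or a
per-frame outer-column median on real data — resamples each projection
onto the output grid and applies a ramp-filtered parallel-beam back
projection (scikit-image `iradon`), returning attenuation in 1/mm.
Lung segmentation thresholds at the arithmetic mean of the lung and
soft-tissue class means inside a body-support mask (the stand-in for
manually removing outside air), keeping connected components of ≥ 20 px.

## The phantom: what it emulates, and what it does not

The phantom is an implicit 3-D object: an axial (x, y) layout of uniform
ellipses — body, two lungs, cardiac region, spine — extruded along the
craniocaudal axis z, with lung tissue present from an apex taper down to a
diaphragm dome. Every projection frame is computed row-by-row with the
closed-form Radon transform of uniform ellipses, converted to
`photon_count · drift(t) · exp(−line integral)` and Poisson-sampled, so a
frame is a genuine 2-D image (rows = z) and an ROI can sit over the
diaphragm interface or the apex, reproducing the placement dependence of
the fitted parameters.

Breathing moves the dome base caudally by `diaphragm_amplitude` (0.2) of
the lung height per unit breath phase; across the dome the lung
cross-section fades linearly (a partial-volume stand-in for the dome's
curvature). This makes the summed ROI line integral *exactly affine* in
the breath phase while the dome stays inside the ROI — the property that
makes k recoverable from the trace. The deliberately small secondary
effects (chest expansion 0.005, lung attenuation air-modulation 0.02)
give the apex a weak signal without breaking affinity. The body is
near-round at the diaphragm level (7.3 × 6.6 mm semi-axes): eccentricity
feeds anatomy harmonics above the K = 20 cutoff into the corrected trace.
Attenuations (soft 0.022, lung 0.008, bone 0.06 mm⁻¹) approximate a
90 kV spectrum; `photon_count` = 5000 per detector pixel puts the
breathing peaks ≈ 10× above the trace noise floor at the default ROI.

The breathing waveform rises from the previous cycle's end value with a
half-sine of 0.2 s ("inspirations are short") to `c + I0`, then decays as
`I0·exp(−k·τ²)+c`; default period 1.4 s, k = 2 s⁻². The acquisition-level
schedule jitters each cycle's period by σ = 3 % (anesthesia variability;
also decoheres high breathing harmonics from the cardiac tone, which at
470 bpm sits next to the 11th multiple of 0.714 Hz). The cardiac region's
attenuation is modulated sinusoidally by ±8 % at 470 bpm. The tube drift
is a linear ramp times a sinusoid with 2.7 cycles per scan — deliberately
not 2π-periodic.

Not emulated: beam hardening, scatter, detector lag, cone-beam geometry,
anatomical realism beyond ellipses, cardiac motion (only attenuation
modulation), airway structure, tidal-volume effects. Passing tests
demonstrate the *pipeline's* correctness under known ground truth, not
robustness to those physical effects.

## Problem sizes and numerical choices

Default simulations use the full 1028-frame protocol on a 192² grid at
0.1 mm pixels (≈ 2 s per acquisition). The parameter-recovery ensemble
runs 20 seeds at each k ∈ {0.5, 1, 2, 4} s⁻²; reconstruction comparisons
use grid 256, unit round-trips grid 96–192, production default 512.
Dataclass validation rejects inconsistent configurations before any
compute; all randomness flows through one seeded generator per
acquisition, and identical seeds give bit-identical stacks.

## Known limitations

- **Slow decays are overestimated.** For k = 0.5 s⁻² at a 1.4 s period the
  expiration never approaches baseline (the trace sits above the 0.3 level
  ~78 % of the cycle) and the cutoff-edge ringing of the background
  removal tilts individual expirations; k̂ is biased high by ~30–40 %
  there, ~+9 % at k = 1, and ≤ ±2 % at k ∈ {2, 4}. The median relative
  error over the whole recovery ensemble stays below 10 %, and rank order
  across the grid is always preserved — the discrimination property the
  readout rests on — but absolute k values in the slow regime should not
  be trusted.
- **Gating pays a noise price in static tissue.** A gated sinogram mostly
  keeps single frames where the ungated baseline averages two, so at the
  default photon count the whole-body RMSE of the gated reconstruction is
  noise-dominated and slightly *worse* than ungated; the improvement is
  where the motion is — lung-region RMSE ratios 0.90–0.97 across seeds.
- With the default k = 2 / 1.4 s breathing, expirations overlap between
  the two rotations at any phasing, so the unreliable-angle count is high
  (~200–280 of 514); rgXLF's stated requirement that breathing events not
  largely overlap between rotations applies to the phantom too.
- The heart-rate search assumes the cardiac tone is not buried under a
  genuinely strong breathing harmonic; when the rates are exactly locked
  no spectral method can separate them.
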
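# rgxlf — retrospectively gated X-ray lung function

`rgxlf` derives respiratory function **from the raw projection stream of a
retrospectively gated lung microCT scan**, so that a single low-dose CT
acquisition yields both the anatomy and the breathing parameters that
previously required a separate planar cinematic X-ray session. It is aimed
at preclinical imaging groups studying mouse models of respiratory disease
(e.g. dystrophin-deficient *mdx* mice with diaphragm fibrosis), and at
anyone who wants a fully synthetic, ground-truthed test bed for self-gating
algorithms.

## What it computes

A rotational scan records projections continuously while the animal
breathes freely. The mean brightness `U(α)` of a rectangular ROI over the
lung–diaphragm interface is modulated by lung air content, superimposed on
a much larger baseline from the projected anatomy and the X-ray tube's
slow intensity drift. The pipeline:

1. **Background removal.** The trace is extended to twice its length by
   appending its mirror image — the extension is always periodic even
   though the tube drift is not periodic in a full rotation — and the
   background is the inverse FFT of the first *K* = 20 Fourier
   coefficients, subtracted from the raw trace.
2. **Normalization and events.** The first and last 90° of rotation are
   discarded, the remainder is scaled to [0, 1], and each maximal run
   above the level 0.3 is one breathing event.
3. **Expiration fit.** Breaths are split at the trace peak; the
   inspiration onset is the point of highest curvature before it. All
   expiration segments are pooled (τ = 0 at each peak) and fitted with

   `f(τ) = I₀ · exp(−k · τ²) + c`

   The decay constant **k** (1/s²) tracks elastic recoil and diaphragm
   damping; heart rate is read from the filtered power spectrum.
4. **Expiration-gated CT.** Every angle of the 720° scan is sampled twice;
   per angle the frame with the lower breathing value is kept, both are
   averaged when both are below 0.1, and angles with no candidate below
   0.3 are counted as *unreliable* — the reliability figure of the scan.
   The gated 360° sinogram is reconstructed by parallel-beam filtered back
   projection and the lung segmented at the midpoint of the lung and
   soft-tissue class means.

A built-in **dynamic thorax phantom** (elliptical body, two lungs with a
moving diaphragm dome, beating cardiac region, spine, tube drift, Poisson
noise) generates both protocols — 1028 frames / 720° / 34 s rotational and
1024-frame planar — with every ground-truth parameter stored alongside the
frames, so each stage is testable by parameter recovery.

## Worked example

```sh
python examples/01_breathing_trace_from_projections.py
```

```
frames: 1028, rotation: 720 deg, sampling 30.21 Hz
breathing events detected (level 0.3): 19
breathing frequency: 0.705 Hz
heart rate:          470.1 bpm
```

The phantom breathes every 1.4 s (0.714 Hz) with 470 bpm cardiac
modulation; both rates are recovered within one spectral bin. The second
example fits the expiration decay (`k = 1.980` for a simulated
`k_true = 2.0`) and the third builds the gated reconstruction and segments
the lung (Dice 0.954 against the phantom labels at grid 256).

The same stages are available as a CLI for on-disk stacks (multi-page TIFF
plus JSON sidecar):

```sh
rgxlf simulate --protocol ct --seed 1 --out scan
rgxlf trace --stack scan --roi 95,136,22,170 --out trace.csv
rgxlf lungfunc --trace trace.csv --out report.json
rgxlf run --seed 1 --out results_dir      # full pipeline in one call
```

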
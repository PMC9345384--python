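"""Extract a self-gating breathing trace from a rotational acquisition.

Simulates the standard CT protocol (1028 frames over 720 degrees in 34 s)
of the breathing thorax phantom, places the recommended ROI over the
lung-diaphragm interface, removes the anatomy/tube background with the
first K=20 Fourier coefficients of the mirror-extended trace, and reads
the breathing and heart rates out of the power spectrum.
"""

import rgxlf as rx

cfg = rx.PhantomConfig()
series = rx.generate_acquisition(cfg, rx.AcquisitionConfig(seed=1),
                                 rx.BreathingParams())

roi = rx.ROI(*rx.interface_roi(cfg))
trace = rx.compute_breathing_trace(series, roi)
events = rx.detect_events(trace)
spectrum = rx.analyze_spectrum(trace)

print(f"frames: {series.n_frames}, rotation: {series.total_rotation:.0f} deg, "
      f"sampling {trace.sampling_rate:.2f} Hz")
print(f"breathing events detected (level 0.3): {len(events)}")
print(f"breathing frequency: {spectrum.breathing_frequency:.3f} Hz")
print(f"heart rate:          {spectrum.heart_rate_bpm:.1f} bpm")
print()
print("The breathing frequency is the dominant sub-2-Hz spectral peak of the")
print("corrected trace; the heart rate is the strongest peak in the 300-700")
print("bpm band after masking breathing harmonics. With the phantom's ground")
print("truth at 1/1.4 s = 0.714 Hz and 470 bpm, both land within one")
print("spectral bin of the truth.")
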
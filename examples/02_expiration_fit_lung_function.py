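"""Fit the expiration decay and assemble the lung-function report.

Each detected breath is segmented into inspiration (onset at the point of
highest curvature before the peak) and expiration (peak to next onset);
all expirations are pooled and f(tau) = I0*exp(-k*tau^2) + c is fitted.
The decay constant k is the functional readout: diaphragm-compromised
animals show faster decays (larger k) than healthy ones.
"""

import rgxlf as rx

cfg = rx.PhantomConfig()
k_true = 2.0
series = rx.generate_acquisition(
    cfg, rx.AcquisitionConfig(seed=1), rx.BreathingParams(k_true=k_true))

trace = rx.compute_breathing_trace(series, rx.ROI(*rx.interface_roi(cfg)))
events = rx.detect_events(trace)
refined = rx.segment_event_phases(trace, events)
fit = rx.fit_expiration(refined)
spectrum = rx.analyze_spectrum(trace)
report = rx.lung_function_report(trace, refined, fit, spectrum)

print(f"events pooled:        {report.n_events} ({fit.n_points} samples)")
print(f"fitted k:             {fit.k:.3f} 1/s^2   (simulated: {k_true})")
print(f"fitted I0, c:         {fit.I0:.3f}, {fit.c:+.3f}   rmse {fit.rmse:.3f}")
print(f"inter-breath interval: {report.mean_interbreath_interval_s:.3f} s")
print(f"relative inspiration time: {report.relative_inspiration_time:.3f}")
print()
print("k is recovered within a few percent at the default settings; the")
print("interval matches the 1.4 s anesthesia target, and inspiration takes")
print("roughly a sixth of each cycle, as configured in the phantom.")
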
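"""Trace module: ROI extraction, background removal, events, spectra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rgxlf as rx
from rgxlf.exceptions import (
    BoundsError,
    DegenerateTraceError,
    InvalidParameterError,
)
from rgxlf.trace import _valid_mask

from conftest import synthetic_trace


def _toy_series(frames, total_rotation=720.0, total_time=None):
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    if total_time is None:
        total_time = float(n - 1)
    times = np.arange(n) * total_time / (n - 1)
    angles = np.arange(n) * total_rotation / n
    return rx.ProjectionSeries(
        frames, angles, times, 0.1,
        {"acquisition": {"total_rotation": total_rotation}},
    )


class TestExtractRoiTrace:
    def test_constant_frames_give_constant_trace(self):
        series = _toy_series(np.full((6, 8, 8), 3.5))
        trace = rx.extract_roi_trace(series, rx.ROI(1, 5, 2, 7))
        np.testing.assert_allclose(trace, 3.5)

    def test_single_pixel_roi_is_pixel_series(self):
        rng = np.random.default_rng(0)
        frames = rng.random((5, 6, 6))
        series = _toy_series(frames)
        trace = rx.extract_roi_trace(series, rx.ROI(2, 3, 4, 5))
        np.testing.assert_allclose(trace, frames[:, 2, 4])

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(1)
        frames = rng.random((5, 7, 9))
        series = _toy_series(frames)
        roi = rx.ROI(2, 5, 3, 7)
        trace = rx.extract_roi_trace(series, roi)
        for i in range(5):
            total, count = 0.0, 0
            for r in range(2, 5):
                for c in range(3, 7):
                    total += frames[i, r, c]
                    count += 1
            assert trace[i] == pytest.approx(total / count)

    def test_roi_outside_frame_raises(self):
        series = _toy_series(np.zeros((4, 8, 8)))
        with pytest.raises(BoundsError):
            rx.extract_roi_trace(series, rx.ROI(0, 9, 0, 4))


class TestRemoveBackground:
    @pytest.mark.parametrize("K", [1, 5, 20])
    def test_constant_trace_fully_removed(self, K):
        background, corrected = rx.remove_background(np.full(128, 7.0), K=K)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-10)
        np.testing.assert_allclose(background, 7.0, atol=1e-10)

    def test_ramp_plus_impulse_train(self):
        # the background model should swallow the ramp and keep the impulses
        n = 1028
        ramp = np.linspace(0.0, 3.0, n)
        impulses = np.zeros(n)
        impulses[20::40] = 1.0
        background, corrected = rx.remove_background(ramp + impulses, K=20)
        peaks = corrected[20::40]
        assert np.all(np.abs(peaks - 1.0) < 0.1)
        between = corrected.copy()
        between[20::40] = 0.0
        # impulse train DC (1/40) ends up in the background estimate; the
        # first/last samples carry the usual edge imprecision that the
        # pipeline's angular margins exist to discard
        assert np.abs(between[20:-20]).max() < 0.05

    @given(st.integers(0, 2**31 - 1))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 100))
        _, ca = rx.remove_background(a, K=7)
        _, cb = rx.remove_background(b, K=7)
        _, cab = rx.remove_background(a + b, K=7)
        np.testing.assert_allclose(cab, ca + cb, atol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal(256) + np.linspace(0, 4, 256)
        _, corrected = rx.remove_background(raw, K=11)
        background2, _ = rx.remove_background(corrected, K=11)
        assert np.abs(background2).max() < 1e-9

    def test_k_too_large_raises(self):
        with pytest.raises(InvalidParameterError):
            rx.remove_background(np.zeros(30), K=16)
        with pytest.raises(InvalidParameterError):
            rx.remove_background(np.zeros(30), K=0)


class TestPrepareTrace:
    def test_rotational_margins_discard_90_degrees(self, default_series,
                                                   default_trace):
        angles = default_series.angles
        expected = (angles >= 90.0) & (angles <= 630.0)
        np.testing.assert_array_equal(default_trace.valid_mask, expected)

    def test_simple_normalization(self):
        series = _toy_series(np.zeros((3, 4, 4)), total_rotation=0.0)
        trace = rx.prepare_trace(np.array([0.0, 5.0, 10.0]), series,
                                 margin_degrees=0.0)
        np.testing.assert_allclose(trace.normalized, [0.0, 0.5, 1.0])

    def test_normalization_identity_over_valid(self, default_trace):
        valid = default_trace.normalized[default_trace.valid_mask]
        assert valid.min() == 0.0
        assert valid.max() == 1.0
        assert np.all(default_trace.normalized[~default_trace.valid_mask] == 0)

    def test_corrected_is_raw_minus_background(self, default_trace):
        np.testing.assert_allclose(
            default_trace.corrected,
            default_trace.raw - default_trace.background,
            atol=1e-9,
        )

    def test_planar_margin_is_time_fraction(self):
        n = 64
        series = _toy_series(np.zeros((n, 4, 4)), total_rotation=0.0)
        mask = _valid_mask(series, 90.0)
        k = round(n * 90.0 / 720.0)
        assert not mask[:k].any() and not mask[n - k:].any()
        assert mask[k: n - k].all()

    def test_degenerate_trace_raises(self):
        series = _toy_series(np.zeros((8, 4, 4)), total_rotation=0.0)
        with pytest.raises(DegenerateTraceError):
            rx.prepare_trace(np.ones(8), series, margin_degrees=0.0)


class TestDetectEvents:
    def test_two_events_in_worked_example(self):
        trace = synthetic_trace([0.0, 0.5, 0.2, 0.6, 0.7, 0.1])
        # single-sample runs allowed here to match the worked example
        events = rx.detect_events(trace, level=0.3, min_event_frames=1)
        assert len(events) == 2
        assert list(events.peaks) == [1, 4]

    def test_min_width_rejects_single_sample_blips(self):
        trace = synthetic_trace([0.0, 0.5, 0.2, 0.6, 0.7, 0.1])
        events = rx.detect_events(trace, level=0.3)
        assert len(events) == 1 and events.peaks[0] == 4

    def test_all_below_level_gives_empty_list(self):
        trace = synthetic_trace([0.1, 0.2, 0.15, 0.05, 0.2, 0.1])
        assert len(rx.detect_events(trace, level=0.9)) == 0

    def test_event_count_matches_simulated_breaths(self, default_series,
                                                   default_trace):
        events = rx.detect_events(default_trace)
        gt_peaks = default_series.metadata["ground_truth"]["peaks"]
        t = default_trace.times[default_trace.valid_mask]
        n_expected = int(np.sum((gt_peaks >= t[0]) & (gt_peaks <= t[-1])))
        assert abs(len(events) - n_expected) <= 1

    def test_peak_times_match_ground_truth(self, default_series, default_trace):
        # the sampled peak wanders on the flat breath top under photon
        # noise, so a small fraction of events may sit a few frames off
        events = rx.detect_events(default_trace)
        gt_peaks = default_series.metadata["ground_truth"]["peaks"]
        dt = 1.0 / default_trace.sampling_rate
        devs = np.asarray([
            np.abs(gt_peaks - default_trace.times[p]).min() / dt
            for p in events.peaks
        ])
        assert np.mean(devs <= 2.0) >= 0.8
        assert devs.max() < 5.0


class TestAnalyzeSpectrum:
    def _tone_trace(self, freqs, amps, fs=30.0, duration=30.0):
        t = np.arange(0, duration, 1 / fs)
        x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
        return synthetic_trace(x + 2.0, times=t)

    def test_single_tone_breathing_frequency(self):
        trace = self._tone_trace([0.7], [1.0])
        spec = rx.analyze_spectrum(trace)
        grid = spec.frequencies
        nearest = grid[np.argmin(np.abs(grid - 0.7))]
        assert spec.breathing_frequency == pytest.approx(nearest)

    def test_heart_rate_from_two_tones(self):
        trace = self._tone_trace([0.7, 470.0 / 60.0], [1.0, 0.05])
        spec = rx.analyze_spectrum(trace)
        assert spec.heart_rate_bpm == pytest.approx(470.0, abs=2.0)
        assert spec.search_band_bpm == (300.0, 700.0)

    def test_white_noise_peak_location_unbiased(self):
        # Monte-Carlo: argmax over a flat spectrum should wander the whole
        # sub-2-Hz band, with roughly half the hits in each half
        hits = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = synthetic_trace(
                rng.standard_normal(512), times=np.arange(512) / 30.0
            )
            spec = rx.analyze_spectrum(trace)
            hits.append(spec.breathing_frequency)
        hits = np.asarray(hits)
        assert hits.min() < 0.4 and hits.max() > 1.6
        frac_low = np.mean(hits < 1.0)
        assert 0.3 < frac_low < 0.7

    def test_too_few_valid_samples_raises(self):
        trace = synthetic_trace(np.arange(32.0))
        with pytest.raises(InvalidParameterError):
            rx.analyze_spectrum(trace)


class TestCorrectionOracle:
    def test_bandlimited_anatomy_plus_spikes_recovered(self):
        # anatomy synthesized INSIDE the background model's span (first K
        # extended-spectrum bins) + breathing-like spikes; the corrected
        # trace must reproduce the spikes to within 5% of their amplitude
        n, K = 1028, 20
        t = np.arange(n)
        # mirror extension + DFT truncation is a DCT-II in disguise: a
        # signal inside the first K bins is exactly cos(pi*m*(t+0.5)/n)
        anatomy = sum(
            amp * np.cos(np.pi * m * (t + 0.5) / n)
            for m, amp in [(2, 5.0), (7, 2.0), (15, 1.0)]
        )
        spikes = np.zeros(n)
        spikes[15::43] = 1.0
        widened = np.convolve(spikes, [0.25, 0.5, 1.0, 0.5, 0.25], "same")
        _, corrected = rx.remove_background(anatomy + widened, K=K)
        # compare against the spike component after ITS OWN background pass,
        # since a spike train has in-band energy of its own
        _, spike_ref = rx.remove_background(widened, K=K)
        assert np.abs(corrected - spike_ref).max() < 0.05
        # and the spike peaks themselves survive near full amplitude
        assert np.abs(corrected[15::43] - 1.0).max() < 0.1
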
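"""Self-gating breathing trace from a projection stream.

The mean brightness of a user-defined rectangular ROI over the
lung-diaphragm interface, tracked across projection frames, is modulated by
lung air content and diaphragm position. The anatomical baseline (the
projected body changing with gantry angle) and the slow tube-intensity drift
dominate the raw trace; because the drift is not periodic in one full
rotation, the trace is mirror-extended to twice its length before the
background is estimated from the first K Fourier coefficients and
subtracted. The corrected trace is cropped by an angular margin, scaled to
[0, 1], thresholded into breathing events and Fourier-analyzed for the
breathing and heart rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .exceptions import (
    BoundsError,
    DegenerateTraceError,
    InvalidParameterError,
    NoHeartRateError,
)
from .phantom import ProjectionSeries

__all__ = [
    "ROI",
    "BreathingTrace",
    "EventList",
    "SpectrumResult",
    "extract_roi_trace",
    "remove_background",
    "prepare_trace",
    "detect_events",
    "analyze_spectrum",
    "compute_breathing_trace",
]

log = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_EVENT_LEVEL = 0.3
DEFAULT_MARGIN_DEGREES = 90.0
FULL_ROTATION = 720.0  # reference rotation for the planar margin fraction


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, half-open pixel ranges [start, end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise BoundsError("ROI must have positive extent on both axes")
        if self.row_start < 0 or self.col_start < 0:
            raise BoundsError("ROI indices must be non-negative")

    def validate(self, frame_shape) -> None:
        rows, cols = frame_shape[-2], frame_shape[-1]
        if self.row_end > rows or self.col_end > cols:
            raise BoundsError(
                f"ROI {self} exceeds frame shape {(rows, cols)}"
            )

    @property
    def slices(self):
        return (slice(self.row_start, self.row_end), slice(self.col_start, self.col_end))


@dataclass
class BreathingTrace:
    """Per-frame ROI trace through every processing stage."""

    raw: np.ndarray
    background: np.ndarray
    corrected: np.ndarray
    normalized: np.ndarray
    valid_mask: np.ndarray
    sampling_rate: float
    angles: np.ndarray
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.raw)


@dataclass
class EventList:
    """Detected breathing events as (onset, peak, end) frame-index triples."""

    events: list[tuple[int, int, int]]
    level: float

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peaks(self) -> np.ndarray:
        return np.asarray([p for _, p, _ in self.events], dtype=int)


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # normalized to max 1
    breathing_frequency: float  # Hz
    heart_rate_bpm: float
    search_band_bpm: tuple[float, float]


def extract_roi_trace(series: ProjectionSeries, roi: ROI) -> np.ndarray:
    """Mean frame intensity over the ROI, one value per frame (U(alpha))."""
    roi.validate(series.frames.shape)
    return series.frames[(slice(None),) + roi.slices].mean(axis=(1, 2)).astype(float)


def remove_background(raw: np.ndarray, K: int = DEFAULT_K):
    """Estimate and subtract the anatomy/tube background of a raw trace.

    The trace is extended to length 2N by appending its reversal, which is
    even-symmetric and hence periodic however the original endpoints differ;
    the background is the inverse transform of the first K Fourier
    coefficients (DC counts as the first; conjugate partners are implicit in
    the real FFT). Returns ``(background, corrected)`` with
    ``corrected = raw - background``.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if K < 1:
        raise InvalidParameterError("K must be at least 1")
    if n < 2 * K:
        raise InvalidParameterError(f"trace length {n} too short for K={K}")
    extended = np.concatenate([raw, raw[::-1]])
    coeffs = np.fft.rfft(extended)
    coeffs[K:] = 0.0
    background = np.fft.irfft(coeffs, 2 * n)[:n]
    return background, raw - background


def _valid_mask(series: ProjectionSeries, margin_degrees: float) -> np.ndarray:
    angles = series.angles
    total = series.total_rotation
    n = len(angles)
    if total > 0:
        return (angles >= margin_degrees) & (angles <= total - margin_degrees)
    # planar: drop the equivalent leading/trailing time fraction
    frac = margin_degrees / FULL_ROTATION
    k = int(round(frac * n))
    mask = np.ones(n, dtype=bool)
    if k > 0:
        mask[:k] = False
        mask[n - k:] = False
    return mask


def prepare_trace(
    corrected: np.ndarray,
    series: ProjectionSeries,
    raw: np.ndarray | None = None,
    background: np.ndarray | None = None,
    margin_degrees: float = DEFAULT_MARGIN_DEGREES,
) -> BreathingTrace:
    """Crop margins and scale the corrected trace to [0, 1].

    For rotational series the margin is angular (frames with angle inside
    ``margin_degrees`` of either end are discarded); for planar series the
    equivalent leading/trailing time fraction (margin/720) is dropped.
    Normalization uses the extrema over the valid range only; outside the
    valid range the normalized trace is reported as 0.
    """
    corrected = np.asarray(corrected, dtype=float)
    mask = _valid_mask(series, margin_degrees)
    if mask.sum() < 2:
        raise InvalidParameterError("fewer than 2 samples remain after margins")
    vals = corrected[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise DegenerateTraceError("corrected trace is constant over valid range")
    normalized = np.zeros_like(corrected)
    normalized[mask] = (corrected[mask] - lo) / (hi - lo)
    if raw is None:
        raw = corrected.copy()
    if background is None:
        background = np.asarray(raw, dtype=float) - corrected
    return BreathingTrace(
        raw=np.asarray(raw, dtype=float),
        background=np.asarray(background, dtype=float),
        corrected=corrected,
        normalized=normalized,
        valid_mask=mask,
        sampling_rate=series.sampling_rate,
        angles=series.angles.copy(),
        times=series.times.copy(),
    )


def detect_events(
    trace: BreathingTrace,
    level: float = DEFAULT_EVENT_LEVEL,
    min_event_frames: int = 2,
) -> EventList:
    """One event per maximal run of normalized >= level inside the valid range.

    The peak is the argmax within the run; onset/end are the provisional run
    boundaries (refined later by the max-curvature rule). Runs shorter than
    ``min_event_frames`` are rejected as single-sample noise crossings.
    """
    if not 0 < level < 1:
        raise InvalidParameterError("level must lie in (0, 1)")
    above = (trace.normalized >= level) & trace.valid_mask
    events: list[tuple[int, int, int]] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[above[edges + 1]] + 1)
    ends = list(edges[~above[edges + 1]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    for s, e in zip(starts, ends):
        if e - s < min_event_frames:
            continue
        peak = s + int(np.argmax(trace.normalized[s:e]))
        events.append((s, peak, e))
    if not events:
        log.info("no breathing events found at level %.2f", level)
    return EventList(events=events, level=level)


def analyze_spectrum(
    trace: BreathingTrace,
    band_bpm: tuple[float, float] = (300.0, 700.0),
    breathing_max_hz: float = 2.0,
    harmonic_tolerance_hz: float = 0.1,
    max_harmonic: int = 8,
) -> SpectrumResult:
    """Power spectrum of the corrected trace; breathing and heart rates.

    A Hann-tapered periodogram of the mean-subtracted valid segment,
    normalized to unit peak. The breathing frequency is the strongest
    component below ``breathing_max_hz``; the heart rate is the strongest
    component inside ``band_bpm`` after excluding bins within
    ``harmonic_tolerance_hz`` of the first ``max_harmonic`` integer multiples
    of the breathing frequency (higher-order breathing harmonics are below
    the noise floor, and excluding them would veto legitimate cardiac peaks).
    Both rates are reported at the spectrum's native resolution.
    """
    x = trace.corrected[trace.valid_mask]
    if len(x) < 64:
        raise InvalidParameterError("need at least 64 valid samples")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x * hann(len(x)))) ** 2
    power /= power.max()
    freqs = np.fft.rfftfreq(len(x), d=1.0 / trace.sampling_rate)

    breath_bins = (freqs > 0) & (freqs < breathing_max_hz)
    if not breath_bins.any():
        raise InvalidParameterError("no spectral bins below breathing_max_hz")
    f_breath = float(freqs[breath_bins][np.argmax(power[breath_bins])])

    lo, hi = band_bpm[0] / 60.0, band_bpm[1] / 60.0
    band = (freqs >= lo) & (freqs <= hi)
    for m in range(1, max_harmonic + 1):
        band &= np.abs(freqs - m * f_breath) > harmonic_tolerance_hz
    if not band.any():
        raise NoHeartRateError("search band empty after harmonic exclusion")
    f_heart = float(freqs[band][np.argmax(power[band])])

    return SpectrumResult(
        frequencies=freqs,
        power=power,
        breathing_frequency=f_breath,
        heart_rate_bpm=60.0 * f_heart,
        search_band_bpm=tuple(band_bpm),
    )


def compute_breathing_trace(
    series: ProjectionSeries,
    roi: ROI,
    K: int = DEFAULT_K,
    margin_degrees: float = DEFAULT_MARGIN_DEGREES,
) -> BreathingTrace:
    """Convenience chain: ROI trace -> background removal -> normalization."""
    raw = extract_roi_trace(series, roi)
    background, corrected = remove_background(raw, K=K)
    return prepare_trace(
        corrected, series, raw=raw, background=background,
        margin_degrees=margin_degrees,
    )
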
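"""Expiration-gated sinogram assembly, FBP reconstruction, lung segmentation.

A 720-degree acquisition samples every projection angle twice. For each
angle the frame whose breathing-trace value is lower (deeper in expiration)
is kept; if both candidates are in deep expiration (below the averaging
level) their mean is used, which lowers the photon-noise level. Angles at
which neither candidate falls below the selection level are counted as
unreliable — the reliability figure of the whole approach. The gated
sinogram is reconstructed slice-wise by parallel-beam filtered back
projection of -log(intensity / flat), and the lung is segmented with a
simple threshold halfway between the lung and soft-tissue class means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .exceptions import GeometryError, InvalidParameterError
from .phantom import ProjectionSeries
from .trace import BreathingTrace

__all__ = [
    "GatedSinogram",
    "ReconVolume",
    "LungMask",
    "pair_and_select",
    "ungated_sinogram",
    "reconstruct_fbp",
    "compute_lung_threshold",
    "segment_lung",
]

log = logging.getLogger(__name__)

DEFAULT_SELECT_LEVEL = 0.3
DEFAULT_AVG_LEVEL = 0.1


@dataclass
class GatedSinogram:
    """One projection per unique angle over [0, 360), with provenance."""

    projections: np.ndarray  # (n_angles, n_rows, n_det)
    angles: np.ndarray  # degrees, ascending in [0, 360)
    provenance: list[str]  # per angle: 'rotation1' | 'rotation2' | 'averaged'
    unreliable_count: int
    selection_level: float
    averaging_level: float
    pixel_size: float  # mm, detector sampling
    flats: np.ndarray | None = None  # per-angle flat-field intensity
    trace_values: np.ndarray | None = None  # selected frame's breathing value


@dataclass
class ReconVolume:
    slices: np.ndarray  # (n_slices, grid_side, grid_side) attenuation, 1/mm
    grid_side: int
    voxel_size: float  # mm
    rows: np.ndarray | None = None  # source detector rows


@dataclass
class LungMask:
    mask: np.ndarray  # boolean, aligned with a ReconVolume slice
    threshold_used: float


def _full_range_normalized(trace: BreathingTrace) -> np.ndarray:
    """Corrected trace rescaled to breathing units over ALL frames.

    Frame selection needs a value at every angle, including the margin
    frames excluded from event detection, so gating rescales the corrected
    trace over its full length. The scaling anchors (min/max) are taken
    over the valid range only — background-correction artifacts at the
    acquisition edges would otherwise stretch the scale and shift the
    selection levels; margin frames may therefore fall slightly outside
    [0, 1].
    """
    c = trace.corrected
    sel = trace.valid_mask if trace.valid_mask.any() else np.ones(len(c), bool)
    lo, hi = c[sel].min(), c[sel].max()
    if hi <= lo:
        raise InvalidParameterError("corrected trace is constant")
    return (c - lo) / (hi - lo)


def _series_flats(series: ProjectionSeries) -> np.ndarray | None:
    gt = series.metadata.get("ground_truth", {})
    acq = series.metadata.get("acquisition", {})
    drift = gt.get("drift")
    photons = acq.get("photon_count")
    if drift is None:
        return None
    drift = np.asarray(drift, dtype=float)
    return drift * (photons if photons is not None else 1.0)


def pair_and_select(
    series: ProjectionSeries,
    trace: BreathingTrace,
    select_level: float = DEFAULT_SELECT_LEVEL,
    avg_level: float = DEFAULT_AVG_LEVEL,
) -> GatedSinogram:
    """Re-bin a two-rotation series into one expiration-gated 360 deg set.

    For angle i the candidates are frames i and i + N/2. The frame with the
    lower breathing value wins; if both values are below ``avg_level`` the
    two frames are averaged. If neither value is below ``select_level`` the
    angle is counted as unreliable (the lower-valued frame is still used).
    """
    n = series.n_frames
    if n % 2 != 0:
        raise GeometryError("two-rotation pairing requires an even frame count")
    if abs(series.total_rotation - 720.0) > 1e-6:
        raise GeometryError("pairing requires a 720 degree acquisition")
    if trace.n_frames != n:
        raise GeometryError("trace is not aligned to the series")

    values = _full_range_normalized(trace)
    half = n // 2
    flats_in = _series_flats(series)

    projections = np.empty((half,) + series.frames.shape[1:], dtype=np.float64)
    provenance: list[str] = []
    selected = np.empty(half)
    flats = np.empty(half) if flats_in is not None else None
    unreliable = 0
    for i in range(half):
        v1, v2 = values[i], values[i + half]
        if v1 < avg_level and v2 < avg_level:
            projections[i] = 0.5 * (
                series.frames[i].astype(np.float64)
                + series.frames[i + half].astype(np.float64)
            )
            provenance.append("averaged")
            selected[i] = min(v1, v2)
            if flats is not None:
                flats[i] = 0.5 * (flats_in[i] + flats_in[i + half])
        else:
            j = i if v1 <= v2 else i + half
            projections[i] = series.frames[j]
            provenance.append("rotation1" if j == i else "rotation2")
            selected[i] = values[j]
            if flats is not None:
                flats[i] = flats_in[j]
        if min(v1, v2) >= select_level:
            unreliable += 1

    log.info("gated sinogram: %d/%d unreliable angles", unreliable, half)
    return GatedSinogram(
        projections=projections,
        angles=np.mod(series.angles[:half], 360.0),
        provenance=provenance,
        unreliable_count=unreliable,
        selection_level=select_level,
        averaging_level=avg_level,
        pixel_size=series.pixel_size,
        flats=flats,
        trace_values=selected,
    )


def ungated_sinogram(series: ProjectionSeries) -> GatedSinogram:
    """Breathing-blind baseline: average the two frames at every angle."""
    n = series.n_frames
    if n % 2 != 0 or abs(series.total_rotation - 720.0) > 1e-6:
        raise GeometryError("requires an even-frame 720 degree acquisition")
    half = n // 2
    frames = series.frames.astype(np.float64)
    projections = 0.5 * (frames[:half] + frames[half:])
    flats_in = _series_flats(series)
    flats = None
    if flats_in is not None:
        flats = 0.5 * (flats_in[:half] + flats_in[half:])
    return GatedSinogram(
        projections=projections,
        angles=np.mod(series.angles[:half], 360.0),
        provenance=["averaged"] * half,
        unreliable_count=0,
        selection_level=1.0,
        averaging_level=1.0,
        pixel_size=series.pixel_size,
        flats=flats,
    )


def _flat_from_air(projection: np.ndarray, margin_cols: int = 16) -> float:
    """Per-frame flat estimate: median over the outermost detector columns."""
    edges = np.concatenate(
        [projection[:, :margin_cols].ravel(), projection[:, -margin_cols:].ravel()]
    )
    return float(np.median(edges))


def reconstruct_fbp(
    gated: GatedSinogram,
    grid_side: int = 512,
    rows: np.ndarray | list[int] | None = None,
) -> ReconVolume:
    """Slice-wise ramp-filtered parallel-beam back projection.

    Each detector row's sinogram is converted to line integrals by
    -log(I / flat) — the flat is the simulated tube intensity when the
    sinogram carries one, else a per-frame air-region median — resampled
    onto ``grid_side`` detector bins spanning the native extent, and passed
    through a standard FBP (ramp filter, linear interpolation). Output
    values are attenuation in 1/mm on an isotropic ``grid_side``^2 grid.
    """
    angles = gated.angles
    spacing = np.diff(angles)
    if len(spacing) and not np.allclose(spacing, spacing[0], atol=1e-6):
        raise GeometryError("projection angles must be equally spaced")
    n_angles, n_rows, n_det = gated.projections.shape
    if rows is None:
        rows = np.asarray([n_rows // 2])
    rows = np.asarray(rows, dtype=int)

    tiny = np.finfo(float).tiny
    if gated.flats is not None:
        flats = np.asarray(gated.flats, dtype=float)
    else:
        flats = np.asarray(
            [_flat_from_air(p) for p in gated.projections], dtype=float
        )
    trans = np.clip(
        gated.projections / np.maximum(flats, tiny)[:, None, None], tiny, None
    )
    line = -np.log(trans)  # (n_angles, n_rows, n_det), units: mm * (1/mm)

    extent = n_det * gated.pixel_size
    voxel = extent / grid_side
    u_in = (np.arange(n_det) - (n_det - 1) / 2.0) * gated.pixel_size
    u_out = (np.arange(grid_side) - (grid_side - 1) / 2.0) * voxel

    slices = np.empty((len(rows), grid_side, grid_side))
    for s, r in enumerate(rows):
        sino = np.stack(
            [np.interp(u_out, u_in, line[a, r, :], left=0.0, right=0.0)
             for a in range(n_angles)],
            axis=1,
        )  # (grid_side, n_angles)
        recon = iradon(
            sino, theta=angles, filter_name="ramp", interpolation="linear",
            circle=True, output_size=grid_side,
        )
        # iradon's y axis points up; our rasters are row-down
        slices[s] = recon[::-1] / voxel  # per-pixel values -> 1/mm
    return ReconVolume(slices=slices, grid_side=grid_side, voxel_size=voxel,
                       rows=rows)


def compute_lung_threshold(lung_mean: float, tissue_mean: float) -> float:
    """Arithmetic mean of the lung and soft-tissue class means."""
    if not lung_mean < tissue_mean:
        raise InvalidParameterError("lung mean must be below tissue mean")
    return 0.5 * (lung_mean + tissue_mean)


def segment_lung(
    slice_: np.ndarray,
    threshold: float,
    body_mask: np.ndarray,
    min_size: int = 20,
) -> LungMask:
    """Threshold segmentation of the lung inside the body support.

    Pixels below the threshold and inside ``body_mask`` (the stand-in for
    manual removal of outside air) form the candidate mask; connected
    components smaller than ``min_size`` pixels are discarded.
    """
    if not np.isfinite(threshold):
        raise InvalidParameterError("threshold must be finite")
    candidate = (slice_ < threshold) & body_mask
    labels, n = ndimage.label(candidate)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_size) + 1
        mask = np.isin(labels, keep)
    else:
        mask = candidate
    if not mask.any():
        log.warning("lung segmentation produced an empty mask")
    return LungMask(mask=mask, threshold_used=float(threshold))
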
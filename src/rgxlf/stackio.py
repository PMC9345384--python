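"""Projection-stack I/O: multi-page TIFF plus a JSON metadata sidecar.

A simulated or measured acquisition is stored as ``<prefix>.tif`` (one page
per projection frame, float32) and ``<prefix>.json`` carrying per-frame
angles and timestamps, the detector pixel size, and — for simulated data —
the full ground-truth block. The pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import FormatError
from .phantom import AcquisitionConfig, ProjectionSeries

__all__ = ["write_projection_stack", "read_projection_stack"]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_projection_stack(series: ProjectionSeries, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tif`` + ``<prefix>.json``; returns both paths."""
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    tifffile.imwrite(tif_path, np.asarray(series.frames, dtype=np.float32))
    sidecar = {
        "n_frames": int(series.n_frames),
        "angles_deg": series.angles.tolist(),
        "times_s": series.times.tolist(),
        "pixel_size_mm": float(series.pixel_size),
        "metadata": _jsonify(series.metadata),
    }
    json_path.write_text(json.dumps(sidecar))
    return tif_path, json_path


def _protocol_geometry(protocol: str, n_frames: int):
    if protocol == "ct":
        acq = AcquisitionConfig(n_frames=n_frames)
    elif protocol == "planar":
        acq = AcquisitionConfig.planar(n_frames=n_frames)
    else:
        raise FormatError(f"unknown protocol {protocol!r}")
    times = np.arange(n_frames) * acq.total_time / (n_frames - 1)
    angles = np.arange(n_frames) * acq.total_rotation / (n_frames - 1)
    return angles, times


def read_projection_stack(
    prefix: str | Path,
    protocol: str | None = None,
) -> ProjectionSeries:
    """Read a stack written by :func:`write_projection_stack`.

    When the sidecar is missing, ``protocol`` ('ct' or 'planar') supplies
    default angles and timestamps; without either, a FormatError is raised.
    A frame-count mismatch between TIFF and sidecar is a FormatError.
    """
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]

    if json_path.exists():
        sidecar = json.loads(json_path.read_text())
        if int(sidecar["n_frames"]) != len(frames):
            raise FormatError(
                f"sidecar says {sidecar['n_frames']} frames, TIFF has {len(frames)}"
            )
        metadata = sidecar.get("metadata", {})
        gt = metadata.get("ground_truth")
        if gt:
            metadata["ground_truth"] = {
                k: np.asarray(v) if isinstance(v, list) else v for k, v in gt.items()
            }
        return ProjectionSeries(
            frames=frames,
            angles=np.asarray(sidecar["angles_deg"], dtype=float),
            times=np.asarray(sidecar["times_s"], dtype=float),
            pixel_size=float(sidecar["pixel_size_mm"]),
            metadata=metadata,
        )

    if protocol is None:
        raise FormatError(
            f"no sidecar at {json_path} and no acquisition protocol given"
        )
    angles, times = _protocol_geometry(protocol, len(frames))
    return ProjectionSeries(
        frames=frames, angles=angles, times=times, pixel_size=1.0,
        metadata={"acquisition": {"protocol": protocol}},
    )
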
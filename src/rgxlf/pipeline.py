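"""End-to-end pipeline: simulate -> trace -> lung function -> gate -> recon.

``run_pipeline`` chains every stage on a simulated acquisition, echoes all
parameters into the report for provenance, and writes the artifact bundle
(trace CSV, report JSON, gated sinogram / reconstruction / lung-mask TIFFs).
Planar acquisitions skip the gating and reconstruction stages and still
produce the full lung-function report — the planar and rotational modes
share the identical trace analysis code path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from . import phantom as ph
from .config import RunConfig
from .gating import (
    compute_lung_threshold,
    pair_and_select,
    reconstruct_fbp,
    segment_lung,
)
from .lungfunc import fit_expiration, lung_function_report, segment_event_phases
from .stackio import write_projection_stack
from .trace import ROI, analyze_spectrum, compute_breathing_trace, detect_events

__all__ = ["run_pipeline", "trace_to_frame", "trace_from_frame"]

log = logging.getLogger(__name__)


def trace_to_frame(trace) -> pd.DataFrame:
    """Tabular view of a BreathingTrace (one row per projection frame)."""
    return pd.DataFrame(
        {
            "frame": np.arange(trace.n_frames),
            "time_s": trace.times,
            "angle_deg": trace.angles,
            "raw": trace.raw,
            "background": trace.background,
            "corrected": trace.corrected,
            "normalized": trace.normalized,
            "valid": trace.valid_mask.astype(int),
        }
    )


def trace_from_frame(df: pd.DataFrame):
    """Rebuild a BreathingTrace from :func:`trace_to_frame` output."""
    from .trace import BreathingTrace

    times = df["time_s"].to_numpy(float)
    return BreathingTrace(
        raw=df["raw"].to_numpy(float),
        background=df["background"].to_numpy(float),
        corrected=df["corrected"].to_numpy(float),
        normalized=df["normalized"].to_numpy(float),
        valid_mask=df["valid"].to_numpy(bool),
        sampling_rate=1.0 / float(np.median(np.diff(times))),
        angles=df["angle_deg"].to_numpy(float),
        times=times,
    )


def _reconstruction_class_means(slice_, cfg: ph.PhantomConfig, voxel_size, z):
    """Lung / soft-tissue means measured in eroded known regions."""
    grid = slice_.shape[0]
    lung = ph.rasterize_lung_mask(cfg, grid, voxel_size, 0.0, z)
    body = ph.rasterize_body_mask(cfg, grid, voxel_size)
    bone = slice_ > 0.8 * cfg.attenuation_bone
    lung_in = ndimage.binary_erosion(lung, iterations=3)
    soft = ndimage.binary_erosion(body & ~lung & ~bone, iterations=3)
    return float(slice_[lung_in].mean()), float(slice_[soft].mean())


def run_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    acq = dataclasses.replace(cfg.acquisition, seed=cfg.seed)
    log.info("simulating %d frames over %g degrees", acq.n_frames, acq.total_rotation)
    series = ph.generate_acquisition(cfg.phantom, acq, cfg.breathing)
    write_projection_stack(series, out / "projections")

    roi = ROI(*ph.interface_roi(cfg.phantom))
    trace = compute_breathing_trace(
        series, roi, K=cfg.trace.K, margin_degrees=cfg.trace.margin_degrees
    )
    trace_to_frame(trace).to_csv(out / "trace.csv", index=False)

    events = detect_events(trace, level=cfg.trace.level)
    refined = segment_event_phases(trace, events)
    fit = fit_expiration(refined)
    spectrum = analyze_spectrum(trace, band_bpm=cfg.trace.heart_band_bpm)
    report_obj = lung_function_report(trace, refined, fit, spectrum)

    report = {
        "seed": cfg.seed,
        "protocol": "ct" if acq.total_rotation > 0 else "planar",
        "roi": dataclasses.asdict(roi),
        "parameters": {
            "K": cfg.trace.K,
            "level": cfg.trace.level,
            "margin_degrees": cfg.trace.margin_degrees,
            "select_level": cfg.gating.select_level,
            "avg_level": cfg.gating.avg_level,
            "grid_side": cfg.gating.grid_side,
        },
        "lung_function": dataclasses.asdict(report_obj),
        "expiration_fit": dataclasses.asdict(fit),
        "n_raw_events": len(events),
    }

    if acq.total_rotation > 0:
        gated = pair_and_select(
            series, trace,
            select_level=cfg.gating.select_level, avg_level=cfg.gating.avg_level,
        )
        tifffile.imwrite(out / "gated.tif",
                         gated.projections.astype(np.float32))
        (out / "gated.json").write_text(json.dumps({
            "angles_deg": gated.angles.tolist(),
            "provenance": gated.provenance,
            "unreliable_count": gated.unreliable_count,
        }))
        log.info("unreliable angles: %d of %d",
                 gated.unreliable_count, len(gated.angles))
        report["gating"] = {
            "unreliable_count": gated.unreliable_count,
            "n_angles": int(len(gated.angles)),
            "averaged": int(sum(p == "averaged" for p in gated.provenance)),
        }

        z = ph.reference_slice_z(cfg.phantom)
        row = int(z / cfg.phantom.pixel_size)
        vol = reconstruct_fbp(gated, grid_side=cfg.gating.grid_side, rows=[row])
        tifffile.imwrite(out / "recon.tif", vol.slices.astype(np.float32))

        lung_mean, tissue_mean = _reconstruction_class_means(
            vol.slices[0], cfg.phantom, vol.voxel_size, z
        )
        threshold = compute_lung_threshold(lung_mean, tissue_mean)
        body = ph.rasterize_body_mask(cfg.phantom, vol.grid_side, vol.voxel_size)
        mask = segment_lung(vol.slices[0], threshold, body)
        tifffile.imwrite(out / "lung_mask.tif",
                         (mask.mask * 255).astype(np.uint8))
        report["segmentation"] = {
            "lung_mean": lung_mean,
            "tissue_mean": tissue_mean,
            "threshold": threshold,
            "lung_pixels": int(mask.mask.sum()),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
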
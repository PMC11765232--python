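"""File formats: delimited-text measurements and waveforms, float TIFF images,
JSON manifests and reports, 1-bit PNG mask export."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .detect import DetectionResult
from .instrument import AdcSpec, MeasurementSeries, NoiseModel
from .patterns import MaskSequence
from .reconstruct import ReconImage
from .tof import Tpsf


def write_measurements(path: str | Path, series: MeasurementSeries) -> None:
    """Three-column TSV (pattern_index, y_plus, y_minus) plus a JSON sidecar."""
    path = Path(path)
    idx = np.arange(series.pattern_count)
    np.savetxt(
        path,
        np.column_stack([idx, series.y_plus, series.y_minus]),
        fmt=("%d", "%.10e", "%.10e"),
        delimiter="\t",
        header="pattern_index\ty_plus\ty_minus",
    )
    sidecar = {
        "band": series.band,
        "gain": series.gain,
        "adc": dataclasses.asdict(series.adc) if series.adc else None,
        "noise": dataclasses.asdict(series.noise) if series.noise else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_measurements(path: str | Path) -> MeasurementSeries:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    adc = AdcSpec(**meta["adc"]) if meta.get("adc") else None
    noise = NoiseModel(**meta["noise"]) if meta.get("noise") else None
    return MeasurementSeries(
        band=meta.get("band"),
        y_plus=data[:, 1],
        y_minus=data[:, 2],
        gain=meta["gain"],
        adc=adc,
        noise=noise,
    )


def write_waveform(path: str | Path, waveform: Tpsf) -> None:
    """Two-column delimited text: time_ps, intensity."""
    np.savetxt(
        path,
        np.column_stack([waveform.t, waveform.intensity]),
        fmt="%.10e",
        delimiter="\t",
        header="time_ps\tintensity",
    )


def read_waveform(path: str | Path, d: float | None = None) -> Tpsf:
    data = np.loadtxt(path, delimiter="\t")
    return Tpsf(t=data[:, 0], intensity=np.clip(data[:, 1], 0.0, None), d=d)


def write_recon_tiff(path: str | Path, recon: ReconImage) -> None:
    """32-bit float TIFF plus a JSON sidecar with method and solver stats."""
    path = Path(path)
    tifffile.imwrite(path, recon.image.astype(np.float32))
    stats = recon.solver_stats
    if stats is not None:
        stats = {k: v for k, v in stats.items() if k != "objective_history"}
    sidecar = {
        "band": recon.band,
        "method": recon.method,
        "sampling_ratio": recon.sampling_ratio,
        "solver_stats": stats,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recon_tiff(path: str | Path) -> ReconImage:
    path = Path(path)
    image = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ReconImage(
        band=meta.get("band"),
        image=image,
        method=meta["method"],
        sampling_ratio=meta["sampling_ratio"],
        solver_stats=meta.get("solver_stats"),
    )


def write_image_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def detection_to_dict(result: DetectionResult) -> dict:
    return {
        "contaminated": bool(result.contaminated),
        "degenerate": bool(result.degenerate),
        "threshold": result.threshold,
        "min_area_px": result.min_area_px,
        "connectivity": result.connectivity,
        "removed_components": result.removed_components,
        "loadings": [float(v) for v in np.atleast_1d(result.loadings)],
        "candidate_pixels": int(np.count_nonzero(result.binary)),
        "surviving_pixels": int(np.count_nonzero(result.binary_denoised)),
        "floored_reference_pixels": result.floored_pixels,
    }


def write_detection_json(path: str | Path, result: DetectionResult) -> None:
    Path(path).write_text(json.dumps(detection_to_dict(result), indent=1))


def export_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a 1-bit PNG."""
    mask = np.asarray(mask)
    Image.fromarray((mask > 0).astype(np.uint8) * 255).convert("1").save(Path(path))


def write_mask_metadata(path: str | Path, seq: MaskSequence) -> None:
    Path(path).write_text(json.dumps(seq.metadata(), indent=1))
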
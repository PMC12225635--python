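"""File-format plumbing: TIFF cubes and masks, CSV tables, JSON metadata.

Decay cubes travel as multi-frame TIFF (frame index = time bin) with a
JSON sidecar holding the acquisition metadata; label masks as single-frame
16-bit TIFF; fitted parameter maps as per-variable 32-bit float TIFFs plus
a CSV summary.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .acquisition import AcquisitionSpec
from .cellquant import MaskSet, derive_cytoplasm
from .decay import DecayCube, FitOptions, ParameterMap

__all__ = [
    "write_decay_tiff",
    "read_decay_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_maskset",
    "read_maskset",
    "write_parameter_map",
    "read_parameter_map",
]

_PMAP_VARS = (
    "tau_m_ns", "tau1_ns", "tau2_ns", "alpha1",
    "background_C", "chi2_reduced", "photons",
)


def _spec_to_meta(spec: AcquisitionSpec) -> dict:
    return {
        "width": spec.width,
        "height": spec.height,
        "n_bins": spec.n_bins,
        "window_ns": spec.window_ns,
        "irf_fwhm_ps": spec.irf_fwhm_ps,
        "channel": spec.channel,
    }


def _spec_from_meta(meta: dict) -> AcquisitionSpec:
    return AcquisitionSpec(
        width=int(meta["width"]),
        height=int(meta["height"]),
        n_bins=int(meta["n_bins"]),
        window_ns=float(meta["window_ns"]),
        irf_fwhm_ps=float(meta["irf_fwhm_ps"]),
        channel=str(meta["channel"]),
    )


def write_decay_tiff(cube: DecayCube, path, meta_path=None) -> None:
    """Write a cube as multi-frame TIFF (frame = time bin) + JSON sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    frames = np.moveaxis(cube.counts, 2, 0).astype(np.uint32)
    tifffile.imwrite(path, frames)
    meta = _spec_to_meta(cube.spec)
    meta["field_id"] = cube.field_id
    meta_path.write_text(json.dumps(meta, indent=1))


def read_decay_tiff(path, meta_path=None) -> DecayCube:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != int(meta["n_bins"]):
        raise ValueError(
            f"frame count {frames.shape[0]} does not match metadata "
            f"n_bins {meta['n_bins']}"
        )
    spec = _spec_from_meta(meta)
    counts = np.moveaxis(frames, 0, 2).astype(np.int64)
    return DecayCube(counts=counts, spec=spec, field_id=meta.get("field_id", "field0"))


def write_mask_tiff(mask: np.ndarray, path) -> None:
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label image exceeds 16-bit range")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def write_maskset(masks: MaskSet, directory, prefix: str = "") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mask_tiff(masks.whole_cell, d / f"{prefix}cells.tif")
    write_mask_tiff(masks.nuclei, d / f"{prefix}nuclei.tif")


def read_maskset(directory, prefix: str = "") -> MaskSet:
    d = Path(directory)
    whole = read_mask_tiff(d / f"{prefix}cells.tif")
    nucs = read_mask_tiff(d / f"{prefix}nuclei.tif")
    return derive_cytoplasm(whole, nucs)


def write_parameter_map(pmap: ParameterMap, directory, prefix: str = "") -> None:
    """Per-variable float32 TIFFs, validity, a JSON sidecar and a CSV
    summary of each variable over the valid pixels."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for var in _PMAP_VARS:
        tifffile.imwrite(d / f"{prefix}{var}.tif", pmap.variable(var).astype(np.float32))
    tifffile.imwrite(d / f"{prefix}valid.tif", pmap.valid.astype(np.uint8))
    meta = _spec_to_meta(pmap.spec)
    meta["field_id"] = pmap.field_id
    meta["min_photons"] = pmap.options.min_photons
    (d / f"{prefix}meta.json").write_text(json.dumps(meta, indent=1))

    lines = ["variable,n_valid,mean,sd,median"]
    for var in _PMAP_VARS:
        vals = pmap.variable(var)[pmap.valid]
        if vals.size:
            lines.append(
                f"{var},{vals.size},{np.nanmean(vals):.6g},"
                f"{np.nanstd(vals, ddof=1) if vals.size > 1 else float('nan'):.6g},"
                f"{np.nanmedian(vals):.6g}"
            )
        else:
            lines.append(f"{var},0,nan,nan,nan")
    (d / f"{prefix}summary.csv").write_text("\n".join(lines) + "\n")


def read_parameter_map(directory, prefix: str = "") -> ParameterMap:
    d = Path(directory)
    meta = json.loads((d / f"{prefix}meta.json").read_text())
    arrays = {
        var: tifffile.imread(d / f"{prefix}{var}.tif").astype(float)
        for var in _PMAP_VARS
    }
    valid = tifffile.imread(d / f"{prefix}valid.tif").astype(bool)
    return ParameterMap(
        tau1_ns=arrays["tau1_ns"],
        tau2_ns=arrays["tau2_ns"],
        alpha1=arrays["alpha1"],
        background_C=arrays["background_C"],
        tau_m_ns=arrays["tau_m_ns"],
        chi2_reduced=arrays["chi2_reduced"],
        photons=arrays["photons"],
        valid=valid,
        spec=_spec_from_meta(meta),
        options=FitOptions(min_photons=float(meta.get("min_photons", 100.0))),
        field_id=meta.get("field_id", "field0"),
    )
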
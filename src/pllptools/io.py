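"""TIFF and sidecar I/O.

Volumes are written as ImageJ-compatible TIFF stacks with the voxel
spacing recorded in the metadata (x/y resolution plus the ImageJ
``spacing`` field for z); label images as 16-bit, masks as 8-bit 0/255.
Ground truth and provenance travel in JSON sidecars next to the images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import LabelVolume, Mask, Volume
from .synthetic import GroundTruth

__all__ = [
    "save_volume", "load_volume", "save_labels", "load_labels",
    "save_mask", "load_mask", "save_ground_truth", "load_ground_truth_sidecar",
    "save_timelapse", "load_timelapse",
]


def _imagej_kwargs(spacing):
    dz, dy, dx = spacing
    return dict(
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def _read_spacing(tif) -> tuple[float, float, float]:
    page = tif.pages[0]
    dz = 1.0
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        dz = float(meta["spacing"])
    def res_to_um(tag):
        num, den = tag.value
        return den / num if num else 1.0
    dx = res_to_um(page.tags["XResolution"]) if "XResolution" in page.tags else 1.0
    dy = res_to_um(page.tags["YResolution"]) if "YResolution" in page.tags else 1.0
    return (dz, dy, dx)


def save_volume(path, v: Volume) -> None:
    tifffile.imwrite(path, v.data.astype(np.float32), **_imagej_kwargs(v.spacing))


def load_volume(path, spacing=None) -> Volume:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if spacing is None:
            spacing = _read_spacing(tif)
    return Volume(np.atleast_3d(data.astype(np.float64)), spacing)


def save_labels(path, lv: LabelVolume) -> None:
    if lv.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(path, lv.labels.astype(np.uint16), **_imagej_kwargs(lv.spacing))


def load_labels(path, spacing=None) -> LabelVolume:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if spacing is None:
            spacing = _read_spacing(tif)
    return LabelVolume(data.astype(np.int32), spacing)


def save_mask(path, m: Mask) -> None:
    tifffile.imwrite(path, (m.mask.astype(np.uint8) * 255),
                     **_imagej_kwargs(m.spacing))


def load_mask(path, spacing=None) -> Mask:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if spacing is None:
            spacing = _read_spacing(tif)
    return Mask(data > 0, spacing)


def save_timelapse(path, frames) -> None:
    stack = np.stack([f.data.astype(np.float32) for f in frames])
    dz, dy, dx = frames[0].spacing
    tifffile.imwrite(
        path, stack, imagej=True, resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "TZYX"},
    )


def load_timelapse(path, spacing=None) -> list[Volume]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if spacing is None:
            spacing = _read_spacing(tif)
    if data.ndim == 3:
        data = data[:, None]
    return [Volume(frame.astype(np.float64), spacing) for frame in data]


def save_ground_truth(path_prefix, gt: GroundTruth, spec=None) -> None:
    """Write the label TIFF plus a JSON sidecar (centers, EdU positives,
    true speed, and an echo of the generating parameters)."""
    prefix = Path(path_prefix)
    save_labels(prefix.with_suffix(".labels.tif"), gt.labels)
    sidecar = {
        "n_cells": gt.n_cells,
        "centers_um_zyx": np.asarray(gt.centers).tolist(),
        "edu_positive": sorted(gt.edu_positive),
        "true_speed_um_per_hr": gt.true_speed,
    }
    if spec is not None:
        sidecar["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(spec).items()}
    prefix.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=2))


def load_ground_truth_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
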
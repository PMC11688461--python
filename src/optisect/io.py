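"""TIFF / CSV / JSON round-trip helpers for volumes, raw stacks and curves."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .config import OpticalConfig, ScanConfig
from .phantoms import SampleVolume
from .simulate import RawOffAxisStack

__all__ = [
    "write_volume",
    "read_volume",
    "write_stack",
    "read_stack",
    "write_curves",
    "read_curves",
]

_DEFAULT_VOXEL = (0.5, 0.325, 0.325)


def write_volume(volume: SampleVolume, path, labels_path=None) -> None:
    """Write a volume as 32-bit multi-page TIFF with voxel-size metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        volume.values.astype(np.float32),
        metadata={"voxel_um": list(volume.voxel), **volume.meta},
    )
    if labels_path is not None and volume.labels is not None:
        tifffile.imwrite(Path(labels_path), volume.labels.astype(np.uint8))


def read_volume(path, labels_path=None) -> SampleVolume:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
    voxel = meta.pop("voxel_um", None)
    if voxel is None:
        import logging

        logging.getLogger(__name__).warning(
            "no voxel metadata in %s; assuming %s um", path, _DEFAULT_VOXEL
        )
        voxel = _DEFAULT_VOXEL
    meta.pop("shape", None)
    labels = None
    if labels_path is not None and Path(labels_path).exists():
        labels = tifffile.imread(labels_path).astype(bool)
    return SampleVolume(
        values=values, voxel=tuple(float(v) for v in voxel), labels=labels, meta=meta
    )


def write_stack(stack: RawOffAxisStack, path) -> None:
    """Raw off-axis stack: one TIFF page per line + a JSON config sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    sidecar = {
        "plane_z": stack.plane_z,
        "scan": {
            "n_lines": stack.scan.n_lines,
            "pitch": stack.scan.pitch,
            "scan_step": stack.scan.scan_step,
            "pixel_width": stack.scan.pixel_width,
            "noise": stack.scan.noise,
            "photons_per_unit": stack.scan.photons_per_unit,
            "read_noise_sigma": stack.scan.read_noise_sigma,
            "seed": stack.scan.seed,
        },
        "optical": {
            "na_det": stack.optical.na_det,
            "na_ill": stack.optical.na_ill,
            "wavelength_ex": stack.optical.wavelength_ex,
            "wavelength_em": stack.optical.wavelength_em,
            "refractive_index": stack.optical.refractive_index,
            "magnification": stack.optical.magnification,
        },
        "meta": stack.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> RawOffAxisStack:
    path = Path(path)
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text())
    return RawOffAxisStack(
        images=images,
        plane_z=sidecar["plane_z"],
        scan=ScanConfig(**sidecar["scan"]),
        optical=OpticalConfig(**sidecar["optical"]),
        meta=sidecar.get("meta", {}),
    )


def write_curves(frame, path) -> None:
    """Long-format curve table (method, u, I) to CSV."""
    frame.to_csv(path, index=False)


def read_curves(path):
    import pandas as pd

    return pd.read_csv(path)
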
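"""Synthetic 3-D fluorophore-density phantoms.

The main phantom emulates a filamentous sample: smooth random 3-D
trajectories rasterized as tubes in a volume block, with intensity varying
randomly along the axial position.  Analytic probes (thin fluorescent
sheet, single point source) validate the simulator against the axial
response and PSF models.

All generators are pure functions of (parameters, seed).
Array layout is (z, y, x); voxel sizes are (dz, dy, dx) in micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SampleVolume",
    "generate_trajectory_volume",
    "fluorescent_sheet",
    "point_source",
]

log = logging.getLogger(__name__)


@dataclass
class SampleVolume:
    """3-D fluorophore density with physical voxel sizes.

    ``labels`` marks structure voxels (tube interiors) for SBR scoring.
    """

    values: np.ndarray                     # (nz, ny, nx), >= 0
    voxel: tuple[float, float, float]      # (dz, dy, dx) um
    labels: Optional[np.ndarray] = None    # bool, same shape
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("fluorophore density must be non-negative")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be positive")
        if self.labels is not None and self.labels.shape != self.values.shape:
            raise ValueError("labels must match the volume shape")

    @property
    def shape(self):
        return self.values.shape

    def z_coords(self) -> np.ndarray:
        """Axial coordinates (um) of the slice centres, centred on 0."""
        nz = self.values.shape[0]
        return (np.arange(nz) - (nz - 1) / 2.0) * self.voxel[0]


def _smooth_path(n_steps: int, extent: np.ndarray, rng, smooth: float = 20.0):
    """Gaussian-smoothed random-walk trajectory inside the given extents."""
    steps = rng.standard_normal((n_steps, 3))
    steps = ndimage.gaussian_filter1d(steps, smooth, axis=0)
    path = np.cumsum(steps, axis=0)
    path -= path.mean(axis=0)
    # scale each axis into the central 80% of the volume
    span = np.abs(path).max(axis=0)
    span[span == 0] = 1.0
    path = path / span * (0.4 * extent)
    path += extent / 2.0
    return path


def generate_trajectory_volume(
    shape: tuple[int, int, int] = (128, 256, 256),
    voxel: tuple[float, float, float] = (0.5, 0.325, 0.325),
    n_paths: int = 4,
    radius: float = 0.5,
    intensity_sigma: float = 0.5,
    background: float = 0.0,
    seed: int = 0,
) -> SampleVolume:
    """Random-trajectory tube phantom.

    Each path is a smoothed 3-D random walk rasterized as a tube of the
    given radius (um); voxel intensity follows a lognormal law varying
    smoothly with z (the axial fluorescence coefficient).  ``labels`` marks
    tube voxels.
    """
    shape = tuple(int(v) for v in shape)
    if any(v <= 0 for v in shape):
        raise ValueError("shape must be positive")
    voxel_arr = np.asarray(voxel, dtype=float)
    rng = np.random.default_rng(seed)
    extent = np.array(shape, dtype=float) * voxel_arr  # (z, y, x) um

    mask = np.zeros(shape, dtype=bool)
    n_steps = 4 * max(shape)
    total_length = 0.0
    for _ in range(n_paths):
        path = _smooth_path(n_steps, extent, rng)
        total_length += float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
        # rasterize densely: walk in steps below half a voxel
        seg = np.diff(path, axis=0)
        seg_len = np.linalg.norm(seg / voxel_arr, axis=1)
        n_sub = np.maximum(1, np.ceil(2 * seg_len).astype(int))
        pts = [path[0]]
        for p0, d, k in zip(path[:-1], seg, n_sub):
            t = np.arange(1, k + 1) / k
            pts.append(p0 + t[:, None] * d)
        pts = np.vstack(pts)
        idx = np.round(pts / voxel_arr - 0.5).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    if n_paths > 0:
        if radius < min(voxel):
            log.warning(
                "tube radius %.3f um is below one voxel; paths are rasterized "
                "as single-voxel chains",
                radius,
            )
            tubes = mask
        else:
            dist = ndimage.distance_transform_edt(~mask, sampling=voxel_arr)
            tubes = dist <= radius
    else:
        tubes = mask

    values = np.zeros(shape, dtype=np.float32)
    if tubes.any():
        # axial fluorescence coefficient: smooth lognormal law in z
        raw = rng.standard_normal(shape[0])
        raw = ndimage.gaussian_filter1d(raw, 4.0, mode="nearest")
        std = raw.std()
        if std > 0:
            raw = raw / std
        a_z = np.exp(intensity_sigma * raw).astype(np.float32)
        values = tubes.astype(np.float32) * a_z[:, None, None]
    if background > 0:
        values = values + np.float32(background)
    return SampleVolume(
        values=values,
        voxel=tuple(float(v) for v in voxel),
        labels=tubes,
        meta={
            "seed": seed,
            "n_paths": n_paths,
            "radius": radius,
            "path_length_um": total_length,
        },
    )


def fluorescent_sheet(
    z0: float,
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
) -> SampleVolume:
    """Thin uniform fluorescent sheet at axial position z0 (um, volume-centred)."""
    nz = shape[0]
    z = (np.arange(nz) - (nz - 1) / 2.0) * voxel[0]
    if not (z.min() - voxel[0] / 2 <= z0 <= z.max() + voxel[0] / 2):
        raise ValueError(f"z0={z0} um outside the volume axial range [{z.min()}, {z.max()}]")
    iz = int(np.argmin(np.abs(z - z0)))
    values = np.zeros(shape, dtype=np.float32)
    values[iz] = 1.0
    labels = np.zeros(shape, dtype=bool)
    labels[iz] = True
    return SampleVolume(values=values, voxel=tuple(voxel), labels=labels)


def point_source(
    position: tuple[int, int, int],
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
) -> SampleVolume:
    """Single unit-intensity voxel at the given (z, y, x) index."""
    position = tuple(int(p) for p in position)
    if any(not (0 <= p < s) for p, s in zip(position, shape)):
        raise ValueError(f"position {position} outside volume of shape {shape}")
    values = np.zeros(shape, dtype=np.float32)
    values[position] = 1.0
    labels = np.zeros(shape, dtype=bool)
    labels[position] = True
    return SampleVolume(values=values, voxel=tuple(voxel), labels=labels)
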
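"""Configuration objects shared across the package.

All optical quantities live in normalized coordinates internally:

* lateral frequency ``s``, normalized so the incoherent cutoff of the
  detection objective is 2 (physical frequency times lambda/NA);
* axial defocus ``u``, the high-aperture normalized defocus
  ``u = (8 pi n z / lambda) * sin^2(alpha/2)`` with ``sin(alpha) = NA/n``.

Physical inputs (wavelengths, NA, voxel sizes) are in micrometres unless
stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "OpticalConfig",
    "MethodParams",
    "ScanConfig",
    "ReconParams",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical system description.

    Defaults follow a water-immersion 20x detection objective (NA 1.0)
    with green fluorescence, the reference system used throughout the
    comparison calculations.
    """

    na_det: float = 1.0
    na_ill: float = 1.0
    wavelength_ex: float = 0.488
    wavelength_em: float = 0.520
    refractive_index: float = 1.33
    magnification: float = 20.0

    def __post_init__(self) -> None:
        n = self.refractive_index
        if not (0.0 < self.na_det <= n):
            raise ValueError(
                f"na_det must satisfy 0 < NA <= n (got NA={self.na_det}, n={n})"
            )
        if not (0.0 < self.na_ill <= n):
            raise ValueError(
                f"na_ill must satisfy 0 < NA <= n (got NA={self.na_ill}, n={n})"
            )
        if self.wavelength_ex <= 0 or self.wavelength_em <= 0:
            raise ValueError("wavelengths must be strictly positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be strictly positive")

    def wavelength(self, arm: str) -> float:
        if arm == "illumination":
            return self.wavelength_ex
        if arm == "detection":
            return self.wavelength_em
        raise ValueError(f"unknown arm {arm!r}; use 'illumination' or 'detection'")

    def na(self, arm: str) -> float:
        if arm == "illumination":
            return self.na_ill
        if arm == "detection":
            return self.na_det
        raise ValueError(f"unknown arm {arm!r}; use 'illumination' or 'detection'")


#: methods with an axial-response model
METHODS = (
    "confocal_pinhole",
    "confocal_slit",
    "two_photon",
    "structured",
    "hybrid",
    "light_sheet",
    "limo",
    "line_confocal",
    "widefield",
)


@dataclass(frozen=True)
class MethodParams:
    """Parameters of one sectioning method's axial-response model.

    ``b``   illumination spot radius (normalized pupil units); 0 = ideal.
    ``beta``  pinhole/slit half-width (normalized); used by confocal,
              line-confocal and LiMo branches.
    ``c``   light-sheet thickness parameter in normalized defocus units.
    ``s0``  structured-illumination modulation frequency, 0 < s0 <= 2.
    ``s_min, s_max``  hybrid-illumination filter band edges.
    """

    method: str
    b: float = 0.0
    beta: float = 0.5
    c: float = 1.0
    s0: float = 1.0
    s_min: float = 0.0
    s_max: float = 2.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.method in ("confocal_pinhole", "confocal_slit", "limo", "line_confocal"):
            if self.beta <= 0:
                raise ValueError("beta must be > 0 for pinhole/slit/LiMo methods")
        if self.method == "light_sheet" and self.c <= 0:
            raise ValueError("c must be > 0 for light sheet")
        if self.method == "structured" and not (0.0 < self.s0 <= 2.0):
            raise ValueError("s0 must lie in (0, 2]")
        if not (0.0 <= self.s_min <= self.s_max <= 2.0):
            raise ValueError("band edges must satisfy 0 <= s_min <= s_max <= 2")

    @property
    def bw(self) -> float:
        """Hybrid-illumination filter bandwidth."""
        return self.s_max - self.s_min


@dataclass(frozen=True)
class ScanConfig:
    """Off-axis line-scan acquisition geometry and noise settings."""

    n_lines: int = 6
    pitch: float = 0.325           # sample-space line pitch (um)
    scan_step: float = 0.325       # x step per exposure (um)
    pixel_width: Optional[float] = None  # detector pixel width (um); None -> pitch
    noise: str = "poisson+gaussian"  # none | poisson | poisson+gaussian
    photons_per_unit: float = 3000.0  # ~450 photons at a fibre peak
    read_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.pitch <= 0 or self.scan_step <= 0:
            raise ValueError("pitch and scan_step must be > 0")
        if self.noise not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.pixel_width is not None and self.pixel_width <= 0:
            raise ValueError("pixel_width must be > 0")

    @property
    def effective_pixel_width(self) -> float:
        return self.pitch if self.pixel_width is None else self.pixel_width

    def line_offsets(self) -> list[float]:
        """Sample-space x offsets of the detector lines.

        Lines are numbered 1..n_lines across the subarray; for the default
        6-line layout lines 3 and 4 straddle the illumination-line centre, so
        offsets are (n - (n_lines+1)/2) * pitch.
        """
        centre = (self.n_lines + 1) / 2.0
        return [(n - centre) * self.pitch for n in range(1, self.n_lines + 1)]


@dataclass(frozen=True)
class ReconParams:
    """Parameters of the four off-axis reconstructions."""

    method: str = "limo"           # lc | dsim | dhilo | limo
    eta: float = 1.0               # LiMo/DHiLo scaling coefficient
    gamma: float = 0.9             # DHiLo low-pass weight
    filter_cutoff: Optional[float] = None  # cycles/um; None -> 1/(4*pixel)
    k: float = 2.0                 # DSIM normalization (lines per phase)
    dsim_general: bool = False     # use the three-phase mask form

    def __post_init__(self) -> None:
        if self.method not in ("lc", "dsim", "dhilo", "limo"):
            raise ValueError(f"unknown reconstruction {self.method!r}")
        if not (0.0 <= self.gamma <= 2.0):
            raise ValueError("gamma must lie in [0, 2]")
        if self.filter_cutoff is not None and self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be > 0")


@dataclass(frozen=True)
class SampleParams:
    """Phantom-generator parameters (desk-scale defaults)."""

    shape: tuple[int, int, int] = (128, 256, 256)  # (nz, ny, nx)
    voxel: tuple[float, float, float] = (0.5, 0.325, 0.325)  # (dz, dy, dx) um
    n_paths: int = 12
    radius: float = 0.5            # tube radius (um)
    intensity_sigma: float = 0.5   # lognormal sigma of the axial intensity law
    background: float = 0.0        # uniform background density


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end pipeline run."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    recon: ReconParams = field(default_factory=ReconParams)
    sample: SampleParams = field(default_factory=SampleParams)
    output_dir: str = "optisect_out"
    seed: int = 0


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def save_config(cfg, path) -> None:
    """Serialize any config dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


_SECTIONS = {
    "optical": OpticalConfig,
    "scan": ScanConfig,
    "recon": ReconParams,
    "sample": SampleParams,
}


def _build(cls, data: dict):
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig (or a subset of its sections) from YAML."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _build(cls, data[key])
    for key in ("output_dir", "seed"):
        if key in data:
            kwargs[key] = data[key]
    return RunConfig(**kwargs)
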
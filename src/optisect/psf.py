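"""Scalar diffraction PSFs: line illumination, off-axis sub-detector PSFs,
and lateral resolution of the focused/wide-field modes.

The point amplitude is the scalar Debye integral over the circular pupil

    a(r, z) = 2 int_0^1 exp(i u rho^2 / 2) J0(v rho) rho drho,

with radial optical coordinate ``v = 2 pi NA r / lambda`` and normalized
defocus ``u`` from :func:`optisect.pupil.optical_coordinate`; the intensity
PSF is ``h_eff = |a|^2``.  The line-illumination PSF integrates ``h_eff``
along the line direction; the sub-detector PSFs convolve ``h_eff`` with a
rect pixel aperture at off-axis offsets ``n p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import j0, j1

from .config import OpticalConfig
from .pupil import optical_coordinate

__all__ = [
    "debye_amplitude",
    "heff_radial",
    "line_profile",
    "LineIlluminationPSF",
    "SubDetectorPSF",
    "build_line_psf",
    "build_sub_psfs",
    "detection_line_kernels",
    "airy_profile",
    "lateral_fwhm",
    "resolution_ranking",
]

log = logging.getLogger(__name__)


def debye_amplitude(cfg: OpticalConfig, r, z: float, arm: str = "detection"):
    """Complex point amplitude a(r, z); a(0, 0) = 1."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    u = optical_coordinate(float(z), cfg, arm)
    v = 2.0 * np.pi * cfg.na(arm) * r / cfg.wavelength(arm)
    # node count grows with the defocus phase u*rho^2/2 (range u/2 rad)
    n_nodes = int(max(256, 8 * abs(u)))
    nodes, weights = np.polynomial.legendre.leggauss(min(n_nodes, 6000))
    rho = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    phase = np.exp(1j * u * rho**2 / 2.0)
    # (n_r x n_rho) Bessel matrix, chunked to bound memory
    out = np.empty(r.shape, dtype=complex)
    chunk = max(1, 4_000_000 // len(rho))
    for lo in range(0, len(r), chunk):
        vv = v[lo : lo + chunk, None]
        out[lo : lo + chunk] = 2.0 * np.sum(
            w * phase * j0(vv * rho) * rho, axis=1
        )
    return out


def heff_radial(cfg: OpticalConfig, r, z: float, arm: str = "detection"):
    """Radial intensity PSF h_eff(r, z) = |a|^2, peak 1 at the focus."""
    return np.abs(debye_amplitude(cfg, r, z, arm)) ** 2


def _radial_table(cfg, r_max, z, arm):
    # fine sampling near the axis where the in-focus peak is sharp, coarser
    # outside where the defocused halo varies on the ~0.5 um scale
    knee = min(5.0, r_max)
    r = np.concatenate([np.arange(0.0, knee, 0.005), np.arange(knee, r_max + 0.1, 0.05)])
    return r, heff_radial(cfg, r, z, arm)


def _symmetric_grid(half_extent: float, step: float) -> np.ndarray:
    """Grid symmetric about 0, so mirror-image offsets sample identically."""
    pos = np.arange(step, half_extent + step, step)
    return np.concatenate([-pos[::-1], [0.0], pos])


def _heff_xy(x, y, r_tab, h_tab):
    """2-D h_eff map from a radial table (bilinear in r)."""
    rr = np.hypot(x[None, :], y[:, None])
    return np.interp(rr, r_tab, h_tab, right=0.0)


def line_profile(cfg: OpticalConfig, x, z: float, arm: str = "illumination"):
    """Line-illumination profile L(x, z) = int h_eff(x, y, z) dy.

    The line runs along y; integrating the intensity PSF over the line
    direction gives the excitation profile across it.
    """
    x = np.asarray(x, dtype=float)
    r_max = float(np.max(np.abs(x)))
    y_extent = max(4.0 * _airy_radius(cfg, arm), 2.0 * _geometric_radius(cfg, z), 2.0)
    r_tab, h_tab = _radial_table(cfg, np.hypot(r_max, y_extent), z, arm)
    dy = min(cfg.wavelength(arm) / (8.0 * cfg.na(arm)), 0.05)
    y = np.arange(0.0, y_extent, dy)
    rr = np.hypot(x[None, :], y[:, None])
    vals = np.interp(rr, r_tab, h_tab, right=0.0)
    # exploit symmetry in y: integral = 2 * int_0^Y - the y=0 sliver
    out = 2.0 * np.trapezoid(vals, y, axis=0)
    return out


def _airy_radius(cfg: OpticalConfig, arm: str) -> float:
    return 0.61 * cfg.wavelength(arm) / cfg.na(arm)


def _geometric_radius(cfg: OpticalConfig, z: float, arm: str = "detection") -> float:
    n = cfg.refractive_index
    na = cfg.na(arm)
    tan_alpha = na / np.sqrt(n**2 - na**2)
    return abs(z) * tan_alpha


@dataclass(frozen=True)
class LineIlluminationPSF:
    """Line-illumination excitation profile on an (z, x) lattice."""

    x: np.ndarray          # across-line coordinate (um)
    z: np.ndarray          # axial coordinate (um)
    values: np.ndarray     # (nz, nx), in-focus peak normalized to 1

    def profile(self, z_index: int) -> np.ndarray:
        return self.values[z_index]


@dataclass(frozen=True)
class SubDetectorPSF:
    """Detection PSF of one off-axis line: h_eff conv rect(x + n p)."""

    line: int              # 1-based line number across the subarray
    offset: float          # signed off-axis distance n p (um)
    pitch: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray     # (nz, ny, nx)


def build_line_psf(
    cfg: OpticalConfig, x: np.ndarray, z: np.ndarray
) -> LineIlluminationPSF:
    """Evaluate the line-illumination PSF over an (z, x) lattice."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    step = float(np.max(np.diff(x))) if len(x) > 1 else 0.0
    lam = cfg.wavelength("illumination")
    if step > lam / (4.0 * cfg.na_ill):
        log.warning(
            "lateral grid step %.3f um exceeds lambda/(4 NA) = %.3f um; the "
            "line profile will be undersampled",
            step,
            lam / (4.0 * cfg.na_ill),
        )
    vals = np.stack([line_profile(cfg, x, zz) for zz in z])
    iz0 = int(np.argmin(np.abs(z)))
    peak = vals[iz0].max()
    return LineIlluminationPSF(x=x, z=z, values=vals / peak)


def _detection_xy(cfg, x_fine, y, z):
    r_max = float(np.hypot(np.max(np.abs(x_fine)), np.max(np.abs(y))))
    r_tab, h_tab = _radial_table(cfg, r_max, z, "detection")
    return _heff_xy(x_fine, y, r_tab, h_tab)


def _rect_convolve_x(vals, x_fine, x_out, width, offsets):
    """Convolve h(x) with a rect aperture of ``width`` and sample the result
    at ``x_out + offset`` for every offset (cumulative-integral evaluation)."""
    cum = cumulative_trapezoid(vals, x_fine, axis=-1, initial=0.0)

    def _at(pts):
        return np.stack([np.interp(pts, x_fine, c) for c in cum])

    out = []
    for off in offsets:
        hi = _at(x_out + off + width / 2.0)
        lo = _at(x_out + off - width / 2.0)
        out.append(hi - lo)
    return out


def build_sub_psfs(
    cfg: OpticalConfig,
    n_lines: int,
    pitch: float,
    pixel_width: float,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
) -> list[SubDetectorPSF]:
    """Sub-detector PSFs h_eff conv rect for each off-axis line.

    Line ``n`` (1..n_lines) sits at off-axis offset
    ``(n - (n_lines+1)/2) * pitch``: an even layout straddles the
    illumination line, an odd layout centres one line on it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    step = float(np.max(np.diff(x))) if len(x) > 1 else 0.0
    if step > 0 and pitch < step:
        raise ValueError(
            f"pitch {pitch} um is below the grid step {step} um; refine the grid"
        )
    centre = (n_lines + 1) / 2.0
    offsets = [(n - centre) * pitch for n in range(1, n_lines + 1)]
    span = max(abs(o) for o in offsets) + pixel_width
    dxf = min(cfg.wavelength_em / (32.0 * cfg.na_det), step if step > 0 else 0.05)
    x_fine = _symmetric_grid(max(abs(x.min()), abs(x.max())) + span + 1.0, dxf)
    stacks = [np.empty((len(z), len(y), len(x))) for _ in offsets]
    for iz, zz in enumerate(z):
        h2d = _detection_xy(cfg, x_fine, y, zz)
        per_line = _rect_convolve_x(h2d, x_fine, x, pixel_width, offsets)
        for vals, stack in zip(per_line, stacks):
            stack[iz] = vals
    return [
        SubDetectorPSF(
            line=n, offset=off, pitch=pitch, x=x, y=y, z=z, values=stack
        )
        for n, off, stack in zip(range(1, n_lines + 1), offsets, stacks)
    ]


def detection_line_kernels(
    cfg: OpticalConfig,
    x: np.ndarray,
    z: np.ndarray,
    offsets,
    pixel_width: float,
):
    """1-D (across-scan) detection kernels: y-integrated h_eff conv rect,
    sampled at ``x + offset`` per line.  Used by the scan simulator, where
    the y blur is applied separately."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    span = max(abs(o) for o in offsets) + pixel_width
    dxf = min(cfg.wavelength_em / (32.0 * cfg.na_det), 0.05)
    x_fine = _symmetric_grid(max(abs(x.min()), abs(x.max())) + span + 1.0, dxf)
    out = np.empty((len(z), len(offsets), len(x)))
    for iz, zz in enumerate(z):
        lx = line_profile(cfg, x_fine, zz, arm="detection")
        cum = cumulative_trapezoid(lx, x_fine, initial=0.0)
        for io, off in enumerate(offsets):
            hi = np.interp(x + off + pixel_width / 2.0, x_fine, cum)
            lo = np.interp(x + off - pixel_width / 2.0, x_fine, cum)
            out[iz, io] = hi - lo
    return out


def airy_profile(v):
    """Airy intensity pattern |2 J1(v)/v|^2 with peak 1."""
    v = np.asarray(v, dtype=float)
    out = np.ones_like(v)
    nz = v != 0
    out[nz] = (2.0 * j1(v[nz]) / v[nz]) ** 2
    return out


def _fwhm_from_profile(x, y) -> float:
    half = y.max() / 2.0
    above = y >= half
    idx = np.where(above)[0]
    i_hi = idx[-1]
    y0, y1 = y[i_hi], y[i_hi + 1]
    t = (half - y0) / (y1 - y0)
    x_half = x[i_hi] + t * (x[i_hi + 1] - x[i_hi])
    return 2.0 * float(x_half)


def lateral_fwhm(
    mode: str,
    cfg: OpticalConfig,
    model: str = "airy",
    wavelength: float | None = None,
) -> float:
    """Lateral FWHM (um) of the wide-field (h_eff) or focused (h_eff^2) PSF.

    ``model="airy"``: numerical FWHM of the Airy pattern (or its square).
    ``model="gaussian"``: Gaussian approximation with wide-field FWHM
    lambda/(2 NA); squaring a Gaussian divides the FWHM by exactly sqrt(2).
    """
    if mode not in ("wide", "focused"):
        raise ValueError("mode must be 'wide' or 'focused'")
    lam = cfg.wavelength_em if wavelength is None else wavelength
    na = cfg.na_det
    if model == "gaussian":
        fwhm_wide = lam / (2.0 * na)
        return fwhm_wide if mode == "wide" else fwhm_wide / np.sqrt(2.0)
    if model != "airy":
        raise ValueError(f"unknown model {model!r}")
    v = np.linspace(0.0, 4.0, 8001)
    y = airy_profile(v)
    if mode == "focused":
        y = y**2
    fwhm_v = _fwhm_from_profile(v, y)
    return fwhm_v * lam / (2.0 * np.pi * na)


#: relative broadening of the reconstruction-based wide-field methods.
#: SIM demodulation at frequency s0 restricts the usable object band to the
#: cutoff minus s0, widening the PSF by 2/(2 - s0); the HiLo fusion of a
#: high-passed wide-field image with a low-passed sectioned image costs a
#: small broadening of the net PSF.
_SIM_S0 = 1.0
_HILO_BROADENING = 1.1


def resolution_ranking(cfg: OpticalConfig, model: str = "airy"):
    """Methods ordered by effective lateral FWHM (um), best first.

    Focused modes (illumination x detection constraint) use h_eff^2; the
    line-scanning methods are focused across the line and wide along it, so
    their figure is the mean of the two FWHMs; two-photon is focused at the
    doubled excitation wavelength.
    """
    f_foc = lateral_fwhm("focused", cfg, model)
    f_wide = lateral_fwhm("wide", cfg, model)
    f_tp = lateral_fwhm("focused", cfg, model, wavelength=2.0 * cfg.wavelength_ex)
    table = {
        "confocal": f_foc,
        "spinning_disk": f_foc,
        "limo": 0.5 * (f_foc + f_wide),
        "line_confocal": 0.5 * (f_foc + f_wide),
        "light_sheet": f_wide,
        "hilo": f_wide * _HILO_BROADENING,
        "sim": f_wide * 2.0 / (2.0 - _SIM_S0),
        "two_photon": f_tp,
    }
    return sorted(table.items(), key=lambda kv: kv[1])
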
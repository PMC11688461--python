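"""Axial responses I(u) and FWHM sectioning strength per method.

Each optical-sectioning method maps to a frequency-domain integral over the
defocused OTF; the detected intensity from a thin fluorescent sheet at
normalized defocus ``u`` is

* confocal (pinhole): int_0^2 jinc(b s) T^2(s,u) jinc(beta s) s ds
* confocal (slit) / line confocal: int_0^2 sinc(b s) T^2(s,u) sinc(beta s) ds
* two-photon:        int_0^2 jinc(2 b s) T^2(s, u/2) s ds  (optional pinhole)
* structured:        |T(s0, u)|
* hybrid:            sqrt( int_{smin}^{smax} T^2(s,u) T(s,0) ds )
* light sheet:       exp(-u^2 / 2 c^2)
* LiMo:              int_0^2 sinc(b s) T^2(s,u) sinc(beta s) (1 - cos(2 beta s)) ds

with jinc(x) = 2 J1(x)/x and sinc(x) = sin(x)/x (both 1 at the origin).
Curves are normalized to I(0) = 1 and the FWHM is the sectioning-strength
figure of merit (smaller = stronger sectioning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.special import j1

from .config import MethodParams, OpticalConfig
from .pupil import OTFGrid, make_otf_grid, optical_coordinate

__all__ = [
    "jinc",
    "sinc",
    "AxialResponseCurve",
    "axial_response",
    "response_confocal",
    "response_two_photon",
    "response_modulated",
    "response_light_sheet",
    "response_limo",
    "fwhm_of_curve",
    "default_light_sheet_c",
    "reference_params",
    "sectioning_ranking",
]


def jinc(x):
    """2 J1(x) / x with jinc(0) = 1 (circular-aperture apodization)."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


def sinc(x):
    """sin(x) / x with sinc(0) = 1 (slit apodization)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


@dataclass(frozen=True)
class AxialResponseCurve:
    """Normalized axial response of one method with its FWHM."""

    method: str
    u_grid: np.ndarray
    intensity: np.ndarray
    fwhm: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"method": self.method, "u": self.u_grid, "I": self.intensity}
        )


def fwhm_of_curve(u: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation around the peak.

    The peak is taken at the grid maximum (u = 0 for all model curves); each
    half-maximum crossing is located by linear interpolation between the
    bracketing grid points.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(intensity, dtype=float)
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0

    def _cross(idx_range) -> float:
        prev = ipk
        for i in idx_range:
            if y[i] <= half:
                # interpolate between i and prev
                y0, y1 = y[prev], y[i]
                if y1 == y0:
                    return u[i]
                t = (half - y0) / (y1 - y0)
                return u[prev] + t * (u[i] - u[prev])
            prev = i
        raise ValueError(
            "axial response does not fall below half maximum inside the grid; "
            "enlarge the u range"
        )

    right = _cross(range(ipk + 1, len(y)))
    left = _cross(range(ipk - 1, -1, -1))
    return float(right - left)


def _normalize(method: str, u: np.ndarray, y: np.ndarray) -> AxialResponseCurve:
    y = np.asarray(y, dtype=float)
    peak = y[np.argmin(np.abs(u))]
    if peak <= 0:
        raise ValueError("axial response vanishes at focus; cannot normalize")
    y = y / peak
    return AxialResponseCurve(method=method, u_grid=u, intensity=y, fwhm=fwhm_of_curve(u, y))


def _grid_arrays(otf: OTFGrid):
    if len(otf.u_grid) == 0:
        raise ValueError("OTF grid has an empty u grid")
    return otf.s_grid, otf.u_grid, otf.values


def response_confocal(params: MethodParams, otf: OTFGrid) -> AxialResponseCurve:
    """Confocal axial response; pinhole (radial) or slit (1-D) branch."""
    if params.method not in ("confocal_pinhole", "confocal_slit", "line_confocal"):
        raise ValueError(f"not a confocal method: {params.method!r}")
    if params.beta <= 0:
        raise ValueError("beta must be > 0")
    s, u, T = _grid_arrays(otf)
    T2 = T**2
    if params.method == "confocal_pinhole":
        w = jinc(params.b * s) * jinc(params.beta * s) * s
    else:  # slit / line confocal: 1-D integral in s_x
        w = sinc(params.b * s) * sinc(params.beta * s)
    y = simpson(w[:, None] * T2, x=s, axis=0)
    return _normalize(params.method, u, y)


def response_two_photon(
    params: MethodParams,
    otf: OTFGrid,
    pinhole_beta: float | None = None,
    model: str = "intra_focal",
) -> AxialResponseCurve:
    """Two-photon axial response.

    ``model="intra_focal"``: integrand jinc(2 b s) T^2(s, u/2) s — both OTF
    factors at the doubled excitation wavelength (halved defocus argument,
    doubled spot argument).  ``model="comparison"``: integrand
    T(s/2, u/2) T(s, u) s — excitation at the doubled wavelength, detection
    at the native emission wavelength, the form used for the cross-method
    comparison.  An optional detection pinhole constrains the detection
    path: the integrand gains the factor T(s, u) jinc(beta s).
    """
    if params.method != "two_photon":
        raise ValueError(f"not two_photon: {params.method!r}")
    from .pupil import otf_defocused

    s, u, T = _grid_arrays(otf)
    if model == "intra_focal":
        core = otf_defocused(s[:, None], u[None, :] / 2.0) ** 2
    elif model == "comparison":
        core = otf_defocused(s[:, None] / 2.0, u[None, :] / 2.0) * T
    else:
        raise ValueError(f"unknown two-photon model {model!r}")
    w = jinc(2.0 * params.b * s) * s
    if pinhole_beta is not None:
        if pinhole_beta <= 0:
            raise ValueError("pinhole_beta must be > 0")
        core = core * T * jinc(pinhole_beta * s)[:, None]
    y = simpson(w[:, None] * core, x=s, axis=0)
    return _normalize(params.method, u, y)


def response_modulated(params: MethodParams, otf: OTFGrid) -> AxialResponseCurve:
    """Structured (single frequency) or hybrid (band) illumination response."""
    s, u, T = _grid_arrays(otf)
    if params.method == "structured":
        y = np.abs(otf.at(np.full_like(u, params.s0), u))
        return _normalize("structured", u, y)
    if params.method != "hybrid":
        raise ValueError(f"not a modulated method: {params.method!r}")
    if params.s_min >= params.s_max:
        raise ValueError(
            "hybrid requires s_min < s_max; use method='structured' for a "
            "single-frequency band"
        )
    mask = (s >= params.s_min) & (s <= params.s_max)
    if mask.sum() < 3:
        raise ValueError("hybrid band too narrow for the OTF grid")
    sb = s[mask]
    integrand = T[mask] ** 2 * otf_in_focus_col(sb)[:, None]
    y = np.sqrt(np.clip(simpson(integrand, x=sb, axis=0), 0.0, None))
    return _normalize("hybrid", u, y)


def otf_in_focus_col(s):
    from .pupil import otf_in_focus

    return np.asarray(otf_in_focus(s))


def response_light_sheet(params: MethodParams, otf: OTFGrid) -> AxialResponseCurve:
    """Gaussian light-sheet response exp(-u^2/2c^2); FWHM = 2 c sqrt(2 ln 2)."""
    if params.method != "light_sheet":
        raise ValueError(f"not light_sheet: {params.method!r}")
    if params.c <= 0:
        raise ValueError("c must be > 0")
    _, u, _ = _grid_arrays(otf)
    y = np.exp(-(u**2) / (2.0 * params.c**2))
    return _normalize("light_sheet", u, y)


def response_limo(params: MethodParams, otf: OTFGrid) -> AxialResponseCurve:
    """LiMo axial response: slit integrand weighted by (1 - cos(2 beta s)).

    The weight suppresses the slowly decaying low frequencies, which is what
    gives the linear decoding its stronger sectioning than a plain slit.
    """
    if params.method != "limo":
        raise ValueError(f"not limo: {params.method!r}")
    if params.beta <= 0:
        raise ValueError("beta must be > 0")
    s, u, T = _grid_arrays(otf)
    w = sinc(params.b * s) * sinc(params.beta * s) * (1.0 - np.cos(2.0 * params.beta * s))
    y = simpson(w[:, None] * T**2, x=s, axis=0)
    return _normalize("limo", u, y)


def response_widefield(otf: OTFGrid) -> AxialResponseCurve:
    """Wide-field: no sectioning; the sheet response is constant in u."""
    _, u, _ = _grid_arrays(otf)
    y = np.ones_like(u)
    return AxialResponseCurve(method="widefield", u_grid=u, intensity=y, fwhm=np.inf)


def axial_response(params: MethodParams, otf: OTFGrid | None = None) -> AxialResponseCurve:
    """Dispatch to the method-specific response."""
    if otf is None:
        otf = make_otf_grid()
    m = params.method
    if m in ("confocal_pinhole", "confocal_slit", "line_confocal"):
        return response_confocal(params, otf)
    if m == "two_photon":
        return response_two_photon(params, otf)
    if m in ("structured", "hybrid"):
        return response_modulated(params, otf)
    if m == "light_sheet":
        return response_light_sheet(params, otf)
    if m == "limo":
        return response_limo(params, otf)
    if m == "widefield":
        return response_widefield(otf)
    raise ValueError(f"unknown method {m!r}")


def default_light_sheet_c(cfg: OpticalConfig) -> float:
    """Light-sheet thickness parameter from the illumination NA.

    The sheet waist stays within the Rayleigh range z_R = n lambda / (pi NA_ill^2);
    c is z_R expressed in detection-arm normalized defocus units.
    """
    z_r = cfg.refractive_index * cfg.wavelength_ex / (np.pi * cfg.na_ill**2)
    return float(optical_coordinate(z_r, cfg, arm="detection"))


def reference_params(cfg: OpticalConfig) -> dict[str, MethodParams]:
    """Reference parameter set for cross-method comparison.

    Ideal illumination (b = 0), beta = 0.5 (one back-projected camera-pixel
    half-width), s0 = 1 (the optimum modulation frequency, half the cutoff),
    HiLo band [1, 2] (s_max pinned at the cutoff), light-sheet c from the
    illumination NA.
    """
    c = default_light_sheet_c(cfg)
    return {
        "light_sheet": MethodParams(method="light_sheet", c=c),
        "limo": MethodParams(method="limo", b=0.0, beta=0.5),
        "confocal": MethodParams(method="confocal_pinhole", b=0.0, beta=0.5),
        "structured": MethodParams(method="structured", s0=1.0),
        "hybrid": MethodParams(method="hybrid", s_min=1.0, s_max=2.0),
        "two_photon": MethodParams(method="two_photon", b=0.0),
        "line_confocal": MethodParams(method="line_confocal", b=0.0, beta=0.5),
    }


def sectioning_ranking(
    cfg: OpticalConfig,
    params_set: dict[str, MethodParams] | None = None,
    otf: OTFGrid | None = None,
) -> list[tuple[str, float]]:
    """Rank methods by axial-response FWHM (ascending = strongest first)."""
    if params_set is None:
        params_set = reference_params(cfg)
    if not params_set:
        raise ValueError("params_set must contain at least one method")
    if otf is None:
        otf = make_otf_grid()
    out = []
    for label, params in params_set.items():
        if params.method == "two_photon":
            # the cross-method comparison keeps detection at the native
            # emission wavelength (unconstrained), excitation at 2x lambda
            curve = response_two_photon(params, otf, model="comparison")
        else:
            curve = axial_response(params, otf)
        out.append((label, curve.fwhm))
    out.sort(key=lambda kv: kv[1])
    return out
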
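"""Performance calculators: imaging time, SNR, penetration depth,
phototoxicity, and the associated cross-method rankings.

Timing models
-------------
Mosaic (stop-and-stare tiling) over an L x L sample with field of view M,
per-field exposure t_m and stage acceleration a:

    T_m = (t_m + sqrt(4 M / a)) L^2 / M^2 - sqrt(4 M / a)

Strip (continuous line-scan) with per-line exposure t_s and sampling size p:

    T_s = L^2 t_s / (p M) + (L / M - 1) sqrt(4 M / a)

For samples smaller than one field the stage never moves and the time is
scan-limited: T = (t_m / M^2) L^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimingParams",
    "SNRInputs",
    "DepthParams",
    "mosaic_time",
    "strip_time",
    "small_area_time",
    "mosaic_quadratic_coefficient",
    "mosaic_constant",
    "small_area_coefficient",
    "point_scan_exposure",
    "snr",
    "snr_ranking",
    "penetration_power",
    "phototoxicity",
    "scanning_invariance",
    "REFERENCE_MODULATION",
]


@dataclass(frozen=True)
class TimingParams:
    """Scan-timing inputs; lengths in mm, times in s."""

    M: float = 0.67          # field-of-view side length
    a: float = 200.0         # stage acceleration (mm/s^2)
    t_m: float = 0.533       # per-field exposure
    t_s: float = 0.4e-6      # per-line exposure
    p: float = 0.325e-3      # sampling size
    L: float = 10.0          # sample side length

    def __post_init__(self) -> None:
        for name in ("M", "a", "t_m", "t_s", "p", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def point_scan_exposure(
    pixels: int = 2048, scan_pixels: int = 512, scan_fps: float = 30.0
) -> float:
    """Per-field exposure of a point scanner covering ``pixels``^2 at a
    mirror rate of ``scan_pixels``^2 per 1/fps: t_m = pixels^2 / (scan^2 fps)."""
    return pixels**2 / (scan_pixels**2 * scan_fps)


def mosaic_time(params: TimingParams) -> float:
    """Total mosaic-scan time; requires L >= M (use small_area_time below M)."""
    if params.L < params.M:
        return small_area_time(params.t_m, params.M, params.L)
    settle = np.sqrt(4.0 * params.M / params.a)
    return (params.t_m + settle) * params.L**2 / params.M**2 - settle


def strip_time(params: TimingParams) -> float:
    """Total strip-scan (continuous line-scan) time; requires L >= M."""
    if params.L < params.M:
        return params.L**2 * params.t_s / (params.p * params.M)
    settle = np.sqrt(4.0 * params.M / params.a)
    return params.L**2 * params.t_s / (params.p * params.M) + (
        params.L / params.M - 1.0
    ) * settle


def small_area_time(t_m: float, M: float, L: float) -> float:
    """Scan-limited time for samples within one field: (t_m / M^2) L^2."""
    if L > M:
        raise ValueError("small-area model applies for L <= M")
    return t_m / M**2 * L**2


def mosaic_quadratic_coefficient(t_m: float, M: float, a: float) -> float:
    """Quadratic coefficient (s/mm^2) of the mosaic timing law:
    (t_m + sqrt(4M/a)) / M^2."""
    return (t_m + np.sqrt(4.0 * M / a)) / M**2


def mosaic_constant(M: float, a: float) -> float:
    """Constant term (s) of the mosaic timing law: -sqrt(4M/a)."""
    return -np.sqrt(4.0 * M / a)


def small_area_coefficient(t_m: float, M: float) -> float:
    """Quadratic coefficient (s/mm^2) of the small-area law: t_m / M^2."""
    return t_m / M**2


# ---------------------------------------------------------------------------
# SNR

#: reference per-line modulation profile m(i), i = 1..6: the relative
#: in-focus response of the six off-axis lines (symmetric, centre-dominated)
REFERENCE_MODULATION = np.array([0.3, 0.6, 1.0, 1.0, 0.6, 0.3])


@dataclass(frozen=True)
class SNRInputs:
    """Signal statistics and geometry entering the SNR branches.

    ``S``/``S0``: pinhole (or slit) area relative to the illumination-spot
    area; ``m``: per-line modulation profile; ``k``: SIM normalization.
    """

    f: float = 1.0
    var_f: float = 1.0
    S: float = 0.098
    S0: float = 1.0
    m: np.ndarray = None
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.var_f < 0:
            raise ValueError("var_f must be >= 0")
        if self.S > self.S0:
            raise ValueError("pinhole area S cannot exceed the spot area S0")
        if self.m is None:
            object.__setattr__(self, "m", REFERENCE_MODULATION.copy())
        m = np.asarray(self.m, dtype=float)
        if np.any(m < 0):
            raise ValueError("modulation values must be >= 0")
        object.__setattr__(self, "m", m)


SNR_METHODS = (
    "confocal",
    "line_confocal",
    "two_photon",
    "light_sheet",
    "limo",
    "sim",
    "hilo",
)


def snr(method: str, inputs: SNRInputs) -> float:
    """Evaluate the per-method SNR branch.

    confocal / line confocal: sqrt(S) f / sqrt(S0 var f)
    two-photon / light sheet: f / sqrt(var f)
    LiMo: sqrt(C_LiMo) f / sqrt(var f),
          C_LiMo = 2 (m3 + m4) - (m1 + m2 + m5 + m6)
    SIM:  C_SIM sqrt(3) f / (2 sqrt(var f)),  C_SIM = (m3 + m4 - m1 - m6)/k
    HiLo: f / sqrt(C_HiLo var f),  C_HiLo = (std(m)/sqrt(2)) / mean(m)
    """
    if method not in SNR_METHODS:
        raise ValueError(f"unknown SNR method {method!r}; one of {SNR_METHODS}")
    if inputs.var_f == 0:
        raise ValueError("var_f must be > 0: the SNR ratio is undefined")
    f = inputs.f
    sig = np.sqrt(inputs.var_f)
    m = inputs.m
    if method in ("confocal", "line_confocal"):
        return float(np.sqrt(inputs.S) * f / (np.sqrt(inputs.S0) * sig))
    if method in ("two_photon", "light_sheet"):
        return float(f / sig)
    if method == "limo":
        c = 2.0 * (m[2] + m[3]) - (m[0] + m[1] + m[4] + m[5])
        if c < 0:
            raise ValueError("LiMo coefficient negative: modulation profile "
                             "must be centre-dominated")
        return float(np.sqrt(c) * f / sig)
    if method == "sim":
        c = (m[2] + m[3] - m[0] - m[5]) / inputs.k
        return float(c * np.sqrt(3.0) * f / (2.0 * sig))
    # hilo
    c = (np.std(m) / np.sqrt(2.0)) / np.mean(m)
    return float(f / (np.sqrt(c) * sig))


def snr_ranking(inputs: SNRInputs | None = None, slit_area: float = 0.31):
    """Methods ordered by SNR (descending) under a shared modulation profile.

    The line-confocal slit constrains one dimension only, so its area ratio
    ``slit_area`` is the 1-D width ratio rather than the 2-D pinhole ratio.
    """
    inputs = inputs or SNRInputs()
    out = []
    for method in SNR_METHODS:
        if method == "line_confocal":
            inp = SNRInputs(f=inputs.f, var_f=inputs.var_f, S=slit_area,
                            S0=inputs.S0, m=inputs.m, k=inputs.k)
        else:
            inp = inputs
        out.append((method, snr(method, inp)))
    out.sort(key=lambda kv: -kv[1])
    return out


# ---------------------------------------------------------------------------
# penetration depth and phototoxicity


@dataclass(frozen=True)
class DepthParams:
    P0: float = 1.0      # surface power (mW)
    z: float = 0.0       # depth (um)
    ls: float = 200.0    # scattering length (um)

    def __post_init__(self) -> None:
        if self.P0 <= 0 or self.ls <= 0:
            raise ValueError("P0 and ls must be strictly positive")
        if self.z < 0:
            raise ValueError("depth z must be >= 0")


def penetration_power(params: DepthParams, order: str = "linear") -> float:
    """Available power at depth z: P0 e^{-z/ls} (linear) or the relative
    nonlinear effective power e^{-2z/ls} (two-photon signal scales with
    intensity squared)."""
    if order == "linear":
        return float(params.P0 * np.exp(-params.z / params.ls))
    if order == "nonlinear":
        return float(np.exp(-2.0 * params.z / params.ls))
    raise ValueError("order must be 'linear' or 'nonlinear'")


def phototoxicity(P: float, t: float, S_area: float) -> float:
    """Light dose G = P t / S_area (power x exposure / illuminated area)."""
    if S_area <= 0:
        raise ValueError("S_area must be > 0")
    return P * t / S_area


def scanning_invariance(P: float, t: float, S_area: float, defocus_factor: float) -> bool:
    """In scanning microscopy both the illuminated area and the dwell time
    grow by the same factor with defocus, leaving the dose G unchanged."""
    g0 = phototoxicity(P, t, S_area)
    g1 = phototoxicity(P, t * defocus_factor, S_area * defocus_factor)
    return bool(np.isclose(g0, g1))
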
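"""Reconstructions on off-axis line-image stacks, and the SBR metric.

Four decodings of the rearranged per-off-axis images I_1..I_6 (lines 3 and 4
are the two most in-focus lines of the default 6-line layout):

* LC (line confocal):  I_3, the virtual-slit image.
* DSIM (digital structured illumination): three phase images assembled from
  line pairs and combined as the modulus of the complex three-phase sum;
  simplified form sqrt(5) |I_3 - I_1|.
* DHiLo (digital hybrid illumination): high-pass of I_3 fused with a
  contrast-weighted low-pass; simplified form I_3 - gamma LP(I_3).
* LiMo (line-illumination modulation): 2 (I_3 + I_4) - (I_1 + I_2 + I_5 + I_6),
  a linear combination that cancels the defocused background, which is
  nearly uniform across the off-axis lines.

Background cancellation: if every line carries the same image (pure
defocused input), DSIM and LiMo return exactly zero and DHiLo returns
(1 - gamma) I_3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ReconParams
from .simulate import RawOffAxisStack

__all__ = [
    "ReconResult",
    "recon_lc",
    "recon_dsim",
    "recon_dhilo",
    "recon_limo",
    "reconstruct",
    "sbr",
]

log = logging.getLogger(__name__)

_SBR_EPS = 1e-12


@dataclass
class ReconResult:
    """Reconstructed image with method label and parameters."""

    image: np.ndarray
    method: str
    params: ReconParams
    raw: np.ndarray | None = None    # pre-clip image, for linearity checks
    meta: dict = field(default_factory=dict)


def _require_lines(stack: RawOffAxisStack, needed: int) -> None:
    if stack.n_lines < needed:
        raise ValueError(
            f"reconstruction needs at least {needed} lines; stack has {stack.n_lines}"
        )


def _finish(image: np.ndarray, method: str, params: ReconParams) -> ReconResult:
    clipped = np.clip(image, 0.0, None)
    return ReconResult(image=clipped, method=method, params=params, raw=image)


def recon_lc(stack: RawOffAxisStack, params: ReconParams | None = None) -> ReconResult:
    """Virtual-slit line-confocal image: line 3 unchanged."""
    _require_lines(stack, 3)
    params = params or ReconParams(method="lc")
    return _finish(stack.line(3).copy(), "lc", params)


def _default_phase_masks(n_lines: int) -> np.ndarray:
    """Assign lines to 3 phases pairing lines half a period (3 lines) apart:
    (1,4), (2,5), (3,6).  Returns the (3, n_lines) mask matrix M_i(n)."""
    if n_lines < 6:
        raise ValueError("the three-phase mask form needs at least 6 lines")
    masks = np.zeros((3, n_lines))
    for i in range(3):
        masks[i, i] = 1.0
        masks[i, i + 3] = 1.0
    return masks


def recon_dsim(stack: RawOffAxisStack, params: ReconParams | None = None) -> ReconResult:
    """Digital SIM decoding.

    Simplified (default): sqrt(5) |I_3 - I_1|.  General: modulus of the
    three-phase complex sum of the mask-assembled phase images, scaled by
    1/k; with the default pairing masks this reduces to
    |I_1 + I_4 - (I_2 + I_5)/2 - (I_3 + I_6)/2| * sqrt(3)/... evaluated
    numerically — both forms vanish on modulation-free input.
    """
    params = params or ReconParams(method="dsim")
    if params.dsim_general:
        _require_lines(stack, 6)
        masks = _default_phase_masks(stack.n_lines)
        phases = np.tensordot(masks, stack.images, axes=(1, 0))
        phasors = np.exp(2j * np.pi * np.arange(1, 4) / 3.0)
        image = np.abs(np.tensordot(phasors, phases, axes=(0, 0))) / params.k
    else:
        _require_lines(stack, 3)
        image = np.sqrt(5.0 * (stack.line(3) - stack.line(1)) ** 2)
    return _finish(image, "dsim", params)


def _lowpass(image: np.ndarray, cutoff: float, pixel: float) -> np.ndarray:
    """Gaussian low-pass with frequency-domain std ``cutoff`` (cycles/um)."""
    nyquist = 0.5 / pixel
    if cutoff > nyquist:
        raise ValueError(
            f"filter cutoff {cutoff} cycles/um exceeds the Nyquist frequency "
            f"{nyquist} cycles/um of the {pixel} um grid"
        )
    sigma_px = 1.0 / (2.0 * np.pi * cutoff * pixel)
    return ndimage.gaussian_filter(image, sigma_px)


def recon_dhilo(
    stack: RawOffAxisStack,
    params: ReconParams | None = None,
    pixel: float | None = None,
    general: bool = False,
) -> ReconResult:
    """Digital HiLo decoding.

    Simplified (default): I_3 - gamma LP(I_3).  The general path fuses
    HP{I_3} with eta LP{C_s I_3}, where the local contrast C_s between the
    most- and least-modulated lines, (I_3 - I_1)/(I_3 + I_1) smoothed,
    weights the low-pass (sectioned) component.
    """
    _require_lines(stack, 3)
    params = params or ReconParams(method="dhilo")
    px = pixel if pixel is not None else stack.scan.pitch
    cutoff = params.filter_cutoff or 1.0 / (4.0 * px)
    i3 = stack.line(3)
    lp = _lowpass(i3, cutoff, px)
    if general:
        i1 = stack.line(1)
        denom = i3 + i1
        cs = np.where(denom > 0, (i3 - i1) / np.where(denom > 0, denom, 1.0), 0.0)
        cs = ndimage.gaussian_filter(cs, 2.0)
        image = (i3 - lp) + params.eta * _lowpass(cs * i3, cutoff, px)
    else:
        image = i3 - params.gamma * lp
    return _finish(image, "dhilo", params)


def recon_limo(stack: RawOffAxisStack, params: ReconParams | None = None) -> ReconResult:
    """LiMo linear decoding: 2 (I_3 + I_4) - (I_1 + I_2 + I_5 + I_6)."""
    _require_lines(stack, 6)
    params = params or ReconParams(method="limo")
    image = 2.0 * (stack.line(3) + stack.line(4)) - (
        stack.line(1) + stack.line(2) + stack.line(5) + stack.line(6)
    )
    return _finish(image, "limo", params)


_RECONSTRUCTORS = {
    "lc": recon_lc,
    "dsim": recon_dsim,
    "dhilo": recon_dhilo,
    "limo": recon_limo,
}


def reconstruct(stack: RawOffAxisStack, params: ReconParams) -> ReconResult:
    """Dispatch by ``params.method``."""
    try:
        fn = _RECONSTRUCTORS[params.method]
    except KeyError:
        raise ValueError(f"unknown reconstruction {params.method!r}") from None
    return fn(stack, params)


def sbr(image: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Signal-to-background ratio: mean over structure / mean over background."""
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("signal and background masks must be non-empty")
    if np.any(signal_mask & background_mask):
        raise ValueError("signal and background masks must be disjoint")
    sig = float(np.mean(image[signal_mask]))
    bg = float(np.mean(image[background_mask]))
    if bg < _SBR_EPS:
        log.info("background mean %.3g floored at %.0e for the SBR ratio", bg, _SBR_EPS)
        bg = _SBR_EPS
    return sig / bg
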
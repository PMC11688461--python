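"""Deep-background tail integrals B(u1) = int_{u1}^inf I(u) du.

The deep-background contribution of each sectioning method is the integral
of its paraxial axial response from a defocus bound ``u1`` outward.  With
the paraxial defocused kernel ``[2 J1(u s)/(u s)]^2`` the per-method
integrands reduce, via the substitution ``xi = u s``, to cumulative
integrals of Bessel moments:

=================  ===========================================  ==============
method             integrand (inner integral over s in [0, 2])  tail order
=================  ===========================================  ==============
natural (LiMo)     [J1(us)/us]^2 s^2 ds      = G2(2u)/u^3       O(ln u1/u1^2)
confocal           [J1(us)/us]^2 s ds        = G1(2u)/u^2       O(1/u1)
two-photon         [J1(us/2)/(us/2)]^2 s ds  = 4 G1(u)/u^2      O(1/u1)
structured         |2 J1(u s0)/(u s0)|                          O(1/sqrt(u1))
light sheet        exp(-u^2/2c^2)                               O(exp(-u1^2/2))
line confocal      [J1(us)/us]^2 ds          = G1(2u)/(4u) *    divergent (log)
=================  ===========================================  ==============

where G1(x) = int_0^x J1^2/xi dxi (-> 1/2) and G2(x) = int_0^x J1^2 dxi
(~ ln x / pi).  The line-confocal integral grows without bound: its growth
is reported as a profile over truncation bounds, never as a number.

The structured branch uses the first power of the jinc (the demodulated
single-frequency response is |T(s0, u)|), which is what produces the
O(1/sqrt(u1)) tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.special import erfc, j1

__all__ = [
    "TAIL_METHODS",
    "TailResult",
    "tail_integral",
    "tail_integral_quad",
    "divergence_check",
    "order_fit",
    "tail_ranking",
]

TAIL_METHODS = (
    "natural",
    "confocal",
    "two_photon",
    "structured",
    "light_sheet",
    "line_confocal",
)

#: alias: the natural-modulation branch is the LiMo decoding
_ALIASES = {"limo": "natural", "lc": "line_confocal"}

_DEFAULT_UPPER = 1.0e4


@dataclass(frozen=True)
class TailResult:
    method: str
    u1: float
    upper: float
    value: float


def _canon(method: str) -> str:
    m = _ALIASES.get(method, method)
    if m not in TAIL_METHODS:
        raise ValueError(f"unknown tail method {method!r}; one of {TAIL_METHODS}")
    return m


class _BesselMoments:
    """Cached cumulative Bessel moments G1, G2 on a fine xi grid."""

    def __init__(self, xi_max: float, step: float = 0.02):
        n = int(np.ceil(xi_max / step)) + 1
        xi = np.linspace(0.0, xi_max, n)
        j2 = j1(xi) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            j2_over_xi = np.where(xi > 0, j2 / xi, 0.0)
        self.xi = xi
        self.g1 = cumulative_trapezoid(j2_over_xi, xi, initial=0.0)
        self.g2 = cumulative_trapezoid(j2, xi, initial=0.0)

    def G1(self, x):
        return np.interp(x, self.xi, self.g1)

    def G2(self, x):
        return np.interp(x, self.xi, self.g2)


_moments_cache: dict[float, _BesselMoments] = {}


def _moments(xi_max: float) -> _BesselMoments:
    # round the requested range up to the next power of 10 so one cached
    # table serves every evaluation point of an adaptive quadrature
    key = 10.0 ** np.ceil(np.log10(max(xi_max, 10.0)))
    have = max(_moments_cache, default=0.0)
    if have >= key:
        return _moments_cache[have]
    _moments_cache.clear()
    _moments_cache[key] = _BesselMoments(key)
    return _moments_cache[key]


def _integrand(method: str, u: np.ndarray, c: float, s0: float) -> np.ndarray:
    """Paraxial axial-response integrand I(u) for the tail integral."""
    u = np.asarray(u, dtype=float)
    mom = _moments(2.0 * float(np.max(u)) + 1.0)
    if method == "natural":
        return mom.G2(2.0 * u) / u**3
    if method == "confocal":
        return mom.G1(2.0 * u) / u**2
    if method == "two_photon":
        return 4.0 * mom.G1(u) / u**2
    if method == "structured":
        x = u * s0
        return np.abs(2.0 * j1(x) / x)
    if method == "light_sheet":
        return np.exp(-(u**2) / (2.0 * c**2))
    if method == "line_confocal":
        return mom.G1(2.0 * u) / u
    raise ValueError(method)


def tail_integral(
    method: str,
    u1: float,
    upper: float = _DEFAULT_UPPER,
    c: float = 1.0,
    s0: float = 1.0,
    n_per_decade: int = 2000,
) -> TailResult:
    """Fixed-grid (log-spaced trapezoid) tail integral from u1 to upper.

    Deterministic given the grid settings.  For the divergent line-confocal
    branch this returns the truncated value at ``upper`` — use
    :func:`divergence_check` to characterize the growth.
    """
    method = _canon(method)
    if u1 <= 0:
        raise ValueError("u1 must be > 0")
    if upper < u1:
        raise ValueError("upper must be >= u1")
    if upper == u1:
        return TailResult(method=method, u1=u1, upper=upper, value=0.0)
    if method == "light_sheet":
        # analytic Gaussian tail; the numeric grid would waste points at
        # large u where the integrand is identically ~0
        val = c * np.sqrt(np.pi / 2.0) * (
            erfc(u1 / (c * np.sqrt(2.0))) - erfc(upper / (c * np.sqrt(2.0)))
        )
        return TailResult(method=method, u1=u1, upper=upper, value=float(val))
    # geometric spacing resolves the power-law region; beyond u ~ 50 the
    # Bessel oscillation (period 2 pi in u) forces a bounded linear step
    knee = min(50.0, upper)
    parts = []
    if u1 < knee:
        decades = np.log10(knee / u1)
        n = max(int(np.ceil(decades * n_per_decade)), 64)
        parts.append(np.geomspace(u1, knee, n))
    if knee < upper:
        step = np.pi / 12.0
        parts.append(np.arange(max(knee, u1), upper + step, step))
    u = np.unique(np.concatenate(parts))
    u = u[(u >= u1) & (u <= upper)]
    y = _integrand(method, u, c, s0)
    val = float(np.trapezoid(y, u))
    return TailResult(method=method, u1=u1, upper=upper, value=val)


def tail_integral_quad(
    method: str,
    u1: float,
    upper: float = _DEFAULT_UPPER,
    c: float = 1.0,
    s0: float = 1.0,
) -> TailResult:
    """Adaptive-quadrature cross-check of :func:`tail_integral`."""
    method = _canon(method)
    if u1 <= 0:
        raise ValueError("u1 must be > 0")
    _moments(2.0 * upper + 1.0)  # warm the cache before quad calls

    def f(u):
        return _integrand(method, np.asarray([u]), c, s0)[0]

    total = 0.0
    lo = u1
    if method == "structured":
        # |J1| oscillates with period ~2 pi/s0: integrate half-period blocks
        block = np.pi / s0
        edges = np.arange(u1, upper + block, block)
        edges[-1] = upper
        for a, b in zip(edges[:-1], edges[1:]):
            if b <= a:
                continue
            val, _ = quad(f, a, b, limit=60)
            total += val
        return TailResult(method=method, u1=u1, upper=upper, value=total)
    # integrate decade by decade so quad sees smooth, bounded pieces
    while lo < upper:
        hi = min(lo * 10.0, upper)
        val, _ = quad(f, lo, hi, limit=400)
        total += val
        lo = hi
    return TailResult(method=method, u1=u1, upper=upper, value=total)


def divergence_check(
    method: str,
    u1: float,
    uppers,
    c: float = 1.0,
    s0: float = 1.0,
) -> list[TailResult]:
    """Growth profile B(u1, U) over increasing truncation bounds U.

    For the line-confocal branch the sequence grows without bound with
    near-constant increments per decade of U (logarithmic divergence); for
    convergent branches it saturates.
    """
    uppers = list(uppers)
    if any(b >= a for b, a in zip(uppers, uppers[1:])):
        raise ValueError("uppers must be strictly increasing")
    return [tail_integral(method, u1, upper=U, c=c, s0=s0) for U in uppers]


def order_fit(
    method: str,
    u1_sweep,
    upper: float = _DEFAULT_UPPER,
    c: float = 1.0,
    s0: float = 1.0,
) -> float:
    """Empirical decay exponent: log-log slope of B(u1) over the sweep."""
    u1_sweep = np.asarray(list(u1_sweep), dtype=float)
    if u1_sweep.max() / u1_sweep.min() < 10.0:
        raise ValueError("u1 sweep must cover at least one decade")
    b = np.array(
        [tail_integral(method, u1, upper=upper, c=c, s0=s0).value for u1 in u1_sweep]
    )
    keep = b > 0
    if keep.sum() < 3:
        raise ValueError(
            f"tail of {method!r} underflows over this sweep; use smaller u1 values"
        )
    slope = np.polyfit(np.log(u1_sweep[keep]), np.log(b[keep]), 1)[0]
    return float(slope)


def tail_ranking(
    u1: float = 2.0,
    upper: float = _DEFAULT_UPPER,
    c: float = 1.0,
    s0: float = 1.0,
    include_divergent: bool = True,
):
    """Methods ordered by deep-background contribution B(u1), smallest first.

    The divergent line-confocal branch is evaluated at the common truncation
    bound so it can be placed relative to the power-law methods.
    """
    methods = list(TAIL_METHODS) if include_divergent else [
        m for m in TAIL_METHODS if m != "line_confocal"
    ]
    vals = [(m, tail_integral(m, u1, upper=upper, c=c, s0=s0).value) for m in methods]
    vals.sort(key=lambda kv: kv[1])
    return vals
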
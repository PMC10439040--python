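"""Defective first-passage time density, derivative, CDF and absorption
probability of the two-boundary Wiener diffusion model.

The model: a Wiener process with drift ``nu`` and unit diffusion coefficient
starts at ``z = a * w`` between absorbing boundaries 0 and ``a``.  The
*defective* density ``g_b(t)`` of the first-passage time at boundary ``b``
integrates to the absorption probability at ``b``, not to one.  The density
is evaluated through the scaled form

    g_lower(t) = a^-2 exp(-nu a w - nu^2 t / 2) f1(t / a^2; w)

with ``f1`` given either by the small-time image series

    f1(u; w) = (2 pi u^3)^(-1/2) sum_k (w + 2k) exp(-(w + 2k)^2 / (2u))

or the large-time spectral series

    f1(u; w) = pi sum_{k>=1} k exp(-k^2 pi^2 u / 2) sin(k pi w),

whichever needs fewer terms.  Upper-boundary quantities follow from the
reflection (nu, w) -> (-nu, 1 - w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as _k

__all__ = [
    "WDMParams",
    "fpt_density",
    "fpt_density_tderiv",
    "fpt_cdf",
    "absorption_probability",
]

_BOUNDARIES = ("lower", "upper")


@dataclass(frozen=True)
class WDMParams:
    """Core 4-parameter Wiener diffusion model (diffusion coefficient 1).

    a : boundary separation (> 0, evidence units)
    nu : drift rate (evidence units per second)
    w : relative starting point (0 < w < 1)
    t0 : non-decision time (seconds, >= 0)
    """

    a: float
    nu: float
    w: float
    t0: float = 0.0

    def __post_init__(self):
        for name in ("a", "nu", "w", "t0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v}")
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.w < 1:
            raise ValueError(f"relative start w must lie in (0, 1), got {self.w}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")

    @property
    def z(self) -> float:
        """Absolute starting point a * w."""
        return self.a * self.w


def _check_boundary(boundary: str) -> str:
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {boundary!r}")
    return boundary


def _check_eps(eps: float) -> float:
    if not (0 < eps <= 1e-3):
        raise ValueError(f"precision eps must lie in (0, 1e-3], got {eps}")
    return eps


def canonical(p: WDMParams, boundary: str) -> tuple[float, float, float]:
    """Map (params, boundary) to lower-boundary form (a, nu_c, w_c)."""
    _check_boundary(boundary)
    if boundary == "lower":
        return p.a, p.nu, p.w
    return p.a, -p.nu, 1.0 - p.w


def fpt_density(t, p: WDMParams, boundary: str = "lower", eps: float = 1e-12):
    """Defective first-passage density g_b(t) at decision time t (1/s).

    t <= 0 returns 0 by convention.  Scalar in, scalar out; array in,
    array out.
    """
    _check_eps(eps)
    a, nu, w = canonical(p, boundary)
    ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
    out = np.empty_like(ts)
    _k.dens_vec(ts, a, nu, w, out)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def fpt_density_tderiv(t, p: WDMParams, boundary: str = "lower",
                       eps: float = 1e-12):
    """Time derivative of the defective density (1/s^2)."""
    _check_eps(eps)
    a, nu, w = canonical(p, boundary)
    ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
    out = np.empty_like(ts)
    _k.deriv_vec(ts, a, nu, w, out)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def fpt_cdf(t, p: WDMParams, boundary: str = "lower", eps: float = 1e-12):
    """Defective CDF F_b(t): nondecreasing, F_b(0) = 0, limit equals the
    absorption probability at b.  Absolute error <= eps."""
    _check_eps(eps)
    a, nu, w = canonical(p, boundary)
    ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
    out = np.empty_like(ts)
    _k.cdf_vec(ts, a, nu, w, eps, out)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def absorption_probability(p: WDMParams, boundary: str = "lower") -> float:
    """Probability that the process is absorbed at the given boundary.

    P(upper) = (1 - exp(2 nu a w)) / (exp(-2 nu a (1-w)) - exp(2 nu a w)),
    evaluated in expm1 form (log-space branch for extreme drift); the
    drift-free limit returns w exactly.
    """
    _check_boundary(boundary)
    pu = _k._p_upper(p.a, p.nu, p.w)
    return float(pu) if boundary == "upper" else float(1.0 - pu)
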
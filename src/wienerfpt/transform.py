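"""Log-time change of variables A = (log T - alpha0) / s_alpha.

The boundary-conditional first-passage density of the diffusion model is not
log-concave in t, but (empirically, and provably for the single-boundary
inverse-Gaussian case) it is log-concave after this transform, which is what
makes adaptive rejection sampling applicable.  The transformed density is

    f_A(alpha) = s_alpha * exp(s_alpha alpha + alpha0)
                 * f_T(exp(s_alpha alpha + alpha0))

and the derivative of its logarithm is

    d/dalpha log f_A(alpha) = s_alpha * (f_T'(t)/f_T(t) * t + 1),
    t = exp(s_alpha alpha + alpha0).

The default (alpha0=0, s_alpha=1) is the pure log transform; any other
choice is an affine reparameterisation and leaves the back-transformed
distribution unchanged, affecting only numerical conditioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .wdm_core import WDMParams, canonical, _check_eps

__all__ = ["TransformSpec", "LogDensityPoint", "to_alpha", "from_alpha",
           "log_density_alpha"]


@dataclass(frozen=True)
class TransformSpec:
    """Location/scale of the log-time transform; s_alpha must be > 0."""

    alpha0: float = 0.0
    s_alpha: float = 1.0

    def __post_init__(self):
        if not (self.s_alpha > 0 and math.isfinite(self.s_alpha)):
            raise ValueError(f"s_alpha must be positive, got {self.s_alpha}")
        if not math.isfinite(self.alpha0):
            raise ValueError(f"alpha0 must be finite, got {self.alpha0}")


@dataclass(frozen=True)
class LogDensityPoint:
    """A point evaluation of the transformed log-density.

    h may be -inf where the density underflows; dh_defined is False there
    and the value of dh must not be used (hull construction skips such
    points).
    """

    alpha: float
    h: float
    dh: float
    dh_defined: bool = True


def to_alpha(t, spec: TransformSpec = TransformSpec()):
    """alpha = (log t - alpha0) / s_alpha; strictly increasing in t."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0 for the log transform")
    out = (np.log(t) - spec.alpha0) / spec.s_alpha
    return float(out) if out.ndim == 0 else out


def from_alpha(alpha, spec: TransformSpec = TransformSpec()):
    """t = exp(s_alpha * alpha + alpha0) > 0."""
    alpha = np.asarray(alpha, dtype=np.float64)
    ex = spec.s_alpha * alpha + spec.alpha0
    if np.any(ex > 709.0):
        raise OverflowError(
            f"from_alpha overflows: s_alpha*alpha+alpha0 reaches {np.max(ex)}")
    out = np.exp(ex)
    return float(out) if out.ndim == 0 else out


def log_density_alpha(alpha: float, p: WDMParams, boundary: str = "lower",
                      spec: TransformSpec = TransformSpec(),
                      eps: float = 1e-12) -> LogDensityPoint:
    """h(alpha) = log f_A(alpha) and its derivative for the ARS target.

    The density here is the *defective* boundary-conditional density; ARS is
    invariant to the missing normalising constant.
    """
    _check_eps(eps)
    a, nu, w = canonical(p, boundary)
    ex = spec.s_alpha * alpha + spec.alpha0
    if ex > 700.0 or ex < -700.0:
        return LogDensityPoint(alpha, -math.inf, math.nan, False)
    t = math.exp(ex)
    one = np.ones(1)
    h_arr = np.empty(1)
    dh_arr = np.empty(1)
    _k.h_dh_vec(np.array([math.log(t)]), a, np.array([nu]), np.array([w]),
                one, h_arr, dh_arr)
    if h_arr[0] < -1e307:
        return LogDensityPoint(alpha, -math.inf, math.nan, False)
    # rescale from the identity log transform to (alpha0, s_alpha)
    h = math.log(spec.s_alpha) + h_arr[0]
    dh = spec.s_alpha * dh_arr[0]
    return LogDensityPoint(alpha, h, dh, True)
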
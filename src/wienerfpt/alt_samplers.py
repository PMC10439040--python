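"""Inverse transform sampling and rejection sampling for the WDM.

ITS draws u ~ U(0, F_b(bound)) and inverts the defective CDF by bisection
(no analytic quantile function exists).  RS follows the Drugowitsch
construction: for w = 1/2, scaled decision time and boundary are
independent; the time is drawn by exact alternating-series rejection with a
truncated inverse-Gaussian / Levy proposal below a switch point in scaled
time and a shifted-exponential proposal above it.  Relative starting points
other than 1/2 reduce to a sequence of nested symmetric subproblems: from
position z the process first exits [z-d, z+d] with d = min(z, a-z) — a
symmetric two-boundary FPT — and by the strong Markov property accumulating
the stage times until z reaches 0 or a reproduces the original first
passage exactly.  Boundary-conditional draws resample until the requested
boundary is hit, with an ITS escape hatch when the conditional mass is
small (tight truncation or extreme drift).
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as _k
from .wdm_core import WDMParams, canonical, _check_eps

__all__ = ["TruncationSpec", "its_sample", "rs_sample", "its_quantile"]


class TruncationSpec:
    """Upper truncation (seconds) of the returned first-passage time."""

    def __init__(self, bound: float = math.inf):
        if not bound > 0:
            raise ValueError(f"truncation bound must be > 0, got {bound}")
        self.bound = float(bound)

    def __repr__(self):
        return f"TruncationSpec(bound={self.bound})"


def _as_bound(trunc) -> float:
    if trunc is None:
        return math.inf
    if isinstance(trunc, TruncationSpec):
        return trunc.bound
    return TruncationSpec(float(trunc)).bound


def _seed(rng: np.random.Generator | None) -> int:
    rng = np.random.default_rng() if rng is None else rng
    return int(rng.integers(0, 2 ** 31 - 1))


def its_quantile(u: float, p: WDMParams, boundary: str = "lower",
                 eps: float = 1e-12) -> float:
    """Solve F_b(t) = u for the decision time t (bisection, 1e-10 in t)."""
    a, nu, w = canonical(p, boundary)
    P = 1.0 - _k._p_upper(a, nu, w)
    if not 0 <= u <= P:
        raise ValueError(f"u={u} outside [0, P_b={P}]")
    return float(_k._its_quantile(u, a, nu, w, math.inf, eps))


def its_sample(p: WDMParams, boundary: str, n: int, trunc=None,
               eps: float = 1e-12, rng: np.random.Generator | None = None):
    """n boundary-conditional decision times by inverse transform sampling."""
    _check_eps(eps)
    bound = _as_bound(trunc)
    a, nu, w = canonical(p, boundary)
    mass = _k._cdf_lower(bound, a, nu, w, eps) if bound != math.inf \
        else 1.0 - _k._p_upper(a, nu, w)
    if mass <= 0.0:
        raise ValueError(
            f"no probability mass at boundary {boundary!r} below "
            f"bound={bound}")
    out = np.empty(n)
    st, _ = _k.sample_set(_k.ITS, n, a, nu, 0.0, w, 0.0,
                          np.array([nu]), np.array([w]), np.array([1.0]),
                          bound, eps, _seed(rng), out)
    if st not in (0, 5):
        raise RuntimeError(f"ITS sampling failed with status {st}")
    return out


def rs_sample(p: WDMParams, boundary: str, n: int, trunc=None,
              eps: float = 1e-12, rng: np.random.Generator | None = None):
    """n boundary-conditional decision times by rejection sampling."""
    _check_eps(eps)
    bound = _as_bound(trunc)
    a, nu, w = canonical(p, boundary)
    mass = _k._cdf_lower(bound, a, nu, w, eps) if bound != math.inf \
        else 1.0 - _k._p_upper(a, nu, w)
    if mass <= 0.0:
        raise ValueError(
            f"no probability mass at boundary {boundary!r} below "
            f"bound={bound}")
    out = np.empty(n)
    st, _ = _k.sample_set(_k.RS, n, a, nu, 0.0, w, 0.0,
                          np.array([nu]), np.array([w]), np.array([1.0]),
                          bound, eps, _seed(rng), out)
    if st not in (0, 5):
        raise RuntimeError(f"RS sampling failed with status {st}")
    return out
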
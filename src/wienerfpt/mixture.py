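"""Trial-to-trial parameter variability: two-step sampling, the boundary-
conditional parameter-rejection step, and the quadrature-mixed density/CDF.

Distributional assumptions: across trials the drift is normal,
nu ~ N(mu_nu, s_nu); the relative starting point is uniform,
w ~ U(mu_w - s_w/2, mu_w + s_w/2); the non-decision time is uniform,
t0 ~ U(min_t0, min_t0 + s_t0).  The marginal ("mixed") defective density is
the double integral of the core density over the drift (Gauss-Hermite) and
starting-point (Gauss-Legendre) laws.

Sampling conditional on one boundary needs a correction: parameters that
favour that boundary are overrepresented among trials absorbed there, so a
proposed parameter draw is accepted only with probability equal to its
absorption mass at the requested boundary — generalised here to the
*truncated* mass F_b(bound; theta) so that truncation and variability
compose exactly (with bound = inf this is the plain absorption
probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .alt_samplers import _as_bound, _seed
from .wdm_core import WDMParams, canonical, _check_eps

__all__ = ["VariabilityParams", "draw_trial_params",
           "conditional_param_accept", "mixed_density", "mixed_cdf",
           "sample_with_variability", "quadrature_nodes"]

_METHODS = {"ars": _k.ARS, "rs": _k.RS, "its": _k.ITS, "p-ars": _k.PARS}


@dataclass(frozen=True)
class VariabilityParams:
    """Trial-to-trial spreads around the mean parameters.

    mu_nu : mean drift; s_nu : drift SD (>= 0)
    mu_w : mean relative start (0 < mu_w < 1); s_w : start range (>= 0),
        with mu_w +/- s_w/2 inside (0, 1)
    min_t0 : minimal non-decision time (>= 0); s_t0 : its range (>= 0)
    """

    mu_nu: float
    mu_w: float
    s_nu: float = 0.0
    s_w: float = 0.0
    min_t0: float = 0.0
    s_t0: float = 0.0

    def __post_init__(self):
        if self.s_nu < 0 or self.s_w < 0 or self.s_t0 < 0:
            raise ValueError("variability spreads must be >= 0")
        if not 0 < self.mu_w < 1:
            raise ValueError(f"mu_w must lie in (0, 1), got {self.mu_w}")
        if self.mu_w - self.s_w / 2 <= 0 or self.mu_w + self.s_w / 2 >= 1:
            raise ValueError(
                f"starting-point range mu_w +/- s_w/2 = "
                f"[{self.mu_w - self.s_w / 2}, {self.mu_w + self.s_w / 2}] "
                "must lie inside (0, 1)")
        if self.min_t0 < 0:
            raise ValueError(f"min_t0 must be >= 0, got {self.min_t0}")


def draw_trial_params(a: float, vp: VariabilityParams,
                      rng: np.random.Generator) -> WDMParams:
    """One trial's parameters from the three variability laws (degenerate
    spreads return the means deterministically)."""
    nu = vp.mu_nu + vp.s_nu * rng.standard_normal() if vp.s_nu > 0 else vp.mu_nu
    w = vp.mu_w + vp.s_w * (rng.random() - 0.5) if vp.s_w > 0 else vp.mu_w
    t0 = vp.min_t0 + vp.s_t0 * rng.random() if vp.s_t0 > 0 else vp.min_t0
    return WDMParams(a=a, nu=nu, w=w, t0=t0)


def conditional_param_accept(p: WDMParams, boundary: str, u: float,
                             bound: float = math.inf,
                             eps: float = 1e-12) -> bool:
    """Accept trial parameters iff u <= (truncated) absorption mass at the
    requested boundary; corrects the boundary-conditional parameter law."""
    a, nu, w = canonical(p, boundary)
    if bound == math.inf:
        m = 1.0 - _k._p_upper(a, nu, w)
    else:
        m = _k._cdf_lower(bound, a, nu, w, eps)
    return u <= m


def quadrature_nodes(a: float, vp: VariabilityParams, boundary: str = "lower",
                     n_nu: int = 32, n_w: int = 32):
    """Flattened (nus, ws, wts) product nodes of the trial-parameter mixture,
    canonicalised to the lower boundary."""
    if vp.s_nu > 0:
        x, wgt = np.polynomial.hermite.hermgauss(n_nu)
        nu_nodes = vp.mu_nu + math.sqrt(2.0) * vp.s_nu * x
        nu_wts = wgt / math.sqrt(math.pi)
    else:
        nu_nodes = np.array([vp.mu_nu])
        nu_wts = np.array([1.0])
    if vp.s_w > 0:
        x, wgt = np.polynomial.legendre.leggauss(n_w)
        w_nodes = vp.mu_w + 0.5 * vp.s_w * x
        w_wts = wgt / 2.0
    else:
        w_nodes = np.array([vp.mu_w])
        w_wts = np.array([1.0])
    nus, ws = np.meshgrid(nu_nodes, w_nodes, indexing="ij")
    wts = np.outer(nu_wts, w_wts)
    nus, ws, wts = nus.ravel(), ws.ravel(), wts.ravel()
    if boundary == "upper":
        nus, ws = -nus, 1.0 - ws
    return np.ascontiguousarray(nus), np.ascontiguousarray(ws), \
        np.ascontiguousarray(wts)


def _refined(fun, t, a, vp, boundary, eps, n_nu, n_w):
    ts = np.atleast_1d(np.asarray(t, dtype=np.float64))
    out = np.empty_like(ts)
    nus, ws, wts = quadrature_nodes(a, vp, boundary, n_nu, n_w)
    fun(ts, a, nus, ws, wts, out)
    out2 = np.empty_like(ts)
    nus2, ws2, wts2 = quadrature_nodes(a, vp, boundary, 2 * n_nu, 2 * n_w)
    fun(ts, a, nus2, ws2, wts2, out2)
    if np.max(np.abs(out2 - out)) > eps:
        raise ArithmeticError(
            "quadrature not converged at the requested precision; "
            "increase n_nu/n_w")
    return out2[0] if np.ndim(t) == 0 else out2


def mixed_density(t, a: float, vp: VariabilityParams, boundary: str = "lower",
                  eps: float = 1e-12, n_nu: int = 32, n_w: int = 32):
    """Marginal defective density, integrated over the nu and w laws by
    Gauss-Hermite x Gauss-Legendre quadrature with an order-doubling
    convergence check.  Degenerate spreads collapse to the core density."""
    _check_eps(eps)
    return _refined(_k.dens_mix_vec, t, a, vp, boundary, eps, n_nu, n_w)


def mixed_cdf(t, a: float, vp: VariabilityParams, boundary: str = "lower",
              eps: float = 1e-12, n_nu: int = 32, n_w: int = 32):
    """Marginal defective CDF (same quadrature scheme as mixed_density)."""
    _check_eps(eps)

    def fun(ts, aa, nus, ws, wts, out):
        _k.cdf_mix_vec(ts, aa, nus, ws, wts, eps, out)

    return _refined(fun, t, a, vp, boundary, eps, n_nu, n_w)


def _draw_conditional(method: str, a, vp, boundary, n, bound, eps, seed,
                      n_nu, n_w):
    """n boundary-conditional decision times (no t0) at the given bound."""
    nus, ws, wts = quadrature_nodes(a, vp, boundary, n_nu, n_w)
    _, nu_c, w_c = canonical(WDMParams(a, vp.mu_nu, vp.mu_w), boundary)
    out = np.empty(n)
    st, mass = _k.sample_set(_METHODS[method], n, a, nu_c, vp.s_nu, w_c,
                             vp.s_w, nus, ws, wts, bound, eps, seed, out)
    if st == 4 or mass <= 0:
        raise ValueError(
            f"no probability mass at boundary {boundary!r} below {bound}")
    if st not in (0, 5):  # 5 = exact CDF-inversion fallback, still valid
        raise RuntimeError(f"sampling failed with status {st}")
    return out


def sample_with_variability(method: str, a: float, vp: VariabilityParams,
                            response: str = "both", n: int = 1,
                            trunc=None, eps: float = 1e-12,
                            rng: np.random.Generator | None = None,
                            n_nu: int = 32, n_w: int = 32):
    """Sample n (q, response) pairs from the WDM with trial variability.

    For ITS/RS/P-ARS the two-step scheme draws per-trial parameters (with
    the conditional-acceptance correction when a single response is
    requested) and then samples the FPT at those fixed parameters.  For ARS
    the hull is built once on the quadrature-mixed density and reused across
    draws.  q = decision time + t0 (+ U(0, s_t0)); the truncation bound
    applies to q.

    Returns (q, labels) as float and object arrays of length n.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    if response not in ("upper", "lower", "both"):
        raise ValueError("response must be 'upper', 'lower' or 'both'")
    _check_eps(eps)
    bound = _as_bound(trunc)
    rng = np.random.default_rng() if rng is None else rng
    if bound != math.inf and vp.min_t0 >= bound:
        raise ValueError(
            f"min_t0={vp.min_t0} >= bound={bound}: no admissible sample")

    q = np.empty(n)
    labels = np.empty(n, dtype=object)
    todo = np.arange(n)
    # per-trial decision-time bound is bound - t0; sample at the loosest
    # bound and restart trials whose total time lands beyond the truncation
    dec_bound = bound - vp.min_t0 if bound != math.inf else math.inf
    guard = 0
    while todo.size and guard < 200:
        m = todo.size
        t0s = (vp.min_t0 + vp.s_t0 * rng.random(m)) if vp.s_t0 > 0 \
            else np.full(m, vp.min_t0)
        if response == "both":
            dec, lab = _sample_both(method, a, vp, m, dec_bound, eps, rng,
                                    n_nu, n_w)
        else:
            dec = _draw_conditional(method, a, vp, response, m, dec_bound,
                                    eps, _seed(rng), n_nu, n_w)
            lab = np.full(m, response, dtype=object)
        qs = dec + t0s
        ok = qs <= bound
        q[todo[ok]] = qs[ok]
        labels[todo[ok]] = lab[ok]
        todo = todo[~ok]
        guard += 1
    if todo.size:
        raise RuntimeError("truncation bound leaves too little mass above "
                           "min_t0; could not complete the sample")
    return q, labels


def _sample_both(method: str, a, vp, n, dec_bound, eps, rng, n_nu, n_w):
    """Unconditional sampling: boundary per trial, then the conditional FPT."""
    if method == "ars":
        # mixed-density route: boundary from the marginal (truncated) masses,
        # times from the two per-boundary hulls
        masses = {}
        for b in ("upper", "lower"):
            nus, ws, wts = quadrature_nodes(a, vp, b, n_nu, n_w)
            masses[b] = _k._mass_mix(a, nus, ws, wts, dec_bound, eps)
        p_up = masses["upper"] / (masses["upper"] + masses["lower"])
        n_up = int(rng.binomial(n, p_up))
        dec = np.empty(n)
        lab = np.empty(n, dtype=object)
        order = rng.permutation(n)
        for b, cnt, sl in (("upper", n_up, order[:n_up]),
                           ("lower", n - n_up, order[n_up:])):
            if cnt:
                dec[sl] = _draw_conditional("ars", a, vp, b, cnt, dec_bound,
                                            eps, _seed(rng), n_nu, n_w)
                lab[sl] = b
        return dec, lab
    # two-step: trial parameters, boundary from the absorption probability
    # at those parameters, then the conditional FPT at fixed parameters
    nu_i = vp.mu_nu + vp.s_nu * rng.standard_normal(n) if vp.s_nu > 0 \
        else np.full(n, vp.mu_nu)
    w_i = vp.mu_w + vp.s_w * (rng.random(n) - 0.5) if vp.s_w > 0 \
        else np.full(n, vp.mu_w)
    pu = np.empty(n)
    _k.p_upper_vec(np.full(n, a), nu_i, w_i, pu)
    upper_i = (rng.random(n) < pu)
    out = np.empty(n)
    # draw untruncated here: the caller restarts whole trials beyond the
    # bound, which composes truncation and variability exactly (per-trial
    # truncation would renormalise within each parameter draw and bias the
    # mixture)
    _k.sample_trials(_METHODS[method], a, nu_i, w_i, upper_i, math.inf,
                     eps, _seed(rng), out)
    lab = np.where(upper_i, "upper", "lower").astype(object)
    # trials without mass below the bound at the drawn boundary: mark for
    # restart by exceeding the bound
    bad = ~np.isfinite(out)
    out[bad] = math.inf
    return out, lab
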
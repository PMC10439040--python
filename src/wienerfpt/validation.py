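"""Built-in validation studies for the samplers.

Three runnable experiments:

* :func:`log_concavity_scan` — numerically second-differentiates the
  log-density of the log-transformed decision time over a time grid for
  random parameter sets (with trial variability) and counts positive second
  derivatives, re-checking flagged points at escalated numerical effort.
  Log-concavity of this target is the precondition for ARS.
* :func:`ks_accuracy_study` — draws boundary-conditional samples for random
  parameter sets and tests them against the (truncated, renormalised,
  possibly mixed) conditional CDF with a one-sample Kolmogorov-Smirnov
  test; under a correct sampler the p-values are standard uniform and the
  share below .05 is 5%.
* :func:`speed_harness` — wall-clock medians over a condition x sample-size
  grid; reporting only, no assertions (timings are hardware-dependent).

plus :func:`binomial_meta_probability`, the exact binomial tail used to
judge how many significant uniformity tests are expected across conditions.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as _k
from .mixture import VariabilityParams, quadrature_nodes

__all__ = ["ParamPrior", "KSStudyResult", "log_concavity_scan",
           "ks_accuracy_study", "binomial_meta_probability", "speed_harness",
           "second_derivs_from_dh", "METHODS"]

METHODS = ("ars", "rs", "its", "p-ars")
_MCODE = {"ars": _k.ARS, "rs": _k.RS, "its": _k.ITS, "p-ars": _k.PARS}

# quadrature orders used by the studies; verified against order doubling to
# be far below the resolution of the statistics computed here (mixed-CDF
# error < 1e-7 over the study priors, versus a KS resolution of ~4e-2)
_GH_STUDY, _GL_STUDY = 20, 12
_GH_SCAN, _GL_SCAN = 32, 12


@dataclass(frozen=True)
class ParamPrior:
    """Parameter-generating prior of the simulation studies.

    a ~ U(a_range); mu_nu ~ N(0,1); mu_w ~ Beta(8,8); when switched on,
    s_nu ~ U(s_nu_range) and s_w ~ U(s_w_range); the requested response is
    Bernoulli(1/2).
    """

    a_range: tuple = (0.6, 2.0)
    s_nu_range: tuple = (0.0, 1.0)
    s_w_range: tuple = (0.0, 0.2)

    def draw(self, rng: np.random.Generator, s_nu_on: bool, s_w_on: bool):
        a = rng.uniform(*self.a_range)
        mu_nu = rng.standard_normal()
        mu_w = rng.beta(8.0, 8.0)
        s_nu = rng.uniform(*self.s_nu_range) if s_nu_on else 0.0
        s_w = rng.uniform(*self.s_w_range) if s_w_on else 0.0
        # keep the starting-point window inside (0, 1)
        s_w = min(s_w, 2.0 * min(mu_w, 1.0 - mu_w) - 1e-9) if s_w > 0 else 0.0
        s_w = max(s_w, 0.0)
        boundary = "upper" if rng.random() < 0.5 else "lower"
        return a, mu_nu, mu_w, s_nu, s_w, boundary


# ---------------------------------------------------------------------------
# log-concavity scan
# ---------------------------------------------------------------------------


def second_derivs_from_dh(alphas, dh_fun, delta: float = 1e-3):
    """Central second differences of h from first-derivative evaluations.

    ``dh_fun(alphas) -> dh`` must be vectorised.  This is the machinery the
    log-concavity scan runs on the diffusion target; it works for any
    differentiable log-density (useful as positive/negative controls).
    """
    alphas = np.asarray(alphas, float)
    return (dh_fun(alphas + delta) - dh_fun(alphas - delta)) / (2.0 * delta)


def _second_derivs(alphas, a, nus, ws, wts, delta):
    def dh_fun(al):
        hh = np.empty(al.size)
        dh = np.empty(al.size)
        _k.h_dh_vec(al, a, nus, ws, wts, hh, dh)
        return dh

    return second_derivs_from_dh(alphas, dh_fun, delta)


def log_concavity_scan(n_sets: int = 200, t_grid=None, seed=None,
                       rng: np.random.Generator | None = None,
                       delta: float = 1e-3, n_escalations: int = 3):
    """Count positive numerical second derivatives of log f_A, after retry.

    For each parameter set (a ~ U[0.5,2], mu_nu ~ N(0,1), mu_w ~ Beta(8,8),
    s_nu ~ U[0,2], s_w ~ U[0,0.2], response ~ Bernoulli(.5)) the grid of
    decision times (default 0.01..5 s in steps of 0.01) is mapped to alpha
    = log t and d^2 h / d alpha^2 is formed from central differences of the
    analytically computed first derivative.  Flagged positives are
    recomputed with Richardson extrapolation at shrinking step sizes; the
    returned dict reports pre- and post-retry counts.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if t_grid is None:
        t_grid = np.arange(0.01, 5.0 + 1e-12, 0.01)
    alphas = np.log(np.asarray(t_grid, float))
    prior = ParamPrior(a_range=(0.5, 2.0), s_nu_range=(0.0, 2.0))
    raw = 0
    after = 0
    checked = 0
    for _ in range(n_sets):
        a, mu_nu, mu_w, s_nu, s_w, b = prior.draw(rng, True, True)
        vp = VariabilityParams(mu_nu=mu_nu, mu_w=mu_w, s_nu=s_nu, s_w=s_w)
        nus, ws, wts = quadrature_nodes(a, vp, b, _GH_SCAN, _GL_SCAN)
        d2 = _second_derivs(alphas, a, nus, ws, wts, delta)
        checked += alphas.size
        bad = np.flatnonzero(d2 > 0)
        raw += bad.size
        for j in bad:
            al = alphas[j:j + 1]
            ok = False
            dd = delta
            for _ in range(n_escalations):
                d2a = _second_derivs(al, a, nus, ws, wts, dd)[0]
                d2b = _second_derivs(al, a, nus, ws, wts, dd / 2.0)[0]
                rich = (4.0 * d2b - d2a) / 3.0
                if rich <= 0.0:
                    ok = True
                    break
                dd /= 4.0
            if not ok:
                after += 1
    return {"n_sets": n_sets, "n_points": checked,
            "violations_raw": raw, "violations_after_retry": after}


# ---------------------------------------------------------------------------
# KS accuracy study
# ---------------------------------------------------------------------------


@dataclass
class KSStudyResult:
    method: str
    trunc: float
    s_nu_on: bool
    s_w_on: bool
    p_values: np.ndarray = field(repr=False)
    share_significant: float = 0.0
    uniformity_p: float = 0.0
    n_redrawn: int = 0
    n_fallback: int = 0  # sets sampled by exact CDF inversion instead of
    # the requested method (non-log-concave node mixture or tiny mass)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.method, "trunc": self.trunc,
            "s_nu_on": self.s_nu_on, "s_w_on": self.s_w_on,
            "p_value": self.p_values,
        })


def _ks_pvalue(draws: np.ndarray, cdf_vals: np.ndarray) -> float:
    """One-sample KS p-value from precomputed CDF values at sorted draws."""
    n = draws.size
    i = np.arange(1, n + 1)
    d = max(np.max(i / n - cdf_vals), np.max(cdf_vals - (i - 1) / n))
    return float(stats.kstwo.sf(d, n))


def ks_accuracy_study(method: str, trunc: float = math.inf,
                      s_nu_on: bool = False, s_w_on: bool = False,
                      n_sets: int = 1000, n_per_set: int = 1000,
                      seed=None, eps: float = 1e-12,
                      prior: ParamPrior = ParamPrior()) -> KSStudyResult:
    """One cell of the sampler-accuracy study.

    Per parameter set: n_per_set boundary-conditional draws, one-sample KS
    test against the truncated renormalised conditional CDF (mixed over the
    trial-variability laws when these are on).  Parameter sets whose
    conditional mass at the sampled boundary is below 1e-6 are redrawn.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    kseeds = ss.generate_state(2 * n_sets, dtype=np.uint32) >> 1
    pvals = np.empty(n_sets)
    redrawn = 0
    fallback = 0
    out = np.empty(n_per_set)
    for i in range(n_sets):
        for attempt in range(100):
            a, mu_nu, mu_w, s_nu, s_w, b = prior.draw(rng, s_nu_on, s_w_on)
            vp = VariabilityParams(mu_nu=mu_nu, mu_w=mu_w, s_nu=s_nu, s_w=s_w)
            nus, ws, wts = quadrature_nodes(a, vp, b, _GH_STUDY, _GL_STUDY)
            mass = _k._mass_mix(a, nus, ws, wts, trunc, eps)
            if mass >= 1e-6:
                break
            redrawn += 1
        nu_c = -mu_nu if b == "upper" else mu_nu
        w_c = 1.0 - mu_w if b == "upper" else mu_w
        st, mass = _k.sample_set(_MCODE[method], n_per_set, a, nu_c, s_nu,
                                 w_c, s_w, nus, ws, wts, trunc, eps,
                                 int(kseeds[i]), out)
        if st == 5:
            fallback += 1
        elif st != 0:
            raise RuntimeError(
                f"sampling failed (status {st}) for set {i}: a={a}, "
                f"mu_nu={mu_nu}, mu_w={mu_w}, s_nu={s_nu}, s_w={s_w}, {b}")
        srt = np.sort(out)
        cdf_vals = np.empty(n_per_set)
        _k.cdf_mix_vec(srt, a, nus, ws, wts, eps, cdf_vals)
        pvals[i] = _ks_pvalue(srt, cdf_vals / mass)
    share = float(np.mean(pvals < 0.05))
    unif = float(stats.kstest(pvals, "uniform").pvalue)
    return KSStudyResult(method, trunc, s_nu_on, s_w_on, pvals, share,
                         unif, redrawn, fallback)


def binomial_meta_probability(n_conditions: int = 32, k_min: int = 3,
                              alpha: float = 0.05) -> float:
    """Exact P(X >= k_min) with X ~ Binomial(n_conditions, alpha): the
    chance of seeing that many significant uniformity tests by luck."""
    if k_min <= 0:
        return 1.0
    return float(stats.binom.sf(k_min - 1, n_conditions, alpha))


# ---------------------------------------------------------------------------
# speed harness (reporting only)
# ---------------------------------------------------------------------------


def speed_harness(n_grid=None, reps: int = 100, seed=None,
                  trunc_opts=(math.inf, 0.5), response_opts=("both", "one"),
                  s_nu_opts=(0.0, 2.0), s_w_opts=(0.0, 0.2),
                  prior: ParamPrior = ParamPrior()) -> pd.DataFrame:
    """Median wall-times over the condition grid (2 truncations x 2 response
    modes x 2 drift-variability x 2 start-variability = 16 conditions) and a
    ladder of sample sizes.  No assertions: output is a tidy table."""
    from .mixture import sample_with_variability

    if n_grid is None:
        n_grid = [10 ** i for i in range(7)]
    rng = np.random.default_rng(seed)
    rows = []
    for trunc in trunc_opts:
        for response in response_opts:
            for s_nu_hi in s_nu_opts:
                for s_w_hi in s_w_opts:
                    for method in METHODS:
                        for n in n_grid:
                            times = np.empty(reps)
                            for r in range(reps):
                                a, mu_nu, mu_w, _, _, b = prior.draw(
                                    rng, False, False)
                                s_nu = rng.uniform(0, s_nu_hi) if s_nu_hi else 0.0
                                s_w = rng.uniform(0, s_w_hi) if s_w_hi else 0.0
                                s_w = min(s_w, 2 * min(mu_w, 1 - mu_w) - 1e-9) \
                                    if s_w > 0 else 0.0
                                vp = VariabilityParams(mu_nu=mu_nu, mu_w=mu_w,
                                                       s_nu=max(s_nu, 0.0),
                                                       s_w=max(s_w, 0.0))
                                resp = b if response == "one" else "both"
                                t0 = time.perf_counter()
                                sample_with_variability(
                                    method, a, vp, resp, n, trunc, rng=rng,
                                    n_nu=_GH_STUDY, n_w=_GL_STUDY)
                                times[r] = time.perf_counter() - t0
                            rows.append({
                                "method": method, "trunc": trunc,
                                "response": response, "s_nu_on": s_nu_hi > 0,
                                "s_w_on": s_w_hi > 0, "n": n,
                                "median_seconds": float(np.median(times)),
                            })
    return pd.DataFrame(rows)
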
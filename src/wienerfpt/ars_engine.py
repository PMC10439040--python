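"""Generic adaptive rejection sampling for log-concave targets.

Given a target supplying ``h(x) = log g(x)`` and its derivative ``h'(x)``,
the sampler maintains a piecewise-linear *upper hull* u_k built from
tangents at support points T_k = {x_1 <= ... <= x_k} and a *lower hull* l_k
of chords, with exp(l_k) <= g <= exp(u_k).  Proposals are drawn from the
piecewise-exponential envelope by segment selection and within-segment
inversion; the squeeze test accepts via exp(l_k - u_k) without evaluating
the target, otherwise the target is evaluated, the full rejection test
applied, and the evaluated point inserted into the hull (tightening both
hulls for all later draws).

The pseudo-adaptive variant (P-ARS) discards the hull after each accepted
draw (``keep_hull=False``): updates only help within a single draw.

A log-concavity violation (support-point slopes not decreasing) raises
:class:`LogConcavityError` rather than being repaired silently: with a
genuinely non-log-concave target the hull algebra is invalid and the error
is the diagnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "HullState", "AcceptDecision", "LogConcavityError", "ArsError",
    "init_hull", "hull_insert", "sample_envelope", "squeeze_accept",
    "ars_sample", "hull_to_json", "hull_from_json",
]

Target = Callable[[float], Tuple[float, float]]

_SLOPE_TOL = 1e-7
_DUP_TOL = 1e-12
_HULL_CAP = 200


class ArsError(RuntimeError):
    pass


class LogConcavityError(ArsError):
    """Support-point slopes increased: the target is not log-concave."""


@dataclass
class AcceptDecision:
    outcome: str                 # accept_squeeze | accept_full | reject
    target_evaluated: bool
    h: float = math.nan          # target value when evaluated
    dh: float = math.nan

    def __post_init__(self):
        assert self.target_evaluated == (self.outcome != "accept_squeeze")


def _seg_logmass(h: float, x: float, s: float, z0: float, z1: float) -> float:
    if z0 == -math.inf:
        return h + s * (z1 - x) - math.log(s)
    if z1 == math.inf:
        return h + s * (z0 - x) - math.log(-s)
    d = z1 - z0
    if d <= 0:
        return -math.inf
    if abs(s) * d < 1e-10:
        return h + s * (0.5 * (z0 + z1) - x) + math.log(d)
    if s > 0:
        return h + s * (z1 - x) + math.log1p(-math.exp(-s * d)) - math.log(s)
    return h + s * (z0 - x) + math.log1p(-math.exp(s * d)) - math.log(-s)


def _intersect(x1, h1, s1, x2, h2, s2):
    if s1 - s2 < 1e-13:
        return 0.5 * (x1 + x2)
    z = (h2 - h1 + x1 * s1 - x2 * s2) / (s1 - s2)
    return min(max(z, x1), x2)


@dataclass
class HullState:
    """Envelope/squeeze state of the sampler.

    xs, hs, dhs : support abscissae, target log-values and slopes
    zs : intersection abscissae, zs[0]/zs[-1] being the domain edges
    logJs : log masses of the envelope segments
    domain : (low, high), possibly infinite
    """

    xs: np.ndarray
    hs: np.ndarray
    dhs: np.ndarray
    zs: np.ndarray
    logJs: np.ndarray
    domain: Tuple[float, float]
    _cum: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.xs)

    @property
    def log_mass(self) -> float:
        m = np.max(self.logJs)
        return float(m + np.log(np.sum(np.exp(self.logJs - m))))

    def cumulative(self) -> np.ndarray:
        if self._cum is None:
            m = np.max(self.logJs)
            j = np.exp(self.logJs - m)
            c = np.cumsum(j)
            self._cum = c / c[-1]
        return self._cum

    def upper(self, x: float) -> float:
        """Upper hull u_k(x)."""
        i = int(np.searchsorted(self.zs, x, side="right")) - 1
        i = min(max(i, 0), self.k - 1)
        return float(self.hs[i] + self.dhs[i] * (x - self.xs[i]))

    def lower(self, x: float) -> float:
        """Lower hull l_k(x); -inf outside [x_1, x_k]."""
        if x < self.xs[0] or x > self.xs[-1]:
            return -math.inf
        j = int(np.searchsorted(self.xs, x))
        if j == 0:
            return float(self.hs[0])
        x0, x1 = self.xs[j - 1], self.xs[j]
        if x1 - x0 < 1e-300:
            return float(self.hs[j])
        lam = (x - x0) / (x1 - x0)
        return float((1 - lam) * self.hs[j - 1] + lam * self.hs[j])

    def _validate(self):
        if np.any(np.diff(self.dhs) > _SLOPE_TOL * (1 + np.abs(self.dhs[1:]))):
            raise LogConcavityError(
                "support-point slopes are not decreasing; the target is not "
                "log-concave on this domain")
        lo, hi = self.domain
        if lo == -math.inf and self.dhs[0] <= 0:
            raise ArsError("leftmost slope must be positive on an unbounded "
                           "lower domain (infinite envelope mass)")
        if hi == math.inf and self.dhs[-1] >= 0:
            raise ArsError("rightmost slope must be negative on an unbounded "
                           "upper domain (infinite envelope mass)")


def _build(xs, hs, dhs, domain) -> HullState:
    xs = np.asarray(xs, float)
    hs = np.asarray(hs, float)
    dhs = np.asarray(dhs, float)
    k = len(xs)
    zs = np.empty(k + 1)
    zs[0], zs[k] = domain
    for i in range(1, k):
        zs[i] = _intersect(xs[i - 1], hs[i - 1], dhs[i - 1],
                           xs[i], hs[i], dhs[i])
    logJs = np.array([_seg_logmass(hs[i], xs[i], dhs[i], zs[i], zs[i + 1])
                      for i in range(k)])
    st = HullState(xs, hs, dhs, zs, logJs, domain)
    st._validate()
    return st


def init_hull(target: Target, domain=(-math.inf, math.inf), k0: int = 3,
              start: float = 0.0) -> HullState:
    """Initial hull from a mode-bracketing geometric search around ``start``.

    Points where h underflows to -inf are never inserted (tangents are
    undefined there); the search steps back towards the mode instead.
    """
    if k0 < 2:
        raise ValueError("k0 must be >= 2")
    lo, hi = domain

    def ev(x):
        h, dh = target(x)
        return float(h), float(dh)

    x0 = min(max(start, lo + 1e-9 if lo != -math.inf else start),
             hi - 1e-9 if hi != math.inf else start)
    h0, d0 = ev(x0)
    if not math.isfinite(h0):
        # ladder probe for a point of finite log-density
        loa = lo if lo != -math.inf else x0 - 50.0
        hia = hi if hi != math.inf else x0 + 50.0
        best = -math.inf
        for xc in np.linspace(loa + 1e-9 * (1 + abs(loa)),
                              hia - 1e-9 * (1 + abs(hia)), 80):
            hc, dc = ev(float(xc))
            if hc > best:
                best, x0, h0, d0 = hc, float(xc), hc, dc
        if not math.isfinite(h0):
            raise ArsError("could not find a point of finite log-density")
    # left bracket: slope > 0 (unless domain edge is finite)
    xl, hl, dl = x0, h0, d0
    step, m = 0.5, 0
    while dl <= 0 and m < 60:
        xn = xl - step
        if lo != -math.inf and xn <= lo:
            xn = lo + 1e-12 * (1 + abs(lo))
        hn, dn = ev(xn)
        if math.isfinite(hn):
            xl, hl, dl = xn, hn, dn
        step *= 2
        m += 1
        if lo != -math.inf and xn <= lo + 1e-9:
            break
    if lo == -math.inf and dl <= 0:
        raise ArsError("initialization failed: no positive slope found left "
                       "of the start on an unbounded domain")
    # a near-flat leftmost tangent gives the unbounded left tail of the
    # envelope enormous mass: walk further left while the slope improves
    if lo == -math.inf:
        step, m = 0.5, 0
        while dl < 1.0 and m < 20:
            xn = xl - step
            hn, dn = ev(xn)
            if not math.isfinite(hn) or dn <= dl:
                break
            xl, hl, dl = xn, hn, dn
            step *= 2
            m += 1
    # right bracket: slope < 0 (unless domain edge is finite)
    xr, hr, dr = x0, h0, d0
    step, m = 0.5, 0
    while dr >= 0 and m < 60:
        xn = xr + step
        if hi != math.inf and xn >= hi:
            xn = hi - 1e-12 * (1 + abs(hi))
        hn, dn = ev(xn)
        if math.isfinite(hn):
            xr, hr, dr = xn, hn, dn
        else:  # stepped past the support: bisect back
            for _ in range(80):
                xm = 0.5 * (xr + xn)
                hm, dm = ev(xm)
                if math.isfinite(hm):
                    xr, hr, dr = xm, hm, dm
                    break
                xn = xm
        step *= 2
        m += 1
        if hi != math.inf and xr >= hi - 1e-9:
            break
    if hi == math.inf and dr >= 0:
        raise ArsError("initialization failed: no negative slope found right "
                       "of the start on an unbounded domain")
    if hi == math.inf:
        step, m = 0.5, 0
        while dr > -1.0 and m < 20:
            xn = xr + step
            hn, dn = ev(xn)
            if not math.isfinite(hn) or dn >= dr:
                break
            xr, hr, dr = xn, hn, dn
            step *= 2
            m += 1
    pts = {xl: (hl, dl), xr: (hr, dr)}
    # interior fill up to k0 points
    while len(pts) < k0:
        keys = sorted(pts)
        gaps = np.diff(keys)
        j = int(np.argmax(gaps))
        xm = 0.5 * (keys[j] + keys[j + 1])
        if xm in pts:
            break
        hm, dm = ev(xm)
        if math.isfinite(hm):
            pts[xm] = (hm, dm)
        else:
            break
    keys = sorted(pts)
    return _build(keys, [pts[x][0] for x in keys], [pts[x][1] for x in keys],
                  domain)


def hull_insert(state: HullState, x_new: float, h_new: float,
                dh_new: float) -> HullState:
    """Insert a support point, recomputing only the affected intersections
    and segment masses.  Inserting an existing point returns the state
    unchanged; envelope mass never increases."""
    lo, hi = state.domain
    if not math.isfinite(h_new):
        return state
    if not (lo <= x_new <= hi):
        raise ValueError(f"x_new={x_new} outside domain {state.domain}")
    if state.k >= _HULL_CAP:
        return state
    pos = int(np.searchsorted(state.xs, x_new))
    for q in (pos - 1, pos):
        if 0 <= q < state.k and abs(state.xs[q] - x_new) \
                < _DUP_TOL * (1 + abs(x_new)):
            return state
    stol = _SLOPE_TOL * (1 + abs(dh_new))
    if pos > 0 and dh_new > state.dhs[pos - 1] + stol:
        raise LogConcavityError(
            f"slope at inserted point x={x_new} exceeds its left neighbour")
    if pos < state.k and dh_new < state.dhs[pos] - stol:
        raise LogConcavityError(
            f"slope at inserted point x={x_new} is below its right neighbour")
    if pos == 0 and lo == -math.inf and dh_new <= 0:
        return state
    if pos == state.k and hi == math.inf and dh_new >= 0:
        return state
    if pos > 0 and dh_new > state.dhs[pos - 1]:
        return state  # roundoff band: skip rather than break ordering
    if pos < state.k and dh_new < state.dhs[pos]:
        return state

    xs = np.insert(state.xs, pos, x_new)
    hs = np.insert(state.hs, pos, h_new)
    dhs = np.insert(state.dhs, pos, dh_new)
    k = state.k + 1
    # affected intersections: z_{pos-1}, z_pos, z_{pos+1} in the new indexing
    zs = np.insert(state.zs, pos, 0.0)
    for i in (pos - 1, pos, pos + 1):
        if 1 <= i <= k - 1:
            zs[i] = _intersect(xs[i - 1], hs[i - 1], dhs[i - 1],
                               xs[i], hs[i], dhs[i])
    zs[0], zs[k] = lo, hi
    # affected segment masses: pos-1, pos, pos+1
    logJs = np.insert(state.logJs, pos, 0.0)
    for i in (pos - 1, pos, pos + 1):
        if 0 <= i <= k - 1:
            logJs[i] = _seg_logmass(hs[i], xs[i], dhs[i], zs[i], zs[i + 1])
    st = HullState(xs, hs, dhs, zs, logJs, state.domain)
    st._validate()
    return st


def sample_envelope(state: HullState, u_prop: float) -> float:
    """Invert the piecewise-exponential envelope CDF at u_prop in [0, 1)."""
    cum = state.cumulative()
    i = int(np.searchsorted(cum, u_prop, side="right"))
    i = min(i, state.k - 1)
    base = cum[i - 1] if i > 0 else 0.0
    width = cum[i] - base
    ustar = (u_prop - base) / width if width > 0 else 0.5
    ustar = min(max(ustar, 0.0), 1.0)
    z0, z1 = state.zs[i], state.zs[i + 1]
    s = state.dhs[i]
    if z0 == -math.inf:
        if ustar == 0.0:
            ustar = 1e-300
        return float(z1 + math.log(ustar) / s)
    if z1 == math.inf:
        return float(z0 + math.log1p(-ustar) / s)
    d = z1 - z0
    if abs(s) * d < 1e-10:
        return float(z0 + ustar * d)
    return float(z0 + math.log1p(ustar * math.expm1(s * d)) / s)


def squeeze_accept(state: HullState, x_star: float, u: float,
                   target: Target) -> AcceptDecision:
    """Squeeze test, then (if needed) full test with a target evaluation.

    When the decision reports ``target_evaluated`` the caller must insert
    the evaluated point into the hull to keep the adaptive guarantee.
    """
    uk = state.upper(x_star)
    lk = state.lower(x_star)
    logu = math.log(u) if u > 0 else -745.0
    if logu <= lk - uk:
        return AcceptDecision("accept_squeeze", False)
    h, dh = target(x_star)
    if math.isfinite(h) and logu <= h - uk:
        return AcceptDecision("accept_full", True, h, dh)
    return AcceptDecision("reject", True, h, dh)


def ars_sample(target: Target, n: int, domain=(-math.inf, math.inf),
               rng: np.random.Generator | None = None, keep_hull: bool = True,
               start: float = 0.0, k0: int = 3, max_reject: int = 10 ** 6,
               hull: HullState | None = None):
    """Draw n values from exp(h)/integral(exp(h)) by ARS (or P-ARS when
    ``keep_hull`` is False).  Returns (samples, final HullState)."""
    rng = np.random.default_rng() if rng is None else rng
    state = hull if hull is not None else init_hull(target, domain, k0, start)
    out = np.empty(n)
    for i in range(n):
        if not keep_hull and i > 0:
            state = init_hull(target, domain, k0, start)
        rejects = 0
        while True:
            x = sample_envelope(state, rng.random())
            dec = squeeze_accept(state, x, rng.random(), target)
            if dec.target_evaluated:
                state = hull_insert(state, x, dec.h, dec.dh)
            if dec.outcome != "reject":
                out[i] = x
                break
            rejects += 1
            if rejects > max_reject:
                raise ArsError(f"more than {max_reject} rejections for a "
                               "single draw; envelope is degenerate")
    return out, state


# --- hull persistence -------------------------------------------------------


def hull_to_json(state: HullState) -> str:
    return json.dumps({
        "xs": state.xs.tolist(),
        "hs": state.hs.tolist(),
        "dhs": state.dhs.tolist(),
        "zs": [("-inf" if z == -math.inf else "inf" if z == math.inf else z)
               for z in state.zs.tolist()],
        "logJs": state.logJs.tolist(),
        "domain": [("-inf" if state.domain[0] == -math.inf
                    else state.domain[0]),
                   ("inf" if state.domain[1] == math.inf
                    else state.domain[1])],
    })


def _unfloat(v):
    if v == "inf":
        return math.inf
    if v == "-inf":
        return -math.inf
    return float(v)


def hull_from_json(doc: str) -> HullState:
    d = json.loads(doc)
    return HullState(
        xs=np.asarray(d["xs"], float),
        hs=np.asarray(d["hs"], float),
        dhs=np.asarray(d["dhs"], float),
        zs=np.asarray([_unfloat(z) for z in d["zs"]], float),
        logJs=np.asarray(d["logJs"], float),
        domain=(_unfloat(d["domain"][0]), _unfloat(d["domain"][1])),
    )
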
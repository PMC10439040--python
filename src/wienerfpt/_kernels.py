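"""Numba-accelerated numerical core: series densities, CDFs and samplers.

Every kernel works on *lower*-boundary defective quantities of a Wiener
diffusion with boundary separation ``a``, drift ``nu``, relative starting
point ``w`` (diffusion coefficient fixed at 1) and decision time ``t``
(net of non-decision time).  Upper-boundary quantities are obtained by the
reflection (nu, w) -> (-nu, 1 - w) at the caller.

Densities are evaluated through the scaled density

    g_lower(t; nu, a, w) = a^-2 * exp(-nu*a*w - nu^2 t / 2) * f1(t/a^2; w)

where f1 has a small-time (image) and a large-time (spectral) series
representation.  To stay finite in far tails everything is carried as
(log value, d log / dt) pairs; mixtures over quadrature nodes combine them
with log-sum-exp.

Method codes used by :func:`sample_set`:
0 = ARS (adaptive rejection sampling, persistent hull),
1 = RS (Drugowitsch-style rejection sampling),
2 = ITS (inverse transform sampling, bisection),
3 = P-ARS (hull rebuilt for every draw).
"""

import math

import numpy as np
from numba import njit

PI = math.pi
PI2 = math.pi * math.pi
SQRT2 = math.sqrt(2.0)
LOG_2PI = math.log(2.0 * math.pi)
INF = math.inf

ARS, RS, ITS, PARS = 0, 1, 2, 3

HULL_CAP = 200  # support points beyond this: envelope frozen, tests stay exact

# ---------------------------------------------------------------------------
# scalar special functions
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ndtr(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True)
def _log_ndtr(x):
    if x > -25.0:
        return math.log(0.5 * math.erfc(-x / SQRT2))
    # asymptotic expansion of the normal tail for deep arguments
    ix2 = 1.0 / (x * x)
    corr = 1.0 + ix2 * (-1.0 + ix2 * (3.0 + ix2 * (-15.0 + 105.0 * ix2)))
    return -0.5 * x * x - 0.5 * LOG_2PI - math.log(-x) + math.log(corr)


# ---------------------------------------------------------------------------
# f1 series: log value and d(log f1)/du
# ---------------------------------------------------------------------------


@njit(cache=True)
def _log_f1_small(u, w):
    """Small-time (image) series, factored by the dominant k=0 term.

    Returns (log f1(u; w), d log f1 / du).
    """
    c0 = w * w / (2.0 * u)
    s1 = w                      # sum (w+2k) e_k, e_0 = 1
    s2 = w * c0                 # sum (w+2k) * (w+2k)^2/(2u) * e_k
    sa = w                      # absolute-value accumulator for stopping
    kmin = int(0.5 * math.sqrt(u)) + 1
    k = 1
    while k <= 500:
        bp = w + 2.0 * k
        bm = w - 2.0 * k
        ep = math.exp(-(bp * bp) / (2.0 * u) + c0)
        em = math.exp(-(bm * bm) / (2.0 * u) + c0)
        tp = bp * ep
        tm = bm * em
        s1 += tp + tm
        s2 += tp * (bp * bp) / (2.0 * u) + tm * (bm * bm) / (2.0 * u)
        sa += abs(tp) + abs(tm)
        if k >= kmin and (abs(tp) + abs(tm)) * (2.0 + bp * bp / (2.0 * u)) \
                < 1e-17 * (sa + 1e-300):
            break
        k += 1
    if s1 <= 0.0:
        s1 = 1e-300
    log_f1 = -0.5 * (LOG_2PI + 3.0 * math.log(u)) - c0 + math.log(s1)
    ratio = (s2 / s1 - 1.5) / u
    if not math.isfinite(ratio) or ratio > 1e300:
        ratio = 1e300  # deep left tail: d log f1 / du ~ w^2 / (2 u^2)
    return log_f1, ratio


@njit(cache=True)
def _log_f1_large(u, w):
    """Large-time (spectral) series, factored by exp(-pi^2 u / 2)."""
    s1 = 0.0
    s3 = 0.0
    sa = 0.0
    kmin = int(1.0 / (PI * math.sqrt(u))) + 1
    k = 1
    while k <= 100000:
        e = math.exp(-(k * k - 1.0) * PI2 * u / 2.0)
        sk = math.sin(k * PI * w)
        t1 = k * e * sk
        s1 += t1
        s3 += k * k * k * e * sk
        sa += k * e
        kk = k + 1.0
        bound = kk * math.exp(-(kk * kk - 1.0) * PI2 * u / 2.0)
        if k >= kmin and bound * (kk * kk + 1.0) < 1e-17 * (sa + 1e-300):
            break
        k += 1
    if s1 <= 0.0:
        s1 = 1e-300
    log_f1 = math.log(PI) - PI2 * u / 2.0 + math.log(s1)
    ratio = -(PI2 / 2.0) * (s3 / s1)
    return log_f1, ratio


@njit(cache=True)
def _log_f1(u, w):
    # representation switch: equal estimated term counts near u ~ 0.64
    if u < 0.64:
        return _log_f1_small(u, w)
    return _log_f1_large(u, w)


@njit(cache=True)
def _log_g_lower(t, a, nu, w):
    """(log g_lower(t), d log g_lower / dt) for the defective density."""
    u = t / (a * a)
    lf, r = _log_f1(u, w)
    log_g = -nu * a * w - nu * nu * t / 2.0 - 2.0 * math.log(a) + lf
    dlog = -nu * nu / 2.0 + r / (a * a)
    return log_g, dlog


@njit(cache=True)
def _dens_lower(t, a, nu, w):
    if t <= 0.0:
        return 0.0
    lg, _ = _log_g_lower(t, a, nu, w)
    if lg < -745.0:
        return 0.0
    return math.exp(lg)


@njit(cache=True)
def _dens_tderiv_lower(t, a, nu, w):
    if t <= 0.0:
        return 0.0
    lg, dl = _log_g_lower(t, a, nu, w)
    if lg < -745.0:
        return 0.0
    return math.exp(lg) * dl


# ---------------------------------------------------------------------------
# absorption probability (stable closed form)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _p_upper(a, nu, w):
    x = 2.0 * nu * a
    if abs(nu * a) < 1e-8:
        return w
    if x > 0.0:
        return math.expm1(-x * w) / math.expm1(-x)
    if x > -650.0:
        return math.expm1(-x * w) / math.expm1(-x)
    # deep negative drift: P(upper) ~ exp(x (1-w))
    ex = x * (1.0 - w)
    if ex < -745.0:
        return 0.0
    return math.exp(ex)


@njit(cache=True)
def _p_lower(a, nu, w):
    return 1.0 - _p_upper(a, nu, w)


# ---------------------------------------------------------------------------
# defective CDF at the lower boundary
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cdf_lower_images(t, a, nu, w, eps):
    """Phi-based image series for the CDF; stable for large |nu*a*w|."""
    total = 0.0
    sq = math.sqrt(t)
    k = 0
    while k <= 200:
        done = 0
        for sgn in range(2):
            kk = k if sgn == 0 else -(k + 1)
            b = a * (w + 2.0 * kk)
            # integral of b/sqrt(2 pi s^3) exp(-(b - mu s)^2 / 2s), mu = -nu
            mu = -nu
            if b > 0.0:
                la = _log_ndtr((mu * t - b) / sq)
                lb = 2.0 * mu * b + _log_ndtr(-(b + mu * t) / sq)
                val = math.exp(la) + math.exp(lb) if lb < 700.0 else math.exp(la)
                sign = 1.0
            else:
                la = _log_ndtr((b - mu * t) / sq)
                lb = 2.0 * mu * b + _log_ndtr((b + mu * t) / sq)
                val = math.exp(la) + math.exp(lb) if lb < 700.0 else math.exp(la)
                sign = -1.0
            pref = nu * (b - a * w)
            term = sign * math.exp(pref) * val if pref < 700.0 else 0.0
            total += term
            if k >= 2 and abs(term) < 0.01 * eps:
                done += 1
        if done == 2:
            break
        k += 1
    if total < 0.0:
        total = 0.0
    return total


@njit(cache=True)
def _cdf_lower(t, a, nu, w, eps):
    """Defective CDF F_lower(t); absolute error <= eps."""
    if t <= 0.0:
        return 0.0
    b0 = a * w
    if b0 * b0 / (2.0 * t) > 700.0:
        return 0.0  # below the first image's support: astronomically small
    if abs(nu * a * w) > 30.0 or abs(nu * a * (1.0 - w)) > 30.0:
        return _cdf_lower_images(t, a, nu, w, eps)
    P = _p_lower(a, nu, w)
    aa = a * a
    s = 0.0
    kmin = int(a / (PI * math.sqrt(t))) + 1
    if kmin > 100000:
        kmin = 100000
    k = 1
    while k <= 1000000:
        lam = 0.5 * (nu * nu + k * k * PI2 / aa)
        ex = -nu * a * w - lam * t
        if ex > -745.0:
            s += k * math.sin(k * PI * w) / lam * math.exp(ex)
        if k >= kmin:
            lamn = 0.5 * (nu * nu + (k + 1.0) * (k + 1.0) * PI2 / aa)
            exn = -nu * a * w - lamn * t
            bnd = (k + 1.0) / lamn * math.exp(exn) if exn > -745.0 else 0.0
            q = math.exp(-(2.0 * k + 3.0) * PI2 * t / (2.0 * aa))
            denom = 1.0 - q
            if denom < 1e-3:
                denom = 1e-3
            if (PI / aa) * bnd / denom < 0.5 * eps:
                break
        k += 1
    F = P - (PI / aa) * s
    if F < 0.0:
        F = 0.0
    elif F > P:
        F = P
    return F


# ---------------------------------------------------------------------------
# mixtures over quadrature nodes (single node == plain WDM)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _log_gmix(t, a, nus, wsn, wts):
    """(log sum_i wts_i g_lower(t; nus_i, wsn_i), d log / dt)."""
    m = nus.shape[0]
    lg = np.empty(m)
    rt = np.empty(m)
    mx = -1e308
    for i in range(m):
        l, r = _log_g_lower(t, a, nus[i], wsn[i])
        lg[i] = l
        rt[i] = r
        if l > mx:
            mx = l
    if mx < -1e306 or not math.isfinite(mx):
        return -1e308, 0.0
    s = 0.0
    sr = 0.0
    for i in range(m):
        e = wts[i] * math.exp(lg[i] - mx)
        s += e
        sr += e * rt[i]
    if s <= 0.0:
        return -1e308, 0.0
    return mx + math.log(s), sr / s


@njit(cache=True)
def _cdf_mix(t, a, nus, wsn, wts, eps):
    s = 0.0
    for i in range(nus.shape[0]):
        s += wts[i] * _cdf_lower(t, a, nus[i], wsn[i], eps)
    return s


@njit(cache=True)
def _mass_mix(a, nus, wsn, wts, bound, eps):
    if bound == INF:
        s = 0.0
        for i in range(nus.shape[0]):
            s += wts[i] * _p_lower(a, nus[i], wsn[i])
        return s
    return _cdf_mix(bound, a, nus, wsn, wts, eps)


@njit(cache=True)
def _h_dh(alpha, a, nus, wsn, wts):
    """Log-density of A = log T and its derivative (identity log transform)."""
    if alpha > 700.0 or alpha < -700.0:
        return -1e308, 0.0
    t = math.exp(alpha)
    l, r = _log_gmix(t, a, nus, wsn, wts)
    if l < -1e307:
        return -1e308, 0.0
    return alpha + l, 1.0 + t * r


# ---------------------------------------------------------------------------
# inverse transform sampling (bisection on the CDF)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _its_quantile(utarget, a, nu, w, bound, eps):
    """Solve F_lower(t) = utarget by bisection (1e-10 absolute in t)."""
    hi = a * a / (1.0 + abs(nu))
    if bound != INF and hi > bound:
        hi = bound
    it = 0
    while _cdf_lower(hi, a, nu, w, eps) < utarget and it < 200:
        hi *= 2.0
        if bound != INF and hi >= bound:
            hi = bound
            break
        it += 1
    lo = 0.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if _cdf_lower(mid, a, nu, w, eps) < utarget:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _its_quantile_mix(utarget, a, nus, wsn, wts, bound, eps):
    hi = a * a
    if bound != INF and hi > bound:
        hi = bound
    it = 0
    while _cdf_mix(hi, a, nus, wsn, wts, eps) < utarget and it < 200:
        hi *= 2.0
        if bound != INF and hi >= bound:
            hi = bound
            break
        it += 1
    lo = 0.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if _cdf_mix(mid, a, nus, wsn, wts, eps) < utarget:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# rejection sampling (Drugowitsch-style, w = 1/2 core + staged recursion)
# ---------------------------------------------------------------------------

_U_SWITCH = 0.64  # scaled-time switch between short- and long-time proposals


@njit(cache=True)
def _ig_draw(mu, lam):
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    z = np.random.normal()
    y = z * z
    x = mu + mu * mu * y / (2.0 * lam) \
        - mu / (2.0 * lam) * math.sqrt(4.0 * mu * lam * y + mu * mu * y * y)
    if x <= 0.0:
        x = 1e-300
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _sym_u_draw(nu_s):
    """One scaled FPT draw for the symmetric (w=1/2) problem.

    Target density (unnormalised): exp(-nu_s^2 u / 2) * f1(u; 1/2).
    Short-time envelope: first image term (truncated inverse Gaussian /
    Levy proposal); long-time envelope: first spectral term (shifted
    exponential proposal).  Exact alternating-series accept tests.
    """
    an = abs(nu_s)
    us = _U_SWITCH
    lam_l = 0.5 * (PI2 + nu_s * nu_s)
    log_ml = math.log(PI / lam_l) - lam_l * us
    use_levy = an < 1e-4
    mu = 0.0
    if use_levy:
        fs = math.erfc(math.sqrt(0.25 / (2.0 * us)))
        log_ms = math.log(fs)
    else:
        mu = 1.0 / (2.0 * an)
        lam = 0.25
        if an >= 50.0:
            fs = 1.0
        else:
            sq = math.sqrt(lam / us)
            fs = _ndtr(sq * (us / mu - 1.0)) \
                + math.exp(2.0 * lam / mu) * _ndtr(-sq * (us / mu + 1.0))
            if fs > 1.0:
                fs = 1.0
            elif fs < 1e-300:
                fs = 1e-300
        log_ms = -0.5 * an + math.log(fs)
    p_short = 1.0 / (1.0 + math.exp(log_ml - log_ms))
    while True:
        if np.random.random() < p_short:
            # --- short-time piece, u <= us
            u = us
            for _ in range(10000):
                if use_levy:
                    z = np.random.normal()
                    if z == 0.0:
                        continue
                    u = 0.25 / (z * z)
                else:
                    u = _ig_draw(mu, 0.25)
                if u <= us:
                    break
            # accept test against small-time alternating series
            # (factored terms: t_j = (j+1/2) exp(-j(j+1)/(2u)), t_0 = 1/2)
            v = np.random.random() * 0.5
            s = 0.0
            j = 0
            ok = False
            while j <= 200:
                tj = (j + 0.5) * math.exp(-j * (j + 1.0) / (2.0 * u))
                if j % 2 == 0:
                    s += tj
                    if v >= s:
                        break  # above an upper bound: reject
                else:
                    s -= tj
                    if v <= s:
                        ok = True
                        break  # below a lower bound: accept
                j += 1
            if ok:
                return u
        else:
            # --- long-time piece, u >= us, rate (pi^2 + nu^2)/2
            u = us - math.log(1.0 - np.random.random()) / lam_l
            # accept test against large-time alternating series
            # (factored terms: t_j = (2j+1) exp(-2j(j+1) pi^2 u), t_0 = 1)
            v = np.random.random()
            s = 0.0
            j = 0
            ok = False
            while j <= 200:
                tj = (2.0 * j + 1.0) * math.exp(-2.0 * j * (j + 1.0) * PI2 * u)
                if j % 2 == 0:
                    s += tj
                    if v >= s:
                        break
                else:
                    s -= tj
                    if v <= s:
                        ok = True
                        break
                j += 1
            if ok:
                return u


@njit(cache=True)
def _rs_uncond(a, nu, w):
    """Unconditional (decision time, boundary) draw by staged symmetric
    subproblems; boundary code 0 = lower, 1 = upper."""
    z = a * w
    t = 0.0
    for _ in range(1000):
        d = z if z < a - z else a - z
        if d < 1e-9 * a:
            break
        sep = 2.0 * d
        nus = nu * sep
        u = _sym_u_draw(nus)
        t += u * sep * sep
        pup = 1.0 / (1.0 + math.exp(-nus))
        if np.random.random() < pup:
            z += d
        else:
            z -= d
    return t, (1 if z >= 0.5 * a else 0)


@njit(cache=True)
def _rs_cond_lower(a, nu, w, bound, eps):
    """Boundary-conditional (lower) truncated RS draw, ITS escape hatch."""
    P = _p_lower(a, nu, w)
    if bound == INF:
        r = P
    else:
        r = _cdf_lower(bound, a, nu, w, eps)
    if r < 0.02 or (bound != INF and r < 0.01 * P):
        u = np.random.random() * r
        return _its_quantile(u, a, nu, w, bound, eps)
    for _ in range(100000):
        t, b = _rs_uncond(a, nu, w)
        if b == 0 and t <= bound:
            return t
    u = np.random.random() * r
    return _its_quantile(u, a, nu, w, bound, eps)


# ---------------------------------------------------------------------------
# adaptive rejection sampling on the log-time transform (numba hull)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seg_logmass(h, x, s, z0, z1):
    """log integral of exp(h + s (x' - x)) over [z0, z1]."""
    if z0 == -INF:
        return h + s * (z1 - x) - math.log(s)
    if z1 == INF:
        return h + s * (z0 - x) - math.log(-s)
    d = z1 - z0
    if d <= 0.0:
        return -1e308
    if abs(s) * d < 1e-10:
        return h + s * (0.5 * (z0 + z1) - x) + math.log(d)
    if s > 0.0:
        return h + s * (z1 - x) + math.log1p(-math.exp(-s * d)) - math.log(s)
    return h + s * (z0 - x) + math.log1p(-math.exp(s * d)) - math.log(-s)


@njit(cache=True)
def _hull_refresh(k, xs, hs, dhs, zs, logJ, cum, lo, hi):
    """Recompute intersections, segment masses and cumulative probabilities.

    Returns the log of the total envelope mass.
    """
    zs[0] = lo
    zs[k] = hi
    for i in range(1, k):
        s1 = dhs[i - 1]
        s2 = dhs[i]
        if s1 - s2 < 1e-13:
            z = 0.5 * (xs[i - 1] + xs[i])
        else:
            z = (hs[i] - hs[i - 1] + xs[i - 1] * s1 - xs[i] * s2) / (s1 - s2)
            if z < xs[i - 1]:
                z = xs[i - 1]
            elif z > xs[i]:
                z = xs[i]
        zs[i] = z
    mx = -1e308
    for i in range(k):
        logJ[i] = _seg_logmass(hs[i], xs[i], dhs[i], zs[i], zs[i + 1])
        if logJ[i] > mx:
            mx = logJ[i]
    tot = 0.0
    for i in range(k):
        tot += math.exp(logJ[i] - mx)
        cum[i] = tot
    for i in range(k):
        cum[i] /= tot
    return mx + math.log(tot)


@njit(cache=True)
def _invert_segment(u, z0, z1, s):
    if z0 == -INF:
        return z1 + math.log(u) / s
    if z1 == INF:
        return z0 + math.log1p(-u) / s
    d = z1 - z0
    if abs(s) * d < 1e-10:
        return z0 + u * d
    return z0 + math.log1p(u * math.expm1(s * d)) / s


@njit(cache=True)
def _lower_hull(k, xs, hs, x):
    if x < xs[0] or x > xs[k - 1]:
        return -1e308
    j = np.searchsorted(xs[:k], x)
    if j == 0:
        return hs[0]
    if j >= k:
        return hs[k - 1]
    x0 = xs[j - 1]
    x1 = xs[j]
    if x1 - x0 < 1e-300:
        return hs[j]
    return hs[j - 1] + (hs[j] - hs[j - 1]) * (x - x0) / (x1 - x0)


@njit(cache=True)
def _hull_try_insert(k, xs, hs, dhs, xn, hn, dn, lo, hi):
    """Insert a support point; returns (new_k, status).

    status: 0 inserted, 1 skipped (duplicate/cap/edge-slope), 2 log-concavity
    violation (slope ordering broken beyond tolerance).
    """
    if hn < -1e307 or not math.isfinite(hn) or not math.isfinite(dn):
        return k, 1
    if k >= HULL_CAP:
        return k, 1
    pos = np.searchsorted(xs[:k], xn)
    tol = 1e-12 * (1.0 + abs(xn))
    if pos < k and abs(xs[pos] - xn) < tol:
        return k, 1
    if pos > 0 and abs(xs[pos - 1] - xn) < tol:
        return k, 1
    # in the far-tail slope-cap region the ordering check is numerically
    # meaningless: skip rather than flag a violation
    capped = dn > 1e140 or (pos > 0 and dhs[pos - 1] > 1e140) \
        or (pos < k and dhs[pos] > 1e140)
    stol = 1e-7 * (1.0 + abs(dn))
    if pos > 0 and dn > dhs[pos - 1] + stol:
        return (k, 1) if capped else (k, 2)
    if pos < k and dn < dhs[pos] - stol:
        return (k, 1) if capped else (k, 2)
    if pos == 0 and lo == -INF and dn <= 1e-12:
        return k, 1
    if pos == k and hi == INF and dn >= -1e-12:
        return k, 1
    if pos > 0 and dn > dhs[pos - 1]:
        return k, 1  # within roundoff band: skip rather than break ordering
    if pos < k and dn < dhs[pos]:
        return k, 1
    for i in range(k, pos, -1):
        xs[i] = xs[i - 1]
        hs[i] = hs[i - 1]
        dhs[i] = dhs[i - 1]
    xs[pos] = xn
    hs[pos] = hn
    dhs[pos] = dn
    return k + 1, 0


@njit(cache=True)
def _ars_init(a, nus, wsn, wts, alpha_hi, xs, hs, dhs):
    """Build the initial 3-point hull by mode bracketing.

    Returns k (3) or -1 on failure.
    """
    # ladder search for a finite, high log-density point
    lo_a = math.log(1e-7 * a * a)
    hi_a = math.log(500.0 * a * a)
    if alpha_hi != INF and hi_a > alpha_hi:
        hi_a = alpha_hi
    best = -1e308
    am = 0.5 * (lo_a + hi_a)
    for i in range(48):
        al = lo_a + (hi_a - lo_a) * i / 47.0
        h, _ = _h_dh(al, a, nus, wsn, wts)
        if h > best:
            best = h
            am = al
    if best < -1e307:
        return -1
    # left point with clearly positive slope (a near-flat leftmost tangent
    # would give the unbounded left tail of the envelope enormous mass)
    xl = am
    hl, dl = _h_dh(xl, a, nus, wsn, wts)
    step = 0.5
    m = 0
    while dl <= 1.0 and m < 60:
        xl -= step
        step *= 2.0
        hl, dl = _h_dh(xl, a, nus, wsn, wts)
        m += 1
    if dl <= 0.0 or not math.isfinite(dl):
        return -1
    # right point with negative slope (or the truncation edge)
    xr = am + 0.5
    if alpha_hi != INF and xr >= alpha_hi:
        xr = alpha_hi
    hr, dr = _h_dh(xr, a, nus, wsn, wts)
    step = 0.5
    m = 0
    while dr >= -1.0 and m < 60:
        if alpha_hi != INF and xr >= alpha_hi:
            break
        xr += step
        step *= 2.0
        if alpha_hi != INF and xr > alpha_hi:
            xr = alpha_hi
        hr, dr = _h_dh(xr, a, nus, wsn, wts)
        m += 1
    if dr >= 0.0 and alpha_hi == INF:
        return -1
    if hr < -1e307:
        # stepped into an underflow region: bisect back towards the mode
        loa = am
        hia = xr
        for _ in range(80):
            mid = 0.5 * (loa + hia)
            hm, dm = _h_dh(mid, a, nus, wsn, wts)
            if hm < -1e307:
                hia = mid
            else:
                loa = mid
                xr = mid
                hr = hm
                dr = dm
                if dm < 0.0:
                    break
        if dr >= 0.0 and alpha_hi == INF:
            return -1
    # middle point
    xm = 0.5 * (xl + xr)
    hm, dm = _h_dh(xm, a, nus, wsn, wts)
    xs[0] = xl
    hs[0] = hl
    dhs[0] = dl
    if hm > -1e307 and xl < xm < xr and dl > dm > dr:
        xs[1] = xm
        hs[1] = hm
        dhs[1] = dm
        xs[2] = xr
        hs[2] = hr
        dhs[2] = dr
        return 3
    xs[1] = xr
    hs[1] = hr
    dhs[1] = dr
    return 2


@njit(cache=True)
def _ars_core(n, a, nus, wsn, wts, alpha_hi, keep_hull, max_reject,
              out_t, outcome, xs, hs, dhs, zs, logJ, cum):
    """Draw n decision times by ARS/P-ARS on the log-time transform.

    outcome[i]: 1 accepted by squeeze, 2 accepted after full evaluation.
    Returns (status, k): 0 ok, 1 init failure, 2 log-concavity violation,
    3 rejection-guard exceeded.
    """
    k = _ars_init(a, nus, wsn, wts, alpha_hi, xs, hs, dhs)
    if k < 0:
        return 1, 0
    _hull_refresh(k, xs, hs, dhs, zs, logJ, cum, -INF, alpha_hi)
    for i in range(n):
        if not keep_hull and i > 0:
            k = _ars_init(a, nus, wsn, wts, alpha_hi, xs, hs, dhs)
            if k < 0:
                return 1, 0
            _hull_refresh(k, xs, hs, dhs, zs, logJ, cum, -INF, alpha_hi)
        rejects = 0
        while True:
            u1 = np.random.random()
            seg = np.searchsorted(cum[:k], u1)
            if seg >= k:
                seg = k - 1
            base = cum[seg - 1] if seg > 0 else 0.0
            width = cum[seg] - base
            ustar = (u1 - base) / width if width > 0.0 else 0.5
            if ustar < 0.0:
                ustar = 0.0
            elif ustar > 1.0:
                ustar = 1.0
            x = _invert_segment(ustar, zs[seg], zs[seg + 1], dhs[seg])
            uk = hs[seg] + dhs[seg] * (x - xs[seg])
            lk = _lower_hull(k, xs, hs, x)
            u2 = np.random.random()
            logu = math.log(u2) if u2 > 0.0 else -745.0
            if logu <= lk - uk:
                out_t[i] = math.exp(x)
                outcome[i] = 1
                break
            hx, dx = _h_dh(x, a, nus, wsn, wts)
            k, st = _hull_try_insert(k, xs, hs, dhs, x, hx, dx, -INF, alpha_hi)
            if st == 2:
                return 2, k
            if st == 0:
                _hull_refresh(k, xs, hs, dhs, zs, logJ, cum, -INF, alpha_hi)
            if hx > -1e307 and logu <= hx - uk:
                out_t[i] = math.exp(x)
                outcome[i] = 2
                break
            rejects += 1
            if rejects > max_reject:
                return 3, k
    return 0, k


@njit(cache=True)
def ars_sample_wdm(n, a, nus, wsn, wts, bound, keep_hull, max_reject, seed):
    """Seeded entry point for WDM ARS/P-ARS; returns (times, outcome, status,
    hull arrays trimmed to k)."""
    np.random.seed(seed)
    alpha_hi = math.log(bound) if bound != INF else INF
    out_t = np.empty(n)
    outcome = np.zeros(n, dtype=np.uint8)
    xs = np.empty(HULL_CAP + 4)
    hs = np.empty(HULL_CAP + 4)
    dhs = np.empty(HULL_CAP + 4)
    zs = np.empty(HULL_CAP + 5)
    logJ = np.empty(HULL_CAP + 4)
    cum = np.empty(HULL_CAP + 4)
    status, k = _ars_core(n, a, nus, wsn, wts, alpha_hi, keep_hull,
                          max_reject, out_t, outcome, xs, hs, dhs, zs,
                          logJ, cum)
    return out_t, outcome, status, xs[:k].copy(), hs[:k].copy(), \
        dhs[:k].copy(), zs[:k + 1].copy(), logJ[:k].copy()


# ---------------------------------------------------------------------------
# one full parameter set: any method, conditional on the (canonical) lower
# boundary, optional trial-to-trial variability, optional truncation
# ---------------------------------------------------------------------------


@njit(cache=True)
def sample_set(method, n, a, mu_nu, s_nu, mu_w, s_w, nus, wsn, wts,
               bound, eps, seed, out_t):
    """Draw n boundary-conditional decision times for one parameter set.

    Parameters are already canonicalised to the lower boundary.  ``nus``,
    ``wsn``, ``wts`` are the flattened quadrature nodes of the trial-
    variability mixture (length 1 without variability).  Returns (status,
    mass) where mass is the conditional (truncated) probability of the
    requested boundary; status as in _ars_core.
    """
    np.random.seed(seed)
    mass = _mass_mix(a, nus, wsn, wts, bound, eps)
    if mass <= 0.0:
        return 4, mass
    if mass < 1e-3 and method != ARS:
        # degenerate conditional mass: exact fallback through the mixture CDF
        for i in range(n):
            u = np.random.random() * mass
            out_t[i] = _its_quantile_mix(u, a, nus, wsn, wts, bound, eps)
        return 0, mass
    has_var = (s_nu > 0.0) or (s_w > 0.0)
    if method == ARS:
        alpha_hi = math.log(bound) if bound != INF else INF
        outcome = np.zeros(n, dtype=np.uint8)
        xs = np.empty(HULL_CAP + 4)
        hs = np.empty(HULL_CAP + 4)
        dhs = np.empty(HULL_CAP + 4)
        zs = np.empty(HULL_CAP + 5)
        logJ = np.empty(HULL_CAP + 4)
        cum = np.empty(HULL_CAP + 4)
        status, _ = _ars_core(n, a, nus, wsn, wts, alpha_hi, True, 1000000,
                              out_t, outcome, xs, hs, dhs, zs, logJ, cum)
        if status != 0:
            # node mixtures with very wide starting-point windows can be
            # genuinely non-log-concave in a far-left shoulder; ARS is
            # invalid there, so fall back to exact inversion of the
            # mixture CDF (status 5 = sampled exactly via fallback)
            for i in range(n):
                u = np.random.random() * mass
                out_t[i] = _its_quantile_mix(u, a, nus, wsn, wts, bound, eps)
            return 5, mass
        return status, mass
    one_nu = np.empty(1)
    one_w = np.empty(1)
    one_wt = np.empty(1)
    one_wt[0] = 1.0
    xs = np.empty(HULL_CAP + 4)
    hs = np.empty(HULL_CAP + 4)
    dhs = np.empty(HULL_CAP + 4)
    zs = np.empty(HULL_CAP + 5)
    logJ = np.empty(HULL_CAP + 4)
    cum = np.empty(HULL_CAP + 4)
    alpha_hi = math.log(bound) if bound != INF else INF
    one_t = np.empty(1)
    one_o = np.zeros(1, dtype=np.uint8)
    for i in range(n):
        # two-step scheme: trial parameters, accepted with probability equal
        # to the (truncated) absorption mass at the requested boundary
        nu_t = mu_nu
        w_t = mu_w
        Ft = mass
        if has_var:
            ok = False
            for _ in range(1000000):
                nu_t = mu_nu + s_nu * np.random.normal() if s_nu > 0.0 else mu_nu
                w_t = mu_w + s_w * (np.random.random() - 0.5) if s_w > 0.0 else mu_w
                if bound == INF:
                    Ft = _p_lower(a, nu_t, w_t)
                else:
                    Ft = _cdf_lower(bound, a, nu_t, w_t, eps)
                if np.random.random() <= Ft:
                    ok = True
                    break
            if not ok:
                return 4, mass
        else:
            if bound == INF:
                Ft = _p_lower(a, nu_t, w_t)
            else:
                Ft = _cdf_lower(bound, a, nu_t, w_t, eps)
        if method == ITS:
            u = np.random.random() * Ft
            out_t[i] = _its_quantile(u, a, nu_t, w_t, bound, eps)
        elif method == RS:
            out_t[i] = _rs_cond_lower(a, nu_t, w_t, bound, eps)
        else:  # P-ARS: rebuild the hull for this trial, draw once
            one_nu[0] = nu_t
            one_w[0] = w_t
            status, _ = _ars_core(1, a, one_nu, one_w, one_wt, alpha_hi,
                                  True, 1000000, one_t, one_o, xs, hs, dhs,
                                  zs, logJ, cum)
            if status != 0:
                u = np.random.random() * Ft
                one_t[0] = _its_quantile(u, a, nu_t, w_t, bound, eps)
            out_t[i] = one_t[0]
    return 0, mass


# ---------------------------------------------------------------------------
# batch trial sampling at explicit per-trial parameters/boundaries (CLI path)
# ---------------------------------------------------------------------------


@njit(cache=True)
def sample_trials(method, a, nu_i, w_i, upper_i, bound, eps, seed, out_t):
    """One conditional draw per trial at given parameters and boundary."""
    np.random.seed(seed)
    n = nu_i.shape[0]
    one_nu = np.empty(1)
    one_w = np.empty(1)
    one_wt = np.empty(1)
    one_wt[0] = 1.0
    xs = np.empty(HULL_CAP + 4)
    hs = np.empty(HULL_CAP + 4)
    dhs = np.empty(HULL_CAP + 4)
    zs = np.empty(HULL_CAP + 5)
    logJ = np.empty(HULL_CAP + 4)
    cum = np.empty(HULL_CAP + 4)
    alpha_hi = math.log(bound) if bound != INF else INF
    one_t = np.empty(1)
    one_o = np.zeros(1, dtype=np.uint8)
    for i in range(n):
        nu_c = -nu_i[i] if upper_i[i] else nu_i[i]
        w_c = 1.0 - w_i[i] if upper_i[i] else w_i[i]
        if bound == INF:
            Ft = _p_lower(a, nu_c, w_c)
        else:
            Ft = _cdf_lower(bound, a, nu_c, w_c, eps)
        if Ft <= 0.0:
            out_t[i] = np.nan
            continue
        if method == ITS or Ft < 1e-3:
            u = np.random.random() * Ft
            out_t[i] = _its_quantile(u, a, nu_c, w_c, bound, eps)
        elif method == RS:
            out_t[i] = _rs_cond_lower(a, nu_c, w_c, bound, eps)
        else:  # ARS / P-ARS per-trial
            one_nu[0] = nu_c
            one_w[0] = w_c
            status, _ = _ars_core(1, a, one_nu, one_w, one_wt, alpha_hi,
                                  True, 1000000, one_t, one_o, xs, hs, dhs,
                                  zs, logJ, cum)
            if status != 0:
                u = np.random.random() * Ft
                one_t[0] = _its_quantile(u, a, nu_c, w_c, bound, eps)
            out_t[i] = one_t[0]
    return 0


# ---------------------------------------------------------------------------
# vectorised wrappers
# ---------------------------------------------------------------------------


@njit(cache=True)
def dens_vec(ts, a, nu, w, out):
    for i in range(ts.shape[0]):
        out[i] = _dens_lower(ts[i], a, nu, w)


@njit(cache=True)
def deriv_vec(ts, a, nu, w, out):
    for i in range(ts.shape[0]):
        out[i] = _dens_tderiv_lower(ts[i], a, nu, w)


@njit(cache=True)
def cdf_vec(ts, a, nu, w, eps, out):
    for i in range(ts.shape[0]):
        out[i] = _cdf_lower(ts[i], a, nu, w, eps)


@njit(cache=True)
def dens_mix_vec(ts, a, nus, wsn, wts, out):
    for i in range(ts.shape[0]):
        lg, _ = _log_gmix(ts[i], a, nus, wsn, wts)
        out[i] = math.exp(lg) if lg > -745.0 else 0.0


@njit(cache=True)
def deriv_mix_vec(ts, a, nus, wsn, wts, out):
    for i in range(ts.shape[0]):
        lg, r = _log_gmix(ts[i], a, nus, wsn, wts)
        out[i] = math.exp(lg) * r if lg > -745.0 else 0.0


@njit(cache=True)
def cdf_mix_vec(ts, a, nus, wsn, wts, eps, out):
    for i in range(ts.shape[0]):
        out[i] = _cdf_mix(ts[i], a, nus, wsn, wts, eps)


@njit(cache=True)
def h_dh_vec(alphas, a, nus, wsn, wts, out_h, out_dh):
    for i in range(alphas.shape[0]):
        h, dh = _h_dh(alphas[i], a, nus, wsn, wts)
        out_h[i] = h
        out_dh[i] = dh


@njit(cache=True)
def p_upper_vec(a_i, nu_i, w_i, out):
    for i in range(a_i.shape[0]):
        out[i] = _p_upper(a_i[i], nu_i[i], w_i[i])
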
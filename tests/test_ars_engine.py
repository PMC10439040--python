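"""Generic ARS engine: hull construction, envelope inversion, squeeze and
acceptance logic, adaptivity, and hull persistence."""

import math

import numpy as np
import pytest
from scipy import stats

from wienerfpt import (ArsError, LogConcavityError, ars_sample,
                       hull_from_json, hull_insert, hull_to_json, init_hull,
                       sample_envelope, squeeze_accept)
from wienerfpt.ars_engine import _build


def normal_target(x):
    return -0.5 * x * x - 0.5 * math.log(2 * math.pi), -x


def test_init_normal_hull_properties():
    st = init_hull(normal_target, start=0.0, k0=3)
    assert st.k >= 2
    assert np.all(np.diff(st.dhs) < 0)
    # envelope dominates the density, so its mass is >= 1
    assert st.log_mass >= 0.0
    assert np.all(st.zs[:-1] <= st.xs)
    assert np.all(st.xs <= st.zs[1:])


def test_init_nondifferentiable_kink_still_valid():
    """h(x) = -|x| is not differentiable at 0; with points straddling the
    kink the hull algebra still goes through at machine level."""

    def target(x):
        return -abs(x), (-1.0 if x > 0 else 1.0)

    st = init_hull(target, start=0.3)
    assert st.k >= 2
    # only two distinct slopes exist, so ties are inherent here
    assert np.all(np.diff(st.dhs) <= 0)
    xs = np.linspace(-3, 3, 101)
    for x in xs:
        assert st.upper(x) >= -abs(x) - 1e-12


def test_init_truncated_linear_target_closed_form_mass():
    """On (-1, 1) with h(x) = 2x all tangents coincide, and the envelope
    mass equals the closed form (e^2 - e^-2) / 2."""

    def target(x):
        return 2.0 * x, 2.0

    st = init_hull(target, domain=(-1.0, 1.0), start=0.0)
    assert math.exp(st.log_mass) == pytest.approx(
        (math.e ** 2 - math.e ** -2) / 2, rel=1e-12)


def test_init_convex_target_fails():
    def target(x):
        return x * x, 2 * x

    with pytest.raises(ArsError):
        init_hull(target, start=0.5)


def test_insert_idempotent_and_mass_monotone(rng):
    st = init_hull(normal_target, start=0.0)
    x0 = float(st.xs[0])
    h0, dh0 = normal_target(x0)
    again = hull_insert(st, x0, h0, dh0)
    assert again is st  # duplicate point: state unchanged
    masses = [st.log_mass]
    for _ in range(1000):
        x = float(rng.normal(scale=2.0))
        h, dh = normal_target(x)
        st = hull_insert(st, x, h, dh)
        masses.append(st.log_mass)
    d = np.diff(masses)
    assert np.all(d <= 1e-12)
    assert masses[-1] < masses[0]  # strictly tighter after 1000 inserts
    assert masses[-1] >= 0.0       # still dominates


def test_insert_tightens_both_hulls_pointwise():
    """Adding one support point to a 3-point hull lowers the upper hull and
    raises the lower hull everywhere."""
    st = init_hull(normal_target, start=0.0, k0=3)
    x_new = 0.5 * (st.xs[-2] + st.xs[-1])
    h, dh = normal_target(float(x_new))
    st2 = hull_insert(st, float(x_new), h, dh)
    assert st2.k == st.k + 1
    grid = np.linspace(st.xs[0] - 2, st.xs[-1] + 2, 1000)
    for x in grid:
        assert st2.upper(x) <= st.upper(x) + 1e-12
        assert st2.lower(x) >= st.lower(x) - 1e-12


def test_insert_slope_violation_raises():
    st = init_hull(normal_target, start=0.0)
    x = float(st.xs[0]) - 1.0
    with pytest.raises(LogConcavityError):
        hull_insert(st, x, normal_target(x)[0], -5.0)  # slope far too low


def test_envelope_dominance_random_hulls(rng):
    for _ in range(100):
        st = init_hull(normal_target, start=float(rng.uniform(-1, 1)))
        for _ in range(int(rng.integers(0, 8))):
            x = float(rng.normal(scale=1.5))
            st = hull_insert(st, x, *normal_target(x))
        xs = rng.uniform(-5, 5, size=1000)
        for x in xs:
            h = normal_target(float(x))[0]
            assert st.upper(float(x)) >= h - 1e-10
            assert st.lower(float(x)) <= h + 1e-10


def test_sample_envelope_single_segment_closed_form():
    """One linear segment with slope s on [z0, z1]: the inverse CDF is
    x = z0 + log(1 + u (e^{s(z1-z0)} - 1)) / s; checked against numerical
    inversion of the segment CDF."""
    s = 1.7
    z0, z1 = -1.0, 1.0
    st = _build([0.0], [0.3], [s], (z0, z1))
    for u in (0.1, 0.5, 0.9):
        x = sample_envelope(st, u)
        closed = z0 + math.log1p(u * math.expm1(s * (z1 - z0))) / s
        assert x == pytest.approx(closed, rel=1e-12)
        # numeric inversion oracle
        grid = np.linspace(z0, z1, 200001)
        cdf = np.cumsum(np.exp(s * (grid - z0)))
        cdf /= cdf[-1]
        num = grid[np.searchsorted(cdf, u)]
        assert x == pytest.approx(num, abs=1e-4)
    assert sample_envelope(st, 0.0) == pytest.approx(z0, abs=1e-12)


def test_envelope_draws_follow_piecewise_exponential(rng):
    """Histogram of envelope draws matches exp(u_k)/J (chi-square GOF)."""
    st = init_hull(normal_target, start=0.0)
    for x in (-1.5, -0.4, 0.7, 1.9):
        st = hull_insert(st, x, *normal_target(x))
    n = 100000
    draws = np.array([sample_envelope(st, u) for u in rng.random(n)])
    edges = np.quantile(draws, np.linspace(0, 1, 51))
    edges[0], edges[-1] = -np.inf, np.inf
    obs, _ = np.histogram(draws, bins=edges)

    def env_cdf(x):
        tot = 0.0
        for i in range(st.k):
            z1 = min(x, st.zs[i + 1])
            if z1 <= st.zs[i]:
                break
            from wienerfpt.ars_engine import _seg_logmass
            tot += math.exp(_seg_logmass(st.hs[i], st.xs[i], st.dhs[i],
                                         st.zs[i], z1) - st.log_mass)
        return tot

    exp_p = np.diff([0] + [env_cdf(e) for e in edges[1:-1]] + [1])
    chi2 = np.sum((obs - n * exp_p) ** 2 / (n * exp_p))
    p = stats.chi2.sf(chi2, df=49)
    assert p > 1e-3


def test_squeeze_at_support_point_and_outside():
    st = init_hull(normal_target, start=0.0)
    x1 = float(st.xs[1])
    # hulls touch at support points: squeeze accepts for any u <= 1
    dec = squeeze_accept(st, x1, 0.999999, normal_target)
    assert dec.outcome == "accept_squeeze"
    assert not dec.target_evaluated
    # outside [x_1, x_k] the lower hull is -inf: squeeze can never fire
    xo = float(st.xs[0]) - 1.0
    dec = squeeze_accept(st, xo, 1e-9, normal_target)
    assert dec.outcome != "accept_squeeze"
    assert dec.target_evaluated


def test_acceptance_rate_equals_mass_ratio(rng):
    """Long-run full-acceptance probability is J_true / J_envelope."""
    st = init_hull(normal_target, start=0.0, k0=3)
    for x in (-1.2, 1.4):
        st = hull_insert(st, x, *normal_target(x))
    n = 100000
    acc = 0
    for _ in range(n):
        x = sample_envelope(st, rng.random())
        u = rng.random()
        h = normal_target(x)[0]
        if math.log(u) <= h - st.upper(x):
            acc += 1
    p_true = math.exp(-st.log_mass)  # normal integrates to 1
    se = math.sqrt(p_true * (1 - p_true) / n)
    assert abs(acc / n - p_true) < 3 * se


def test_ars_sample_normal_moments(rng):
    x, hull = ars_sample(normal_target, 100000, rng=rng)
    assert abs(np.mean(x)) < 0.02
    assert 0.98 < np.var(x) < 1.02
    assert hull.k > 3  # hull grew during sampling


def test_ars_vs_pars_same_distribution(rng):
    a, _ = ars_sample(normal_target, 10000, rng=rng, keep_hull=True)
    b, _ = ars_sample(normal_target, 10000, rng=rng, keep_hull=False)
    assert stats.ks_2samp(a, b).pvalue > 1e-3


def test_ars_sample_truncated_domain(rng):
    x, _ = ars_sample(normal_target, 5000, domain=(-math.inf, 0.25),
                      rng=rng)
    assert np.max(x) <= 0.25
    # truncated-normal oracle
    ref = stats.truncnorm.rvs(-np.inf, 0.25, size=5000, random_state=rng)
    assert stats.ks_2samp(x, ref).pvalue > 1e-3


def test_squeeze_fraction_grows(rng):
    """Updates make full target evaluations increasingly rare: the fraction
    of squeeze acceptances is nondecreasing (within 2%) across blocks."""
    outcomes = []
    st = init_hull(normal_target, start=0.0)
    n = 10000
    for _ in range(n):
        while True:
            x = sample_envelope(st, rng.random())
            dec = squeeze_accept(st, x, rng.random(), normal_target)
            if dec.target_evaluated:
                st = hull_insert(st, x, dec.h, dec.dh)
            if dec.outcome != "reject":
                outcomes.append(dec.outcome == "accept_squeeze")
                break
    blocks = np.array(outcomes, dtype=float).reshape(10, n // 10).mean(axis=1)
    assert np.all(np.diff(blocks) >= -0.02)
    assert blocks[-1] > 0.95


def test_hull_json_roundtrip():
    st = init_hull(normal_target, start=0.0)
    st2 = hull_from_json(hull_to_json(st))
    np.testing.assert_array_equal(st.xs, st2.xs)
    np.testing.assert_array_equal(st.hs, st2.hs)
    np.testing.assert_array_equal(st.dhs, st2.dhs)
    np.testing.assert_array_equal(st.zs, st2.zs)
    np.testing.assert_array_equal(st.logJs, st2.logJs)
    assert st.domain == st2.domain
    # the deserialised hull is immediately usable
    assert sample_envelope(st2, 0.5) == sample_envelope(st, 0.5)
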
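"""Series density, derivative, CDF and absorption probability checks
against independent oracles (dual-series, quadrature, image-series CDF)."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from wienerfpt import (WDMParams, absorption_probability, fpt_cdf,
                       fpt_density, fpt_density_tderiv)
from conftest import random_params

# ---------------------------------------------------------------------------
# independent oracles (pure python / scipy; deliberately naive)
# ---------------------------------------------------------------------------


def dens_small_series(t, a, nu, w, K=120):
    """Small-time image series with a fixed large term count."""
    u = t / a ** 2
    s = 0.0
    for k in range(-K, K + 1):
        b = w + 2 * k
        s += b * math.exp(-(b * b) / (2 * u))
    f1 = s / math.sqrt(2 * math.pi * u ** 3)
    return math.exp(-nu * a * w - nu ** 2 * t / 2) * f1 / a ** 2


def dens_large_series(t, a, nu, w, K=800):
    """Large-time spectral series with a fixed large term count."""
    u = t / a ** 2
    s = sum(k * math.exp(-k * k * math.pi ** 2 * u / 2)
            * math.sin(k * math.pi * w) for k in range(1, K + 1))
    return math.exp(-nu * a * w - nu ** 2 * t / 2) * math.pi * s / a ** 2


def cdf_images(t, a, nu, w, K=60):
    """Phi-based image-series CDF for the lower boundary (independent of
    the package's spectral-series route)."""
    mu = -nu
    total = 0.0
    for k in range(-K, K + 1):
        b = a * (w + 2 * k)
        if b > 0:
            val = math.exp(special.log_ndtr((mu * t - b) / math.sqrt(t))) \
                + math.exp(2 * mu * b
                           + special.log_ndtr(-(b + mu * t) / math.sqrt(t)))
            sign = 1.0
        else:
            val = math.exp(special.log_ndtr((b - mu * t) / math.sqrt(t))) \
                + math.exp(2 * mu * b
                           + special.log_ndtr((b + mu * t) / math.sqrt(t)))
            sign = -1.0
        total += sign * math.exp(nu * (b - a * w)) * val
    return total


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------


def test_dual_series_oracle_pointwise():
    """Both classical series agree with the implementation at a point where
    they are comparably converged."""
    p = WDMParams(a=1.5, nu=1.0, w=0.5)
    t = 0.35
    g = fpt_density(t, p, "lower")
    assert g == pytest.approx(dens_small_series(t, 1.5, 1.0, 0.5), abs=2e-12)
    assert g == pytest.approx(dens_large_series(t, 1.5, 1.0, 0.5), abs=2e-12)


def test_dual_series_consistency_random(rng):
    for p in random_params(rng, 20):
        t = float(rng.uniform(0.05, 3.0))
        g = fpt_density(t, p, "lower")
        ref = dens_small_series(t, p.a, p.nu, p.w)
        assert g == pytest.approx(ref, abs=2e-12 + 1e-12 * abs(ref))


def test_normalization_by_quadrature():
    p = WDMParams(a=1.0, nu=0.3, w=0.6)
    tot = sum(integrate.quad(lambda t: fpt_density(t, p, b), 0, np.inf,
                             limit=200)[0] for b in ("upper", "lower"))
    assert tot == pytest.approx(1.0, abs=1e-8)


def test_density_integrates_to_absorption_probability():
    p = WDMParams(a=1.4, nu=-0.8, w=0.35)
    for b in ("upper", "lower"):
        mass = integrate.quad(lambda t: fpt_density(t, p, b), 0, np.inf,
                              limit=200)[0]
        assert mass == pytest.approx(absorption_probability(p, b), abs=1e-8)


def test_reflection_symmetry(rng):
    """g_upper(t; nu, a, w) = g_lower(t; -nu, a, 1-w), and likewise for the
    derivative, the CDF and the absorption probability."""
    for p in random_params(rng, 10):
        q = WDMParams(a=p.a, nu=-p.nu, w=1 - p.w)
        t = float(rng.uniform(0.05, 2.0))
        assert fpt_density(t, p, "upper") == pytest.approx(
            fpt_density(t, q, "lower"), rel=1e-12, abs=1e-300)
        assert fpt_density_tderiv(t, p, "upper") == pytest.approx(
            fpt_density_tderiv(t, q, "lower"), rel=1e-10, abs=1e-300)
        assert fpt_cdf(t, p, "upper") == pytest.approx(
            fpt_cdf(t, q, "lower"), rel=1e-10, abs=1e-14)
        assert absorption_probability(p, "upper") == pytest.approx(
            absorption_probability(q, "lower"), rel=1e-12)


def test_density_zero_for_nonpositive_time(base_params):
    assert fpt_density(0.0, base_params) == 0.0
    assert fpt_density(-1.0, base_params) == 0.0
    np.testing.assert_array_equal(
        fpt_density(np.array([-0.5, 0.0]), base_params), [0.0, 0.0])


def test_invalid_parameters_raise():
    with pytest.raises(ValueError, match="a must be > 0"):
        WDMParams(a=-1, nu=0, w=0.5)
    with pytest.raises(ValueError, match="w must lie"):
        WDMParams(a=1, nu=0, w=1.2)
    with pytest.raises(ValueError, match="finite"):
        WDMParams(a=1, nu=math.nan, w=0.5)
    with pytest.raises(ValueError, match="t0"):
        WDMParams(a=1, nu=0, w=0.5, t0=-0.1)
    with pytest.raises(ValueError, match="boundary"):
        fpt_density(0.5, WDMParams(1, 0, 0.5), "sideways")
    with pytest.raises(ValueError, match="eps"):
        fpt_density(0.5, WDMParams(1, 0, 0.5), "lower", eps=0.5)


# ---------------------------------------------------------------------------
# time derivative
# ---------------------------------------------------------------------------


def test_tderiv_matches_finite_difference(rng):
    checked = 0
    for p in random_params(rng, 100):
        t = float(rng.uniform(0.08, 2.5))
        g = fpt_density(t, p, "lower")
        if g < 1e-8:  # relative FD comparison meaningless in deep tails
            continue
        h = 1e-6 * t
        fd = (fpt_density(t + h, p, "lower")
              - fpt_density(t - h, p, "lower")) / (2 * h)
        an = fpt_density_tderiv(t, p, "lower")
        assert an == pytest.approx(fd, rel=1e-4, abs=1e-8)
        checked += 1
    assert checked > 60


def test_tderiv_sign_change_at_mode(base_params):
    ts = np.linspace(0.01, 3.0, 500)
    d = fpt_density_tderiv(ts, base_params, "lower")
    signs = np.sign(d)
    assert signs[0] > 0 and signs[-1] < 0
    assert np.sum(np.diff(signs) != 0) == 1  # unimodal: one sign change


# ---------------------------------------------------------------------------
# CDF
# ---------------------------------------------------------------------------


def test_cdf_at_zero_and_infinity(rng):
    for p in random_params(rng, 5):
        assert fpt_cdf(0.0, p, "lower") == 0.0
        up = fpt_cdf(1e8, p, "upper")
        lo = fpt_cdf(1e8, p, "lower")
        assert up + lo == pytest.approx(1.0, abs=1e-8)
        assert up == pytest.approx(absorption_probability(p, "upper"),
                                   abs=1e-10)


def test_cdf_matches_quadrature_oracle(rng):
    for p in random_params(rng, 30):
        t = float(rng.uniform(0.05, 2.0))
        ref = integrate.quad(lambda s: fpt_density(s, p, "lower"), 0, t,
                             limit=200)[0]
        assert fpt_cdf(t, p, "lower") == pytest.approx(ref, abs=1e-7)


def test_cdf_matches_image_series_oracle(rng):
    for p in random_params(rng, 20):
        t = float(rng.uniform(0.05, 2.0))
        assert fpt_cdf(t, p, "lower") == pytest.approx(
            cdf_images(t, p.a, p.nu, p.w), abs=1e-9)


def test_cdf_monotone_on_grid(rng):
    ts = np.linspace(1e-3, 5.0, 1000)
    for p in random_params(rng, 100):
        F = fpt_cdf(ts, p, "lower")
        # nondecreasing up to roundoff at the eps scale
        assert np.all(np.diff(F) >= -1e-12)
        assert F[0] >= 0.0
        assert F[-1] <= absorption_probability(p, "lower") + 1e-12


def test_cdf_extreme_drift_stable():
    """Image-series branch engages for large |nu a w| without overflow."""
    p = WDMParams(a=1.0, nu=-40.0, w=0.5)
    F = fpt_cdf(0.05, p, "lower")
    assert 0.0 <= F <= absorption_probability(p, "lower")
    ref = integrate.quad(lambda s: fpt_density(s, p, "lower"), 0, 0.05,
                         limit=200)[0]
    assert F == pytest.approx(ref, abs=1e-8)


# ---------------------------------------------------------------------------
# absorption probability
# ---------------------------------------------------------------------------


def test_absorption_zero_drift_limit_returns_w():
    for w in (0.2, 0.5, 0.8):
        assert absorption_probability(WDMParams(1.3, 0.0, w), "upper") == w
        assert absorption_probability(
            WDMParams(1.3, 1e-12, w), "upper") == pytest.approx(w, abs=1e-9)


def test_absorption_closed_form_value():
    p = WDMParams(a=1.0, nu=1.0, w=0.5)
    assert absorption_probability(p, "upper") == pytest.approx(
        1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)


def test_absorption_probabilities_sum_to_one(rng):
    for p in random_params(rng, 20):
        pu = absorption_probability(p, "upper")
        pl = absorption_probability(p, "lower")
        assert pu + pl == 1.0
        assert 0.0 <= pu <= 1.0


def test_absorption_matches_naive_formula(rng):
    """Stable expm1 form equals the textbook ratio where the latter is
    representable."""
    for p in random_params(rng, 20):
        x = 2 * p.nu * p.a
        naive = (1 - math.exp(x * p.w)) / (math.exp(-x * (1 - p.w))
                                           - math.exp(x * p.w))
        assert absorption_probability(p, "upper") == pytest.approx(
            naive, rel=1e-9)


def test_absorption_extreme_drift_no_overflow():
    assert absorption_probability(WDMParams(2.0, 400.0, 0.5), "upper") \
        == pytest.approx(1.0, abs=1e-12)
    small = absorption_probability(WDMParams(2.0, -400.0, 0.5), "upper")
    assert 0.0 <= small < 1e-300 or small == 0.0
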
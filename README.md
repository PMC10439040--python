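# wienerfpt

Exact random-number generation for the first-passage time (FPT)
distribution of the **two-boundary Wiener diffusion model** — the standard
evidence-accumulation model of binary decisions and response times in
cognitive psychology — together with the validation harness that certifies
the samplers.

## The model

A Wiener process with drift ν and unit diffusion coefficient starts at
z = a·w between absorbing boundaries 0 and a (boundary separation a > 0,
relative starting point 0 < w < 1).  The boundary reached first determines
the response; the first-passage time **T** plus a non-decision time t₀ is
the response time.  The *defective* FPT densities g_upper, g_lower
integrate to the absorption probabilities, with

P(upper) = (1 − e^{2νaw}) / (e^{−2νa(1−w)} − e^{2νaw}),  P(lower) = 1 − P(upper).

Neither the density nor the CDF has a closed form; both are infinite
series (a small-time image series and a large-time spectral series), which
this package evaluates to a requested absolute precision, switching to
whichever series needs fewer terms.

Optional trial-to-trial variability: ν ~ N(μ_ν, s_ν), w ~ U(μ_w ± s_w/2),
t₀ ~ U(min_t₀, min_t₀ + s_t₀).

## Sampling methods

* **ARS** — adaptive rejection sampling on the log-time transform
  A = (log T − α₀)/s_α, whose density is log-concave (numerically verified
  over wide parameter ranges by the built-in scan).  Piecewise-exponential
  envelope and squeeze hulls built from tangents/chords of the
  log-density; every full density evaluation tightens the hulls, so
  expensive evaluations become increasingly rare as draws accumulate.
  Under parameter variability the hull is built once on the
  quadrature-mixed density and reused.
* **P-ARS** — pseudo-adaptive variant: the hull is discarded after every
  accepted draw; under variability it joins the two-step scheme below and
  avoids the quadrature.
* **ITS** — inverse transform sampling: u ~ U(0, F_b(bound)) inverted by
  bisection on the CDF (no analytic quantile function exists).
* **RS** — rejection sampling in the Drugowitsch style: for w = ½, scaled
  time and boundary are independent; time is drawn with truncated
  inverse-Gaussian/Lévy (short-time) and shifted-exponential (long-time)
  proposals and exact alternating-series accept tests.  Other starting
  points reduce to nested symmetric subproblems by the strong Markov
  property.

All methods support truncation from above and sampling conditional on one
response; under variability, trial parameters proposed for a
single-response sample are accepted with probability equal to their
(truncated) absorption mass at that boundary, which makes the conditional
two-step scheme exact.

## Worked example

```python
import numpy as np
import wienerfpt as wf

p = wf.WDMParams(a=1.0, nu=0.3, w=0.6, t0=0.2)
wf.absorption_probability(p, "upper")   # 0.670061
wf.fpt_density(0.3, p, "upper")         # 0.767245 (decision time 0.3 s)
wf.fpt_cdf(0.3, p, "upper")             # 0.517642

res = wf.run_request(wf.SamplerRequest(N=10, a=1.0, v=0.3, w=0.6,
                                       t0=0.2, seed=1234))
res.q.round(4)
# array([0.3124, 0.2915, 0.8115, 0.5132, 0.4812, 0.281 , 0.3917, 0.3997,
#        0.858 , 0.5457])
list(res.response)
# ['upper', 'lower', 'lower', 'upper', 'lower', 'upper', 'lower',
#  'lower', 'lower', 'upper']
```

`q` are total response times (decision time + t₀ = 0.2 s, hence all
q > 0.2); about 67% of a long run lands at the upper boundary, matching
P(upper) above.  With trial variability:

```python
vp = wf.VariabilityParams(mu_nu=0.3, mu_w=0.6, s_nu=0.5,
                          min_t0=0.2, s_t0=0.1)
q, lab = wf.sample_with_variability("ars", 1.0, vp, "both", 100000,
                                    rng=np.random.default_rng(7))
q.mean(), (lab == "upper").mean()       # (0.4801, 0.6616)
```

The same surface is available from the shell:

```sh
wienerfpt sample --n 1000 --a 1 --v .3 --w .6 --t0 .2 --method its \
    --bound 0.5 --seed 7 --out samples.csv
wienerfpt validate-ks --method ars --bound 0.5 --n-sets 1000 \
    --n-per-set 1000 --seed 7 --out pvalues.csv
wienerfpt scan-logconcavity --n-sets 200 --seed 7
wienerfpt bench --reps 20 --max-n 1000 --seed 7 --out timings.csv
```

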
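# Methods

This note records the numerical methods, default parameters and design
choices behind `wienerfpt`, and what the built-in studies do and do not
establish.

## Density, derivative and CDF evaluation

The defective lower-boundary density is evaluated through the scaled form

    g_lower(t; ν, a, w) = a⁻² · exp(−νaw − ν²t/2) · f1(t/a²; w)

with two classical series for f1 in scaled time u = t/a²:

* small-time (image) series: (2πu³)^{−1/2} Σ_k (w+2k) exp(−(w+2k)²/(2u));
* large-time (spectral) series: π Σ_{k≥1} k exp(−k²π²u/2) sin(kπw).

The implementation switches at u ≈ 0.64, where the two series need a
comparable number of terms, and sums adaptively with conservative tail
bounds (Gaussian-tail for the image series, geometric for the spectral
series).  Everything is carried as (log value, d log/dt) pairs with the
dominant term factored out, so evaluations stay finite far into both
tails; the far-left slope of the log-density is capped at 10³⁰⁰ where the
true value exceeds double range.  Upper-boundary quantities use the
reflection (ν, w) → (−ν, 1−w).

The time derivative is computed analytically from the term-wise
differentiated series (verified against central finite differences at
1e−4 relative).

The defective CDF uses the term-wise integral of the spectral series,

    F_lower(t) = P_lower − (π/a²) e^{−νaw} Σ_k k sin(kπw) e^{−λ_k t}/λ_k,
    λ_k = (ν² + k²π²/a²)/2,

at *all* t.  This series converges exponentially for every t > 0 and
meets the absolute-precision contract everywhere: at very small t it
returns P minus a converged tail with absolute error near machine level,
which is what inverse transform sampling needs.  For |νaw| > 30 a
Φ-based image-series branch avoids the cancellation that the exponential
prefactor would otherwise cause.  An adaptive-quadrature route and an
independent Φ-based series serve as oracles in the test suite.  The
precision parameter (default 1e−12, bounded above by 1e−3) is an
**absolute** error bound; in practice the kernels deliver close to
machine precision except in extreme-drift corners where the error is of
order e^{|νaw|}·1e−16.

The absorption probability is evaluated as expm1(−2νaw)/expm1(−2νa),
algebraically identical to the textbook ratio, with an asymptotic branch
for 2νa < −650 and the exact limit P(upper) = w for |νa| < 1e−8.

## The ARS target and engine

ARS operates on A = (log T − α₀)/s_α.  The default is α₀ = 0, s_α = 1:
the transform family is affine in log t, so the choice affects only
numerical conditioning, never the back-transformed distribution (tested
by a two-sample KS across two specs).  The derivative of the transformed
log-density is s_α(1 + t·f′/f), taken from the analytic density ratio.

Engine choices, where the construction is genuinely open:

* **Initial points** (k₀ = 3): a coarse ladder over α locates a
  high-density point; geometric steps (± 0.5·2^m) bracket the mode.  On
  unbounded sides the search continues while the edge slope improves and
  is below 1 in magnitude — a near-flat edge tangent would give the
  infinite tail of the envelope enormous mass and stall the sampler.
* **Near-zero slopes** |h′| < 1e−10 in segment masses/inversion use the
  linear-in-x limit to avoid cancellation in (e^{sΔ}−1)/s.
* **Ties at segment boundaries** go to the right segment (half-open
  intervals).
* **Hull cap** at 200 support points; beyond it, accepted/rejected points
  are no longer inserted (pure rejection against the frozen envelope —
  the accept tests remain exact, so the distribution is unaffected).
* **Log-concavity violations** (support slopes not decreasing beyond a
  1e−7 relative tolerance) raise an error rather than being repaired: the
  hull algebra is invalid for such targets and the error is the
  diagnostic.  Slope comparisons inside the far-tail cap region are
  skipped instead, as ordering there is numerically meaningless.
* Segment masses live in log space and are combined by log-sum-exp.

The generic engine (`ars_engine`) is pure Python and takes any (h, h′)
callable; the high-throughput paths use a structurally identical
numba-compiled specialisation for the diffusion target.  The two are
cross-checked by distributional tests; the Python engine also provides
hull persistence (JSON) and warm starts.

## ITS and RS

ITS draws u ~ U(0, F_b(bound)) and bisects F_b(t) = u to 1e−10 absolute
in t, starting from a bracket grown geometrically from a²/(1+|ν|).

RS follows the cited three-regime construction.  For w = ½ the scaled
time u has unnormalised density e^{−(νa)²u/2} f1(u; ½), and f1 is an
alternating series with decreasing terms on each side of the switch point
u_s = 0.64 (image side valid for u ≤ 0.91, spectral side for u ≥ 0.028).
Short times use the first image term as envelope — a truncated inverse
Gaussian IG(μ = 1/(2|νa|), λ = ¼) proposal (Lévy when |νa| < 1e−4) —
long times the first spectral term, a shifted exponential with rate
(π² + ν²a²)/2.  The drift factor cancels from the accept test, which
compares v·(first term) against the alternating partial sums and is
therefore exact.  Piece probabilities are computed from log masses, so
extreme drift cannot overflow.  For w ≠ ½ the process exits nested
symmetric intervals [z−d, z+d], d = min(z, a−z); stage times are w = ½
subproblems with separation 2d, and the stage boundary is Bernoulli with
P(up) = logistic(2dν).  By the strong Markov property the accumulated
exit time and final boundary reproduce the original first passage
exactly.  Boundary-conditional draws resample whole trajectories;
when the conditional (truncated) mass r is small (r < 0.02, or
r < 0.01·P_b under truncation) the draw delegates to ITS on the truncated
CDF, which caps the resampling cost without changing the distribution.

## Variability and truncation

The mixed density/CDF integrate the core quantities over ν (Gauss–Hermite)
and w (Gauss–Legendre).  Library defaults are 32 × 32 nodes with an
order-doubling convergence check against the precision parameter; the
validation studies use GH 20 × GL 12 (accuracy study) and GH 32 × GL 12
(log-concavity scan), for which the mixed-CDF error against order
doubling is below 1e−7 over the study priors — four orders of magnitude
under the resolution of a KS statistic at n = 1,000.

Conditional sampling with variability uses the two-step scheme: propose
trial parameters from their laws, accept with probability equal to the
absorption mass at the requested boundary, then sample the FPT at fixed
parameters.  Under truncation the acceptance probability is the
*truncated* mass F_b(bound; θ): accepting with P_b(θ) and truncating
per-trial would renormalise within each parameter draw and bias the
mixture, whereas acceptance ∝ F_b(bound; θ) followed by per-θ truncated
sampling yields exactly the truncated mixture (the factors cancel).
With bound = ∞ this reduces to the plain absorption probability.

The truncation bound applies to the total time q = T + t₀.  With t₀
variability, trials are drawn at the loosest decision-time bound
(bound − min_t₀) and whole trials are redrawn when q exceeds the bound,
which composes truncation and t₀ variability exactly.  Unconditional
("both") two-step sampling draws the boundary per trial from the
closed-form absorption probability at that trial's parameters, samples
untruncated, and restarts overshooting trials for the same reason.

Parameter sets whose conditional truncated mass is below 1e−3 route the
time draws through inverse transform sampling on the mixture CDF
regardless of the requested method — exact and distribution-identical —
because naive resampling degenerates in that regime.  The validation
studies redraw parameter sets with mass below 1e−6.

One genuine limitation of the mixed-density ARS route surfaced in
testing: when the starting-point window is very wide relative to its mean
(e.g. w ~ U[0.0004, 0.15]), the mixture spans decades of time scales and
its log-time log-density develops a *real* non-log-concave shoulder at
very small t (of order 1e−6 to 1e−4 s, i.e. below the 0.01–5 s range the
log-concavity scan covers) with appreciable local density.  ARS is
invalid for such targets.  The diffusion sampler detects the hull
violation and falls back to exact inverse-CDF sampling on the mixture for
that parameter set; the fallback count is reported by the study results
(`n_fallback`), and a regression test pins the offending parameter set.
The generic engine still raises on violations, as the diagnostic.

## Validation studies and problem sizes

* **Log-concavity scan** (default 200 parameter sets × 500 grid points,
  0.01–5 s in 0.01 steps; priors a ~ U[0.5, 2], μ_ν ~ N(0,1),
  μ_w ~ Beta(8,8), s_ν ~ U[0,2], s_w ~ U[0,0.2], response Bernoulli(½)):
  second central differences of the analytically computed first
  derivative of log f_A (step 1e−3); flagged positives are recomputed
  with Richardson extrapolation at shrinking steps, up to three
  escalations.  The package-default runs report zero violations after
  retry.  This is numerical evidence, not a proof, of log-concavity.
* **KS accuracy study** (default 1,000 sets × 1,000 draws per cell;
  priors a ~ U[0.6, 2], μ_ν ~ N(0,1), μ_w ~ Beta(8,8), s_ν ~ U(0,1) and
  s_w ~ U(0,0.2) when on): one-sample KS against the truncated,
  renormalised conditional CDF, using the exact KS null distribution.
  Reported per cell: the share of p < .05 (≈ 5% for a correct sampler)
  and the uniformity KS p of the p-value sample.  The acceptance script
  runs all 32 cells with 1,000 sets each and 500 draws per set in cells
  with variability — the KS test is exact at any sample size, so the
  draw count affects only Monte Carlo smoothness, not calibration.
  Across 32 cells, about three significant uniformity tests arise by
  chance with probability ≈ .21 (exact binomial tail), which
  `binomial_meta_probability` computes.
* **Speed harness**: medians over a 16-condition × sample-size grid,
  reporting only — wall-clock comparisons are hardware-dependent and are
  deliberately not asserted.

Seeds: one root seed feeds a SeedSequence; each parameter set and cell
receives an independent substream.  Raw pre-retry violation counts in the
scan are therefore seed-dependent and not comparable across machines;
only the post-retry zero is a stable outcome.

## What the synthetic studies do not show

The generators emulate the study priors above, not empirical response
time data: no contaminant/outlier process, no fast guesses, no
parameter correlations across trials, and no collapsing boundaries.
Passing calibration certifies that the samplers draw from the intended
model distributions — it says nothing about whether that model fits any
particular dataset.

## Known limitations

* Log-concavity of the transformed density is supported numerically and
  by the single-boundary analogue, not proven; the engine's
  violation-detection error is the safeguard.
* The precision contract degrades to ~e^{|νaw|}·1e−16 absolute for
  extreme drift–geometry combinations (far outside the study priors).
* `n_threads` partitions work across independent substreams; the pooled
  sample is distribution-identical to a single stream but per-draw
  ordering is not preserved, and compiled kernels hold the interpreter
  lock, so threading currently adds little wall-clock benefit.
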
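# Methods

## Model

`stpfit` models short-term depression (STD) at a GABAergic synapse as a
two-variable presynaptic system: residual calcium `c` above baseline,
normalized so one stimulus raises it by Δ = 1, and the available fraction
`R` of the readily-releasable pool.  Calcium decays exponentially
(`τ_Ca`, ms); the pool refills at a calcium-dependent rate
`k(c) = k_min + Δk·c/(c + K_r)` (per ms) and release probability is
`P(c) = P_max·c/(c + K)`.  Both `P` and `k` are first-order (Hill-1)
saturating functions: `K` and `K_r` are half-saturation calcium levels,
`k(0) = k_min` is the resting recovery rate, and `P_max` is the asymptote
of the release function, fixed from variance–mean analysis rather than
fitted.

Event ordering at a pulse: calcium jumps by Δ; the observable release
probability `p_n = P(c_post)·R_pre` is recorded; the pool is depleted by
the released fraction `P·R`.  The observable corresponds to IPSC
amplitude divided by `N·q`.  Between pulses both variables have exact
updates: `c` decays exponentially, and `1 − R` decays by the integral of
`k` along the calcium trajectory,

    I_k = k_min·T + Δk·τ_Ca·ln[(c0 + K_r)/(c(T) + K_r)] ,

so train simulation involves no numerical integration.  An ODE
integration of the continuous system serves as an independent oracle in
the tests (agreement to 1e-6 relative on random draws), never as the
production path.

Assumptions and limits: a single homogeneous vesicle pool, no
facilitation term, no receptor desensitization or autoreceptor
modulation, mean-field depletion shared across sites.  One consequence
worth knowing: at interpulse intervals shorter than ~3·τ_Ca the residual
calcium elevates `P` at the second pulse faster than the pool deficit
recovers, so the model's paired-pulse recovery curve has a shallow dip
around 20–100 ms for the SH parameter set before rising monotonically to
1.  This is intrinsic to applying the release function to post-jump
calcium, and is visible in `simulate_recovery_curve`.

## Parameters

Shipped parameter sets (`SH.json`, `HC.json`) hold the fitted population
means for the septohippocampal and local hippocampal PV synapse models:

| parameter | units | SH | HC | meaning |
|---|---|---|---|---|
| τ_Ca | ms | 27.7 | 22.4 | calcium decay |
| P_max | – | 0.75 | 0.91 | max release probability (from VM analysis; fixed) |
| K | – | 0.69 | 0.68 | half-saturation calcium for release |
| k_min | /ms | 9.0e-4 | 1.2e-3 | resting recovery rate |
| Δk | /ms | 0.017 | 9.4e-3 | calcium-dependent recovery increment |
| K_r | – | 1.18 | 0.19 | half-saturation calcium for recovery |
| Δ | – | 1 | 1 | per-stimulus calcium increment (fixed) |

The qualitative mechanism separating the two: `K_r` is ~6-fold larger at
SH synapses, so their recovery rate keeps accelerating as calcium
accumulates at 20–50 Hz, while the HC recovery function is already
saturated and the HC synapse depresses to a deeper plateau.

## Quantal analysis

Per-pulse means and variances are taken across repeats (missing cells
are skipped; at least 3 valid repeats per point).  P1 from each
frequency enters the variance–mean fit as its own point; pulses 2–20 are
pooled across frequencies and binned with width 0.1× the grand-mean P1
amplitude, averaging the (mean, variance) pairs within a bin and
dropping bins with fewer than 2 points.  The parabola
`σ² = (1 + CV²)qI − I²/N` is linear in `a = (1+CV²)q` and `b = 1/N`, so
the fit is unweighted linear least squares; `CV = 0.3` is the fixed
intrasite quantal coefficient of variation.  Degenerate fits
(non-positive `q` or `N`, e.g. zero variance) raise a diagnostic error.
`p_max` is the largest fitted mean divided by `N·q`, clipped to [0, 1]
with a warning above 1.

Amplitude extraction measures the absolute peak of the
baseline-subtracted current in a window (default 2 ms plus a 1 ms rise
allowance, truncated at the next pulse).  The baseline is fitted over
1 ms before the pulse and extrapolated linearly across the window; with
a constant baseline the two are equivalent, but in 50 Hz trains the
extrapolation subtracts the decaying tail of summated earlier IPSCs and
keeps extraction errors near 0.5% instead of up to 10%.

IPSC kinetics: the 10–90% rise time uses interpolated threshold
crossings; the decay constant is a nonlinear least-squares
single-exponential fit starting two measured rise times after the peak.
The offset matters: for a biexponential event the residual rise
component biases a from-peak fit by ~2% (8.70 ms recovered for a
programmed 8.5 ms); two rise times out, the recovered constant is
8.51 ms, and for an instant-rise event the start collapses to the peak
so a pure exponential is recovered exactly.

The readily-releasable pool estimate back-extrapolates a line through
the last 5 points of the cumulative mean amplitude to pulse 0 and
divides by `q`.  Caveat: this method assumes replenishment is negligible
late in the train; with the SH model's strong calcium-dependent recovery
a 50 Hz train sustains substantial steady-state release and the estimate
undershoots the true `N` by ~40% (it is exact in the pure-depletion
limit, which is what the tests assert).

## Inference

The fit target is the 92-point vector of observed release probabilities:
4 frequencies × 20 pulses plus (P1, P2) at 6 recovery intervals, equally
weighted.  Free parameters are {τ_Ca, K, k_min, Δk, K_r}; `P_max` and Δ
are fixed.  MAP estimation runs Nelder–Mead on the logarithms of the
parameters (positivity for free) and minimizes log(MSE), which turns the
simplex's absolute function tolerance (1e-4) into a relative convergence
criterion on the misfit itself.  An iteration cap of 5000 raises a
non-convergence error carrying the best point, except when the misfit is
already below 1e-20 (a perfect fit).

The sampler is an adaptive random-walk Metropolis in log-parameter
space: Gaussian likelihood; error variance Gibbs-sampled each iteration
from its conjugate inverse-gamma conditional (weak prior: one
pseudo-observation at the starting MSE); flat prior on log-parameters
within ×/÷1000 of the start; proposal covariance re-estimated from the
chain history every 100 iterations after a 1000-iteration non-adaptive
phase, scaled by 2.38²/d; and a delayed-rejection second stage from a
5-fold narrower proposal, which raises the post-adaptation acceptance
rate from ~0.05 to 0.4–0.8 on this posterior's curved ridges.  Default
chain length 50,000 (a warning is issued outside 50,000–150,000); the
summary reports posterior means ± SDs after a 20% burn-in, the full
correlation matrix, and the `K_r`–`τ_Ca` correlation explicitly, because
those two parameters are strongly interdependent: the data constrain
roughly the amount of recovery accumulated per train, so a slower
calcium decay can be traded against a higher recovery half-saturation.
This ridge is the dominant identifiability limit — in synthetic recovery
experiments `K`, `k_min` and `Δk` come back within small bands while
`τ_Ca` and `K_r` wander together.

## Synthetic data

The generator emulates the experimental design: 20-pulse trains at
5/10/20/50 Hz repeated 7 times, and paired-pulse recovery protocols at
20/50/100/500/1000/3000 ms.  Per repeat and pulse, each of `N`
independent sites releases with probability `p_n` from the model; a
released quantum contributes `max(0, Normal(q, 0.3·q))`; Gaussian
recording noise (default SD 2 pA, a typical whole-cell baseline) is
added and the measured magnitude floored at zero.  Under this model the
amplitude mean is `N·p·q` and the variance `N·p·q²(1 + CV² − p)` —
exactly the structure the variance–mean parabola assumes, which the
tests verify at 10,000 repeats to 2%.  Defaults for `N` and `q` are the
SH population estimates (15 sites, 36.4 pA).  A `p_scale` factor
rescales the release profile to emulate cells whose peak release
probability differs from the population model's.

Raw traces are synthesized by placing peak-normalized biexponential
kernels (`exp(−t/τ_d) − exp(−t/τ_r)`) at the pulse times with linear
summation and baseline noise; the default kernel has an 8.5 ms decay and
a rise constant solved numerically so the 10–90% rise time is 1.0 ms, at
20 kHz sampling.

What the generator does not emulate: between-train carryover (every
sweep starts from rest, whereas real trains delivered in semi-random
order may interact), between-site heterogeneity of `q`, correlated or
non-Gaussian noise, optogenetic spike failures, and conduction jitter.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated generative model, not robustness to these real-data
features.

For parameter-recovery experiments the fit target is averaged over a
population of synthetic cells (12 for SH, 19 for HC, matching the group
sizes behind the reference fits), because fitting averaged release
probabilities is what the reference procedure did; a single cell's 7
repeats leave per-point noise (~0.04 SD) too large for the printed
posterior SDs to be recoverable bands.

## Numerical choices

* Times in ms, rates per ms, currents in pA magnitudes (polarity flag at
  trace ingestion); pulse and repeat indices are 1-based everywhere.
* Steady-state iteration: relative tolerance 1e-6 on successive `p_n`,
  cap 10,000 iterations.
* Fixed-seed reproducibility: every stochastic API takes a seed;
  `generate_experiment` spawns child streams deterministically, and CLI
  outputs embed the seed and a config hash.
* Problem sizes in the test suite (repeat counts from 7 to 10,000,
  20-seed Monte-Carlo averages, 50,000-sample chains) were chosen to
  keep each statistical assertion's sampling error several times smaller
  than the tolerance it checks.
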
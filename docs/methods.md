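# Methods

## Model

The population is partitioned into normal cells `n(t)` and persisters
`p(t)` (CFU/mL, treated as continuous). Within a phase of constant
antibiotic level the dynamics are linear, `dx/dt = A x` with
`A = [[K_n, b], [a, K_p]]` (row order normal, persister). `K_n` and `K_p`
are net per-capita rates — growth minus kill minus outgoing switch — and
`a`, `b` ≥ 0 are the switch rates into and out of dormancy. All internal
rates are natural-log units (1/h); slopes read off log10 plots convert by
ln 10. The observable is the total viable count `c = n + p`, because
plating cannot distinguish the two states.

Assumptions inherited from the linear model: no density dependence below
the carrying capacity, memoryless exponential switching, a single
persister phenotype, on/off antibiotic action only (no concentration
dependence or pharmacokinetic decay), and no demographic stochasticity —
eradication is defined by a threshold on the deterministic trajectory,
1 CFU/mL (0 log10) by default and configurable, since "reaching zero" is
not meaningful for a continuous state.

## Propagation

Phase propagation is the exact 2×2 matrix exponential, computed in closed
form: with `m = (K_n + K_p)/2` and `q = sqrt(ab + ((K_n − K_p)/2)²)`
(always real for `a, b ≥ 0`),
`exp(At) = e^{mt}[cosh(qt) I + sinh(qt)/q (A − mI)]`, switching to the
series limit `sinh(qt)/q → t` when `qt < 1e−12` so degenerate spectra are
handled without a general scaling-and-squaring code path. The tests
cross-check against `scipy.linalg.expm` and against the triangular
closed-form solution. Simulation over a regimen propagates segment by
segment, sampling on a uniform grid merged with every phase boundary so
per-cycle peaks and dips always appear in the output.

Saturation: cultures stop growing near 9 log10 CFU/mL. The exact
functional form of the saturation law used in the original analysis is
not available to us, so the simulator applies proportional clipping of
`(n, p)` at the ceiling (`cap_log10`, default 9.0) at sample resolution;
the clipped state propagates forward. This is an approximation — it
flattens the approach to the ceiling instead of bending it — but it only
matters for regimens that have already failed (growing peaks), where the
verdict, not the exact trajectory, is the output of interest.

## Cycle-map analysis

For a uniform regimen the per-period propagator is
`M = exp(A_off t_off) exp(A_on t_on)`. `M` is a product of entrywise
nonnegative matrices (exponentials of Metzler matrices), so its
eigenvalues are real; they are ordered by descending modulus with ties
broken by descending real part. Peaks at cycle starts follow
`c(t_2ℓ) = p1 λ1^ℓ + p2 λ2^ℓ`, with coefficients obtained by projecting
the initial state on the dual (left-eigenvector) basis and weighting each
right eigenvector by its component sum. When the eigenvalue gap is below
`1e−10` relative, the matrix is treated as defective: coefficients are
reported as unavailable and peaks are computed by explicit matrix powers,
which remain exact.

Design formulas: the critical ratio `x_c = −K_n,on/K_n,off` requires
`K_n,on < 0 < K_n,off`, and violations raise an error stating that the
design condition is inapplicable rather than returning a sign-less
number. The decline-rate optimum is the stationary point of
`k(x) = sqrt((K_n,on + K_n,off x)(K_p,on + K_p,off x))/(1 + x)`, which is
a linear equation in `x` with solution
`(2 R_n R_p − R_n − R_p)/(2 − R_n − R_p)`; the tests verify against a
bounded scalar maximisation that this linear form (and not, e.g., a
geometric-mean variant of the numerator, which is complex-valued for the
reference signs) is the argmax. The tolerant-persister approximation
`x_opt ≈ x_c/(x_c + 2)` is computed through the identical floating
expression wherever both appear so the identity is exact. Results
falling outside `(0, x_c)` carry a warning flag: the derivation assumes
an interior maximum of the decline-rate domain.

`k` is reported as the geometric mean of the two mode rates
`k_i = −ln λ_i/(t_on + t_off)` because it weights the early, steep part
of the decline, which drives time-to-eradication; the dominant
(slower) rate is exposed alongside it and as a surface over `(t_on,
t_off)` with the crease locus where the two mode rates coincide (the
straight line `x = (K_p,on − K_n,on)/(K_n,off − K_p,off)` when neither
phase switches normal cells into dormancy; located numerically as the
minimum eigenvalue gap otherwise, where it is a soft locus since the
surfaces no longer truly intersect).

Recommended durations: given an on-duration policy, `t_off = x_opt t_on`
is rounded to the nearest 0.5 h by default — lab schedules are kept to
half-hour resolution — with rounding configurable including "none".

## Estimation

Quick route: OLS of log10 counts vs time on an early window (default
0–3 h) of a time-growth and a time-kill experiment, via statsmodels;
slopes × ln 10 give `K_n,off` and `K_n,on`. A quadratic-term refit
provides a bend diagnostic (p < 0.05 flags curvature), because a window
reaching past the biphasic bend of a kill curve mixes the persister tail
into the normal-cell slope. Points within 0.05 log10 of the saturation
ceiling are dropped from growth windows.

Full fit: bounded nonlinear least squares (`scipy.optimize.least_squares`)
on log10-scale residuals — matching how colony-count data are plotted and
how their noise is closest to homoscedastic — unweighted, with parameters
shared across datasets. Free parameters are the eight phase rates plus
`log10 f0` and `log10 c0`; `f0` is optimised on the log scale because it
spans orders of magnitude near 1e−7, and its standard error is mapped
back by the delta method. Bounds encode the sign structure
(`K_on ≤ 0`, `K_n,off ≥ 0`, switch rates in [0, 10]). Censored
(below-detection) observations are excluded by default — they carry no
count — with an optional one-sided penalty mode that charges predictions
above the detection limit at censored times; the penalty mode removes the
small upward truncation bias that exclusion introduces near the limit.

Constraint profiles handle the identifiability problem: `c(t)` is a sum
of two exponential modes `q1 e^{ρ1 t} + q2 e^{ρ2 t}` with
`ρ1,2 = (K_n + K_p)/2 ± sqrt(ab + ((K_n−K_p)/2)²)`, so a single curve
cannot pin down all four rates of a phase. The built-in `standard`
profile fixes `a_on = a_off = 0` (switching into dormancy is negligible
during brief stress and early exponential growth) and `b_on = 0`
(persisters stay dormant under antibiotic); `standard_tied` additionally
ties `K_p,off = −b_off` (off-antibiotic, dormant cells neither grow nor
die — their only loss is resuscitation); `free` applies none and, on a
single constant-dose curve, demonstrably yields a rank-deficient Jacobian
or inflated standard errors, which the fit reports. Multi-start (default
10 seeded jittered starts, `f0` log-uniform in [1e−8, 1e−3]) guards
against local minima; standard errors come from the SVD-pseudoinverse
covariance at the optimum.

## Synthetic data

The generator emulates the package's reference experimental designs:
constant-dose kill curves, growth curves, uniform pulse trains, and
seeded ±25% perturbations of the nominal 3 h/2 h schedule (the exact
perturbed durations of the reference experiment are not published, so the
preset defines its own documented jitter). The mean structure is exactly
the simulator output; noise is normal on log10 counts (default σ = 0.2,
the visual scatter scale of log-plotted CFU data, since no empirical
noise model or replicate count is published), optionally followed by a
Poisson plating stage at an effective plated volume for realistic
low-count behaviour; observations below the detection limit (default
1 CFU/mL) are flagged censored and recorded at the limit, never as zero.
Everything is deterministic given a seed.

What passing tests on these data do not show: real kill curves carry
serial-dilution error chains, plate-count overdispersion, between-day
batch effects, and model misspecification (multiple persister phenotypes,
concentration-dependent kill), none of which are simulated. Recovery
rates measured here are therefore an upper bound on what the same designs
achieve in the lab.

Reference problem sizes used in the validation suite: hourly sampling
over 13 h (constant dose) and 15 h (three 3 h/2 h cycles), three
replicates, σ = 0.2 — the cadence and span of a realistic bench
experiment; parameter-recovery checks run 50 seeded repetitions under the
`standard_tied` profile, whose constraints the generating parameters
satisfy.

## Numerical conventions

- Eigenvalue ordering: descending modulus, ties by descending real part.
- Degenerate-spectrum threshold `1e−12` (propagator series switch),
  defective-cycle threshold `1e−10` relative (coefficient fallback).
- Eradication-time crossings are refined by linear interpolation of
  log10 c between bracketing samples; the time reported is the first
  crossing after which the trajectory stays below threshold.
- Exact propagation of a nonnegative state stays nonnegative (Metzler
  structure); floating-point undershoot is clipped at zero.
- Report keys carry unit suffixes (`_per_h`, `_h`, `_log10`) because
  ln-vs-log10 confusion is the single most error-prone convention in this
  problem.

## Known limitations

- The saturation cap is a proportional clip, not a mechanistic logistic
  term; trajectories at the ceiling are qualitative.
- The closed-form decline rate `k(x)` ignores switching into dormancy
  during either phase (`a > 0` makes it approximate); the cycle-matrix
  eigenvalue route is exact and is what the surface and verdict functions
  use.
- Dip-to-dip analysis (troughs at the end of on-phases) is available only
  through simulated trajectories, not in closed form; peaks and dips
  share the same multipliers, so the verdicts coincide.
- No Bayesian uncertainty, no mixed effects across replicates, no raw
  colony-count/dilution bookkeeping.
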
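# Methods

## Model class

The package treats coupled stochastic systems of the form

```
dv = (1/eps1) [ F(v, W) + u(t/eps2) ] dt + (1/sqrt(eps1)) Sigma dB(t)
dW = G(v, W) dt
```

where `v` in R^n is the fast membrane-potential field of a linear rate
network, `W` in R^{n x n} the slow connectivity, `u` a tau-periodic input,
and `B` an n-dimensional Brownian motion.  Three plasticity rules are
implemented:

* **Hebbian**: `F = (W - L) v`, `G = -kappa W + v (x) v` with `L = l Id`.
* **Trace**: activity, synapses and the learning window all carry the same
  exponential memory `g_beta(t) = beta e^{-beta t} H(t)`; the rule is
  simulated in its augmented memoryless form with an auxiliary trace `z`
  integrating `v` at rate `beta` (the Hebbian rule is the `beta = inf`
  limit).
* **STDP**: an additive asymmetric window `a+ g_gamma(-t) - a- g_gamma(t)`
  applied to linear activities, i.e.
  `G = -kappa W + a+ v (x) (v*g_gamma) - a- (v*g_gamma) (x) v`, again in the
  augmented form; the noise matrix `Sigma` may be non-diagonal (spatially
  correlated noise).

Two small parameters govern the analysis: the time-scale separation
`eps = (eps1, eps2)` and their asymptotic ratio `mu = eps1/eps2` between the
internal activity time-scale and the input time-scale.  In the joint limit
`|eps| -> 0` at fixed `mu`, the connectivity follows a deterministic averaged
ODE

```
dW/dt = -kappa W  +  correlation(W)  +  noise(W)
```

whose drift averages `G` over the periodic quasi-stationary law of the
frozen fast variable: a Gaussian of constant covariance `Q` (the Lyapunov
solution of the frozen Ornstein-Uhlenbeck fluctuations) carried along the
`tau/mu`-periodic attractor `vbar` of the frozen fast system driven by
`u(mu t)`.  Because `G` is quadratic in `v`, the input and noise
contributions are additive, with no cross term.

## Numerical conventions

**Fourier-domain periodic filtering.** All periodic computations (attractor,
correlation terms, filtered correlation families, the symmetric/antisymmetric
STDP decomposition) are done on Fourier coefficients: harmonic `j` of a
tau-periodic signal lives at frequency `j/tau` and is multiplied by
closed-form transfer functions, then period averages use Parseval.  This is
exact for periodic signals — no kernel truncation, no transient
contamination.  Sampled time-domain kernels exist only for L1 norms,
plotting, and oracle cross-checks (there, discrete convolutions carry
trapezoid end-corrections because the exponential windows jump at 0).

**One frequency frame.**  Harmonics are evaluated at the fast-frame
frequencies `omega_j = mu j / tau` with the unscaled rates `l`, `beta`,
`gamma`; this is identical to filtering on the input frame with rates
divided by `mu`, and it is the frame in which the damped kernels
`v`, `w` (below) are written.

**Kernels.**  The iterated exponential windows are gamma densities
`rate^{k+1} t^k e^{-rate t}/k!` (unit L1 norm).  The trace rule's
second-order filter has discriminant `Delta = sqrt(1 - 4l/beta)`: hyperbolic
kernels for `4l <= beta` (L1 norm 1), damped oscillations for `4l > beta`
(L1 norm `coth(pi/(2|Delta|)) > 1`, computed from the closed form).  The
`k`-fold self-convolution `v_k` uses the Bessel closed form
(`I_{k-1/2}` on the hyperbolic branch via the exponentially scaled `ive` to
avoid overflow, `J_{k-1/2}` on the oscillatory branch), with an FFT
self-convolution fallback.  `Delta = 0` (`beta = 4l`) routes to the
confluent limit kernel `(l beta/mu^2) t e^{-beta t/(2 mu)}` inside a band
`|Delta| < 1e-8`.  No closed form is known for `||w||_1` on the oscillatory
branch; it is computed numerically.

**Correlation families.**  `C_{k,q}` (Hebbian), `Ctilde_{k,q}` (trace,
`||v||_1`-normalized) and `D_{k,q}` (STDP, `(|a+|+|a-|)`-normalized) are the
input correlations filtered by iterated kernels; each has spectral norm at
most 1 (asserted at build time).  The weakly connected series for the
correlation term converges for spectral radius of `W` below `l` (Hebbian /
STDP) or `l/||v||_1` (trace); the truncation tail is reported as a
geometric bound.  The default truncation `K = 4` matches the order used in
the reference experiments; expansion work uses the orders it needs.

**Lyapunov solvers.**  The stationary covariance solves
`A Q + Q A' = D` with `A = L - W` the stable part; a dense Bartels–Stewart
solve (scipy) is the default and the geometric series
`Q = sum_k W^k D (2L - W')^{-(k+1)}` (valid when
`|||W||| |||(2L-W)^{-1}||| < 1`) is kept as an independent backend, each
serving as the other's oracle in tests.

**Averaged integration.**  Adaptive RK45 on the flattened connectivity, with
an invariant-set guard (`spectral radius < l`) inside the right-hand side.

**Equilibrium.**  Damped Picard iteration `W <- (1-w) W + (w/kappa) F(W)`
with `w = 0.8`; the contraction certificate guarantees plain iteration, the
damping widens the practical basin.  Convergence is declared at relative
residual `1e-12` (absolute floor at the same value).

**Stochastic integration.**  Euler–Maruyama in fast time with the slow
update scaled by `eps1` and the input driven at phase `mu s`;
`eps1 = eps2 = eps` by default.  The auxiliary trace/STDP variable carries
no noise of its own (the formal auxiliary noise `sigma_z` that makes the
augmented system non-degenerate is taken in its `sigma_z -> 0` limit).
Additive noise in `v` makes the scheme strong order 1.0; `dt = 0.01` on the
fast scale is the default.  Blow-up (entries above `1e8`) raises with a
pointer at the well-posedness report.

## Weak-connectivity expansions

The weak connectivity index

```
p~ = u_m^2/(kappa l^3) + sigma^2/(2 kappa l^2)                (Hebbian, trace)
p~ = (|a+|+|a-|)/(kappa l^3) (s^2/2 (1/l + 1/gamma) + u_m^2)  (STDP)
```

controls the equilibrium size (`W* = O(p~ l)`); `lambda` is the noise/input
ratio inside `p~`.  Orders 1 and 2 of the equilibrium expansion are
assembled from the recursion that cancels the fixed-point equation order by
order; order 3 and beyond are not implemented (their complexity grows
combinatorially and the order-2 truncation already reaches the round-off
floor at the reference parameter scales).  Two derivation-level choices are
worth recording:

* the trace order-2 noise term carries coefficient `lambda^2 Id` (the noise
  series does not involve the damped kernel), which the recursion gives
  directly; a display of the closed formula elsewhere carries an extra
  `||v||_1^2` on that term, which is inconsistent with the recursion and is
  not used;
* the STDP zeroth-order noise normalization `d` is fixed to
  `s^2 = |||Sigma Sigma'|||`, the unique choice making the noise series
  term-by-term consistent; the first-order noise term
  `lambda (alpha+ - alpha-) Sigma Sigma'/d` then vanishes exactly for
  balanced amplitudes, which is why balanced STDP learning is insensitive to
  noise at first order.

The STDP noise contribution to the averaged field is
`a+ Q12' - a- Q12` with `Q12 = gamma Q11 (L + gamma - W')^{-1}`, i.e. the
amplitude-weighted combination consistent with the correlation term's
symmetrization (not the bare `Q12`).

## Well-posedness

The admissibility inequalities (one per rule) are scanned over
`p in ]0,1[` on a 10^4-point grid with bisection refinement of interval
endpoints — a single code path for the three rules rather than closed-form
cubic roots.  Uniqueness/global-stability thresholds: `p <= 1/3` (Hebbian,
STDP) and `p <= 1/(2||v||_1^3 + 1)` (trace).  "Strictly inside" uses a
`1e-9 l` spectral margin.  The one-neuron truncation example exposes
`eta = 2 sigma^2/(kappa l^2)` and the closed-form equilibria
`w± = l/2 (1 ± sqrt(1-eta))` (stable/unstable; none for `eta > 1`).

## Synthetic inputs and what the experiments show

All inputs are synthetic and periodic: sinusoids with optional frozen random
spatial profiles, piecewise-constant pattern sequences (optionally
orthonormalized, hard switches by default as the reference protocols imply;
a raised-cosine `smooth_frac` exists), and circular one-hot sequences.
Pattern amplitudes are unit-norm by default — the reference protocols do not
pin `u_m`, and this choice sets the scale of `p~` and of the expansion
errors.  Default sampling is `M = 4096` points per period, enough to resolve
the sharpest kernels used at desk scale.

The experiments run at deliberately small problem sizes (n = 3 and 8,
slow horizons of a few multiples of `1/kappa`, 5 Brownian seeds) chosen so
the whole suite executes in minutes on one core while leaving each
qualitative claim (deviation decreasing in `eps`, expansion error of order
`1e-4` percent, antisymmetric STDP equilibrium) clearly resolved above its
numerical floor.  The error-decay exponent check scales `u_m` and `sigma`
jointly so `p~` quarters while `lambda` stays fixed; it runs at `p~ ~ 0.06`
where the order-3 remainder is far above double-precision round-off.

What passing does **not** show: the generators emulate the idealized study
conditions — linear rate dynamics, identical neurons, perfectly periodic
inputs, additive Gaussian noise.  Spiking or otherwise nonlinear activity,
heterogeneous time constants, non-periodic (ergodic) inputs, and
multiplicative plasticity updates are outside the model class, and
conclusions about them cannot be drawn from these tests.

## Known limitations

* Expansion orders >= 3 are not available.
* The extreme regimes `mu = 0` and `mu = infinity` are represented by
  evaluating the matching-regime machinery at very small/large `mu`, not by
  dedicated sequential-limit code paths.
* `sup_deviation` compares trajectories on their shared time range by
  linear interpolation; strongly under-sampled trajectories will alias.
* The admissibility scan reports open intervals to bisection accuracy
  (~1e-15 in `p`), not exact algebraic endpoints.
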
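# Methods

## Model

The package targets state-space models of biochemical reaction networks in
which some reaction hazards depend on the *past* of the process through a
distributed delay. The latent dynamics follow the chemical Langevin
equation (CLE) of the network, with the reactions split into a delayed set
(stoichiometry `S_d`, hazards `h_d`) and a plain set (`S_p`, `h_p`):

    dX(t) = [ g(X(t)) + f(u(t)) ] dt + sqrt( l(X(t)) + q(u(t)) ) dB(t),

where `g = S_p h_p(X)`, `f = S_d h_d(u)`, `l = S_p diag(h_p) S_p'`,
`q = S_d diag(h_d) S_d'` and

    u(t) = ∫_{t-τ_m}^{t} X(s) K(t-s) ds

is the kernel-weighted past with a delay density `K` truncated at a maximum
delay `τ_m`. Observations are linear-Gaussian: an integrated light signal
`Y_t = κ ∫_{t-Δ}^{t} X(s) ds + ε_t`, `ε_t ~ N(0, σ_ε²)`, with exposure
`Δ = 0.5 h`.

The shipped application is a one-species transcriptional–translational
negative feedback loop (TTFL) for circadian mRNA (e.g. *Cry*1): delayed
transcription `∅ → X` with Hill-repressed rate
`ν(u) = R_max / (1 + (u/K_pc)^n)`, and degradation `X → ∅` at rate `μX`.
The delay kernel is a Gamma density parameterized by its mean `E[τ]` and
standard deviation `SD[τ]`, truncated at `τ_m = 30 h` and renormalized.
Renormalization after truncation is a deliberate choice — it keeps `K` a
proper density on `[0, τ_m]`; with the default parameters the truncated
mass is ~1e-5, so the choice is numerically inconsequential. Kernel
weights live on the same lattice as the filter window, by direct density
evaluation at the lattice points (no quadrature weighting); the degenerate
no-delay case is represented as a point mass at lag zero, making the
non-delayed model a special case of the delayed machinery.

## Filter

The linear noise approximation (LNA) linearizes the hazards about the
mean path, giving Gaussian transition densities. For delayed systems the
current state alone is not Markov, so the filter tracks a joint Gaussian
over the whole window `[t - τ_m, t]` on a lattice of `m + 1 = τ_m/δt + 1`
points: a mean vector and a dense `(m+1) × (m+1)` covariance (per
species).

One Euler step of size `δt` linearizes `g`, `l` about the current mean and
`f`, `q` about the mean delayed integral. The new lattice point is an
affine function of the window vector,

    X⁺ ≈ ρ⁺ + (1 + J_g δt)(X_t - ρ_t) + J_f δt Σ_j K_j (X_{t-jδt} - ρ_{t-jδt}) + η,

with `η ~ N(0, [l(ρ_t) + q(u_t)] δt)`, so its cross-covariances against
every retained lag and its marginal variance follow in closed form; the
oldest point is dropped and the window shifts. The covariance recursion
uses the one-step transition form `P ← T P T' + Q`, which agrees with the
covariance ODE to first order in `δt` and has the property that
linear-hazard models become *exactly* discrete-time linear-Gaussian
systems — the test suite exploits this by checking the filter against
textbook Kalman recursions on the stacked window vector to near machine
precision.

Each observation conditions the entire window through a Kalman step whose
gain is the cross-covariance between the window and the current
integrated-light functional, divided by the innovation variance: every
past lattice point within `τ_m` is revised. The marginal likelihood
accumulates the Gaussian innovation densities `N(y; Fρ, F P F' + σ_ε²)`.
The moments a lattice point carries when it finally leaves the window form
a *partial smoothing* density — conditioned on all observations received
while the point was inside the window.

The integrated-light row `F` discretizes `κ ∫_{t-Δ}^{t} X ds` with
trapezoid weights over the trailing `Δ/δt + 1` lattice points (a right
Riemann sum is selectable). Observation time stamps mark the END of each
exposure bin.

Numerical choices: covariance blocks are assembled symmetric by
construction and the rank-one update is exactly symmetric, so no
per-step re-symmetrization is needed; new marginal variances and diagonal
entries are floored at zero; a full eigenvalue projection (floor 1e-10)
is applied only if a diagonal entry goes materially negative. Hazards
evaluated at a (possibly negative) mean are evaluated at the clipped
argument and floored at zero with a debug-level log entry. The innovation
variance must exceed `σ_ε² × 1e-12`, otherwise the filter raises.

A note on the scale parameter `κ`: rescaling the state to `κX` (moving
`κ` from the observation to the state equation) is an exact linear
transformation of a Gaussian model, and the LNA commutes with linear
maps, so the marginal likelihood is unchanged. The filter therefore
always works in molecule coordinates.

### Initialization window

Over `[0, τ_m]` the delayed integral would depend on unobserved pre-data
history, so the dynamics there are modelled as a linear birth–death
process: constant transcription `ν₀` (`init_rate`) and degradation `μ₀` —
a step-function transcription model whose parameters are inferred
alongside the rest. The state at time zero has prior mean
`x̄₀ = y₁ / (κΔ)` (the first observation de-integrated) and variance
`β x̄₀` by default, or `var_x0` when that parameter is supplied
(`var_x0` is what the sampler infers; `β` is a convenience for the
filtering API). The window is grown one lattice point at a time while the
head observations are assimilated with the same window update, so their
likelihood contribution and the full joint covariance at `τ_m` are exact
within the linear model.

## Simulator

Ground truth comes from a delayed stochastic simulation algorithm: the
trajectory is stored on a 0.01 h grid; at the start of every grid step the
delayed hazard is refreshed from the kernel-weighted stored past and then
held constant, while non-delayed hazards are refreshed after every
reaction event and exponential clocks run within the step (each selected
reaction fires immediately). Linear sub-models (pure death, constant
birth) are therefore simulated exactly, and the approximation error for
delayed hazards is confined to 0.01 h hazard staleness.

The measurement emulator mimics a bioluminescence camera: counts are
divided by their overall mean level, summed within 0.5 h exposure bins,
and corrupted with i.i.d. Gaussian noise of standard deviation
`sd(noise-free binned signal) / SNR`. SNR is defined through the signal's
standard deviation by default (a mean-based definition is selectable);
the emulator records the realized `κ = 1/(0.01 × mean level)` and `σ_ε`
so that filters can be run at the exact truth. A linear intensity decay
(luciferin consumption, ~30% over five days) can be applied and removed
by division.

Default study conditions (the package's reference simulation truth):
`R_max = 100 /h`, `K_pc = 100` molecules, `n = 5`, `μ = μ₀ = 0.58 /h`,
`E[τ] = 9.67 h`, `SD[τ] = 3.56 h`, `τ_m = 30 h`, exposure 0.5 h, SNR ∈
{20, 100}, horizon 5 days. The delay moments and degradation rate are the
posterior point estimates reported for real SCN *Cry1-luc* data, and the
Hill coefficient 5 is the reference cooperativity of the simulation
studies in this literature; `R_max = K_pc = 100` sets a copy-number scale
of ~100 molecules where the LNA is accurate and places the deterministic
fixed point (~95.7 molecules) on the steep flank of the Hill curve, which
is required for oscillation. Under these conditions the stochastic model
oscillates with a dominant period of ~24 h. Replicates start from a
constant history at the fixed point and discard a 72 h burn-in, long
enough for intrinsic noise to establish the limit-cycle oscillation.

What the generator does *not* emulate: reporter-protein kinetics (light
reads the mRNA surrogate directly), spatial coupling between cells,
photon shot noise (measurement error is homoscedastic Gaussian), and slow
instrument drift other than the optional linear decay. Passing
calibration tests on these data therefore demonstrates the filter's
correctness under the model's own assumptions, not robustness to these
real-data complications.

## Inference

Priors (log scale unless noted): generic rates and scales `N(0, 10²)`;
Hill coefficient `log n ~ N(log 1.5, 5²)`; degradation rates
`log μ, log μ₀ ~ N(log 0.58, 0.5²)` (reporter half-life information);
`log κ`, `log var_x0 ~ N(0, 20²)`; delay mean `~ U(0, 23) h` and SD
`~ U(0, 20) h` on the natural scale; `log σ_ε` normal with unit SD about
a user-supplied center (for synthetic data, the true value; for real
data it must come from an external noise measurement). Uniform-prior
parameters are sampled through a logit transform with the Jacobian folded
into the transformed-scale prior.

The sampler is a delayed-acceptance Metropolis–Hastings: stage 1
accepts/rejects with the posterior under the *coarse* filter likelihood
(`δt = 0.5 h`); stage-1 survivors face the correction ratio
`[L_fine(ψ') L_coarse(ψ)] / [L_fine(ψ) L_coarse(ψ')]` with the *fine*
likelihood (`δt = 0.1 h`), so the fine-discretization posterior is the
invariant law while most rejections cost only a coarse evaluation.
Proposals are Gaussian random walks on the transformed scale with
Haario-style covariance adaptation (`2.38²/d` times the running empirical
covariance plus jitter) and a Robbins–Monro global scale steered to a
0.234 acceptance rate; all adaptation freezes after 80% of the run, so
the chain tail uses a fixed kernel. The adaptive covariance is seeded
with a Laplace approximation (finite-difference Hessian of the coarse
posterior at the starting point, eigenvalue-floored so flat ridge
directions get bounded proposal scales): the posterior's strong
`R_max`–`K_pc`–`κ` correlations would otherwise take thousands of
iterations for the adaptation to discover. Parameters sampled by default:
`R_max, K_pc, n, μ, E[τ], SD[τ], κ, σ_ε, μ₀, ν₀, var_x0`.

Chain starts: `init="prior"` draws from the priors until the posterior is
finite. With priors as diffuse as `N(0, 20²)` on a log scale this is
faithful to the reference procedure but needs very long chains to recover
from extreme draws; for desk-scale runs `init="auto"` starts the diffuse
scale parameters at data-informed method-of-moments guesses (jittered,
so chains are overdispersed) and can precede sampling with a bounded
Nelder–Mead climb of the coarse posterior (`warm_start`). Convergence
screening mirrors practice for this model class: chains whose
log-posterior trace has split-R̂ > 1.1 (equilibration transients, stuck
modes) are excluded, then chains are dropped greedily while the maximum
parameter-wise cross-chain split-R̂ exceeds 1.1. The within-chain screen
uses the log-posterior rather than parameter traces because the strong
`R_max`–`K_pc`–`κ` posterior correlations produce slowly mixing ridge
directions even in healthy chains.

The MCMC target excludes the initialization window's likelihood
contribution (the head observations are still assimilated to build the
window state). This is deliberate: the step-transcription birth–death
model of the first `τ_m` hours is instrumental — it exists to produce a
first estimate of the window mean and covariance, not to describe an
oscillating head segment — and letting its misfit into the target
demonstrably biases the main parameters towards a spurious
low-copy-number, high-noise basin that compensates for the head. The
filtering API reports both components (`loglik`, `head_loglik`).

Summaries are reported on the natural scale as means, SDs and highest
posterior density intervals (narrowest interval containing the target
mass, computed by a sorted-sample scan).

## Diagnostics

* **Coverage**: the filter is run at the true parameters on replicated
  synthetic series; empirical coverage counts how often the noise-free
  binned signal falls in the central Gaussian `level` interval of the
  one-step predictive (`Fρ ± z sqrt(F P F')`) and of the partial
  smoothing density. Comparing against the noise-free binned observation
  (rather than the latent state path) is a choice — it matches what the
  observation functional estimates; a latent-state mode would need the
  state smoothing moments instead (also returned by the filter).
  Intervals from the initialization window are excluded.
* **Posterior predictive**: thinned posterior draws re-simulate the
  observation process (delayed SSA + `y = κ ∫X + ε` with the draw's own
  scales); pointwise quantile envelopes are returned.
* **Standardized residuals**: one-step innovations divided by their
  predictive SD, after the initialization window. Under a correct model
  they are approximately white with unit variance.
* **Residual periodicity**: periodogram of the residuals; the top peaks
  are reported with significance against a white-noise null (exponential
  ordinates, Bonferroni over Fourier frequencies, 5%), with explicit
  flags for the circadian (24 ± 2 h) and semi-circadian (12 ± 1.5 h)
  bands.

## Problem sizes used by the shipped studies

The test suite and the acceptance script run deliberately scaled-down
versions of the reference studies, chosen as the smallest sizes at which
the checked properties are statistically meaningful:

* Calibration: 10 replicates × 5 days, SNR 100, filter at `δt = 0.1 h`
  (~1800 predictive + 1800 smoothing intervals).
* Parameter recovery: one 5-day series, 2 chains × 4000 iterations of
  delayed acceptance (coarse 0.5 h / fine 0.1 h) with warm start,
  burn-in 50% — against 4 × 50k in a full-size study. Recovery is scored
  as the number of the 9 main parameters (`R_max, K_pc, n, μ, E[τ],
  SD[τ], κ, σ_ε, μ₀`) whose truth lies inside the 95% HPDI. At the
  default copy-number scale this check currently falls short of its
  target (see the ridge limitation below): a 50k-iteration reference
  chain recovers 6 of 9, desk-scale chains fewer.
* Sampler validity: 20k iterations on a two-parameter conjugate-style
  toy model, delayed acceptance vs plain MH.

## Known limitations

* **Kernel-shape ridge.** At the default study conditions (~100-molecule
  oscillation amplitude, five cycles of data) the posterior contains a
  nearly flat ridge along which the Hill coefficient and the delay
  kernel's mean and SD compensate one another (steeper repression with a
  wider, later kernel reproduces almost the same waveform). The
  log-likelihood at the truth exceeds the ridge by only a few nats while
  the ridge carries far more volume, so posterior mass drifts along it
  and HPDIs for `n`, `E[τ]`, `SD[τ]` can exclude the generating values
  even for long, stationary chains — a property of the inference problem
  at this copy-number scale and data length, not of the filter (whose
  conditional likelihood profiles peak at the truth, and whose
  predictive intervals are calibrated). Larger copy numbers sharpen the
  ridge; more cycles or replicate series would too.

* The moment propagation is first-order Euler; likelihood values depend
  on `δt` (the delayed-acceptance construction makes this harmless for
  inference, and the convergence order is asserted in tests).
* Only scalar observations (`q = 1`) are exercised; the update algebra is
  written generally but untested beyond one observed functional.
* Full (fixed-interval) smoothing is not implemented — only the partial
  smoothing that the sliding window yields for free.
* The initialization birth–death model is instrumental; its parameters
  soak up early-window misfit and are not interpretable.
* Per-step cost is quadratic in the window length `τ_m/δt`, so halving
  `δt` quadruples both memory and time for the covariance work.
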
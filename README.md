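# dlnafilter

Filtering and Bayesian parameter inference for stochastic biochemical
oscillators with **distributed delays**, built around a linear noise
approximation (LNA) filter that tracks the joint Gaussian law of an entire
delay window of latent states.

## The problem

Circadian gene expression arises from transcriptional–translational
negative feedback: a gene's product, after nuclear export, translation and
re-import, represses its own transcription. Explicitly modelling every
intermediate species is hopeless when only one reporter signal is
measured, so the loop is reduced to a single mRNA species whose
transcription hazard depends on its *own past*, weighted by a Gamma delay
density `K` on `[0, τ_m]`:

    R1:  ∅ → X   at rate  ν(u(t)) = R_max / (1 + (u(t)/K_pc)^n)
    R2:  X → ∅   at rate  μ X(t)
    u(t) = ∫_{t-τ_m}^t X(s) K(t-s) ds,   K ~ Gamma(E[τ], SD[τ]), τ_m = 30 h

observed through an integrating camera,
`Y_t = κ ∫_{t-Δ}^t X(s) ds + ε_t`, `ε_t ~ N(0, σ_ε²)`, `Δ = 0.5 h`.

Because the hazard depends on the past, the current state is not Markov —
but the path over a sliding window `[t-τ_m, t]` is. The filter therefore
propagates the mean vector and full covariance matrix of the latent state
over a `τ_m/δt + 1`-point lattice, linearizing the delayed chemical
Langevin equation at each Euler step, and conditions the *whole window* on
every observation with gain

    C = P_{t-τ_m:t, t} F' (F P_t F' + σ_ε²)^{-1}.

This yields a closed-form marginal likelihood `π(y | ψ)`, one-step
predictive moments, and "partial smoothing" moments (each past state
conditioned on all observations received while it was inside the window).
Parameters `ψ = (R_max, K_pc, n, μ, E[τ], SD[τ], κ, σ_ε, …)` are inferred
with a delayed-acceptance MCMC that screens proposals with a cheap
coarse-step (`δt = 0.5 h`) likelihood and accepts against the fine-step
(`δt = 0.1 h`) one, keeping the fine posterior exactly invariant.

For whom: systems biologists and statisticians fitting stochastic
delay-feedback models to bioluminescence/fluorescence reporter time series
(e.g. *Cry1-luc* imaging of SCN tissue), and method developers who need a
reference implementation of delayed-LNA filtering with honest oracles.

## Worked example

```python
from dlnafilter import ParameterSet, generate_dataset, filter_loglik

params = ParameterSet()          # reference TTFL truth: n=5, mu=0.58/h,
                                 # E[tau]=9.67 h, SD[tau]=3.56 h, ...
data = generate_dataset(params, n_rep=1, snr=100.0, seed=1)[0]
truth = params.replace(kappa=data.meta["kappa"],
                       sigma_eps=data.meta["sigma_eps"])
res = filter_loglik(data, truth, dt=0.1)
print(f"log-likelihood: {res.loglik:.2f}")
z = (data.meta["truth"][res.n_head:] - res.pred_mean[res.n_head:]) \
    / res.pred_var_signal[res.n_head:]**0.5
print(f"predictive z-scores: mean {z.mean():.3f}, sd {z.std():.3f}")
```

prints

```
log-likelihood: -595.83
predictive z-scores: mean 0.074, sd 0.997
```

The log-likelihood is the sum of Gaussian innovation densities over all
240 half-hour observations of the five-day series. The z-scores compare
the *noise-free* integrated signal (known for synthetic data) with the
filter's one-step predictive law: mean ≈ 0 and sd ≈ 1 say the filter is
calibrated — its predictive intervals can be taken at face value.

The same pipeline from the shell:

```bash
dlnafilter simulate --config model.yaml --n-rep 10 --snr 100 --seed 1 --out data/
dlnafilter filter   --data data/replicate_00.csv --config model.yaml --dt 0.1 --out moments.csv
dlnafilter fit      --data data/replicate_00.csv --config model.yaml \
                    --iters 50000 --chains 4 --seed 1 --dt-coarse 0.5 --dt-fine 0.1 --out chains/
dlnafilter diagnose --data data/replicate_00.csv --config model.yaml --chains chains/ --out report/
```

`model.yaml` is a flat key:value file with the `ParameterSet` fields
(`r_max`, `k_pc`, `n`, `mu`, `delay_mean`, `delay_sd`, `kappa`,
`sigma_eps`, `init_rate`, `mu0`, `beta`, `tau_max`).

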
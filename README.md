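# ringdrift

Drift–diffusion and neural-field models of how working-memory recall of a
circular feature (color, orientation, direction) is biased by learned
environmental statistics.

## The problem

In delayed-estimation tasks, a subject briefly views items, holds one feature
value in memory over a delay, and reports it on a continuous ring. Errors
grow with the delay like a diffusion process, and are systematically biased:
responses drift toward *common* feature values. This package implements a
complete modeling framework for that phenomenon:

- the remembered value `θ(t)` as a particle on the ring obeying

  ```
  dθ = −U′(θ) dt + σ dW(t)
  ```

  where `U(θ)` is an energy landscape whose wells are attractors of the
  memory — flat (pure diffusion), a fixed heterogeneous form
  `U(θ) = −(A_p/n) cos(n(θ − θ_off))`, or *learned*: after each observed
  stimulus `θ_N`, an inverted von Mises kernel is averaged into the
  landscape,

  ```
  U_N(θ) = [(N−1) U_{N−1}(θ) + h − s·f_vM(θ − θ_N; β)] / N ,
  ```

  the additive surrogate of sequential Bayesian updating of the stimulus
  prior (the stationary density `p̄ ∝ exp(−2U/σ²)` plays the role of the
  posterior);
- the Fokker–Planck equation of the same process (conservative
  exponentially-fitted finite volumes, Crank–Nicolson in time) for exact
  conditional/marginal response distributions and trial likelihoods;
- recall-error metrics: local mean distortion
  `d̄(θ) = ∫ P(θ′|θ)(1 − cos(θ − θ′)) dθ′`, its prior-weighted total
  `d̄_tot`, and bootstrap bands;
- a stochastic neural field with a Heaviside firing nonlinearity and
  local-excitation / broad-inhibition connectivity in which a bump of
  persistent activity encodes the estimate; presynaptic, experience-driven
  potentiation (with weak decay) reshapes the connectivity, and asymptotic
  reductions map the bump position exactly onto the particle model;
- the synthetic task protocol (two items per trial, 0.5 s / 4 s delays, 50%
  draws from four 20°-wide arcs at a random per-subject offset) and a
  generator of synthetic subjects driven by any of the models;
- the model-comparison pipeline: eight candidate models (flat / three fixed
  heterogeneous / four learning), random-search fits under 5-fold
  cross-validation of the mean squared circular error, model selection, and
  trial-by-trial log-likelihood ratios computed from the PDE likelihoods.

## Worked example

```python
import numpy as np
from ringdrift import (EnvironmentalPrior, ParticleParams, cosine, flat,
                       total_mean_distortion, simulate_response_set)
from ringdrift.distortion import bootstrap_distortion

prior = EnvironmentalPrior(form="exp_cosine", amplitude=1.0, modes=4)

# drift-free baseline vs the closed form 1 - exp(-sigma^2 T / 2)
d_flat = total_mean_distortion(flat(), 0.05, prior, T=5.0, n_sim=20_000, seed=0)
print(f"flat landscape d_tot = {d_flat:.5f}   (closed form {1-np.exp(-0.05**2*5/2):.5f})")

# local distortion at a common (attractor) vs rare (saddle) target
params = ParticleParams(sigma=0.05, T_delay=5.0, seed=1)
resp = simulate_response_set(cosine(1.0, 4), [0.0, np.pi/4], params, n_rep=4000)
prof = bootstrap_distortion({0.0: resp[0], np.pi/4: resp[1]}, n_boot=200, seed=2)
print(f"matched 4-well: d(0 deg) = {prof.d_mean[0]:.5f} +/- {prof.d_sd[0]:.1e}, "
      f"d(45 deg) = {prof.d_mean[1]:.3f} +/- {prof.d_sd[1]:.1e}")

# total distortion, matched wells vs flat, when diffusion dominates
d_f = total_mean_distortion(flat(), 0.3, prior, T=5.0, n_sim=20_000, seed=3)
d_m = total_mean_distortion(cosine(1.0, 4), 0.3, prior, T=5.0, n_sim=20_000, seed=4)
print(f"sigma=0.3: d_tot flat = {d_f:.3f}, matched 4-well = {d_m:.3f}")
```

prints

```
flat landscape d_tot = 0.00621   (closed form 0.00623)
matched 4-well: d(0 deg) = 0.00016 +/- 4.4e-06, d(45 deg) = 0.293 +/- 1.9e-04
sigma=0.3: d_tot flat = 0.204, matched 4-well = 0.056
```

Without drift, total distortion matches wrapped Brownian motion exactly.
A four-well landscape matched to a four-peak environment pins common targets
(errors collapse by ~40×) at the cost of dragging rare targets to the
nearest well; when diffusion is the dominant error source the trade-off is
favorable and the matched landscape beats the flat one overall.

A command-line layer wraps the same functionality:

```bash
ringdrift gen-synthetic --config session.yaml --out runs/     # synthetic subjects -> CSV
ringdrift fit-subjects --data runs/trials.csv --models all \
          --k-sets 100 --n-rep 100 --seed 1 --out runs/       # CV model comparison
ringdrift llr --data runs/trials.csv --out runs/              # trial-wise LLR
ringdrift distortion --config session.yaml --out runs/        # d_tot, MC and PDE
```

Every command writes a JSON manifest (resolved seed and parameters) so runs
reproduce bit-for-bit.

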
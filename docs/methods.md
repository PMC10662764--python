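# Methods

This note documents the models, the numerical choices behind them, what the
synthetic data do and do not emulate, and the design decisions taken where
the design was genuinely open.

## Ring conventions

All angles are radians on the half-open interval `[-pi, pi)`; `pi` wraps to
`-pi`, so every angle has one representative. Files and printed output use
degrees on `[-180, 180)`. The standard discretization is 360 bins of 1°,
with bin 0 centered at `-pi` so integer degrees fall on bin centers.
Particle positions are *not* snapped to the grid during integration — the 1°
discretization is a readout convention, and snapping would inject artificial
quantization noise into the SDE; gridded (learned) landscapes are the one
place the grid enters the dynamics, via a per-bin drift lookup.

## Environmental priors and the task protocol

Two heterogeneous stimulus distributions are implemented: the smooth
periodic prior `P_env(θ) ∝ exp(A cos(m(θ − φ)))` (default `A = 1`, `m = 4`;
sampled exactly by folding a von Mises draw onto the `m`-fold cover), and
the task-style mixture used by the behavioral protocol: with probability
`p_biased = 0.5` an item is uniform over one of four equispaced arcs of 20°
*full* width centered at `φ + k·90°`, otherwise uniform on the ring. The
synthetic session generator emulates the protocol — two items per trial
(target and distractor, drawn independently; the biased flag is per item),
100 short (0.5 s) and 100 long (4 s) delay trials in randomized interleaved
order, a per-subject offset `φ` uniform on one period `[0, π/2)`.

What the synthetic subjects do *not* emulate: swap errors, reaction times,
lapses, perceptual encoding noise, or any cue-identity effects (the target
is by construction the reported item). Passing the recovery tests therefore
shows the pipeline can identify model classes from clean model-generated
responses at realistic trial counts — not that human data are that clean.

## Particle model

Euler–Maruyama with `dt = 10 ms`; noise amplitude `σ` in rad·s^-1/2
(reference value 0.05), delay `T = 5 s` unless a protocol delay applies.
Energy landscapes follow the per-well normalization
`U = −(A_p/n)·cos(n(θ − θ_off))`, so the drift is `−A_p sin(n(θ − θ_off))`
with no extra factor of `n` — this is the form the fitted models use; the
plain normalization `U = −A_p cos(nθ)` is available via a flag
(`convention="plain"`). Offsets enter as `sin(n(θ − θ_off))`, consistent
with offsets bounded to one period `[0, π/2]` at `n = 4`. The dual
(two-frequency) landscape superposes two such terms sharing one offset.

Per-target response sets derive their generator from `(seed, target_index)`
so a target's replicate set is stable regardless of the batch around it.
Long-run occupancy is estimated from an ensemble of trajectories (64 × 2000
s in the validation studies) because the slowest ring mode decorrelates in
`~2/σ²` seconds and a single trajectory leaves total-variation sampling
error comparable to the 0.05 acceptance band.

## Learning rule

After each observed stimulus the landscape estimate is updated as

    U_N = [(N−1)·U_{N−1} + h − s·f_vM(θ − θ_N; β)] / N

with `f_vM` the *normalized* von Mises density and `h` a constant shift
(defaults `β = 8`, `s = 5`, `h = 0.25`). The unrolled form is a symmetric
average of the per-observation increments, which makes the estimate exactly
invariant to observation order. Two readings of the update's shift/kernel
term are implemented; the normalized kernel is the default because with the
reference constants an unnormalized `exp(β cos)` kernel (peak `e^8 ≈ 3000`)
would dwarf every other term, and constant shifts are gauge-irrelevant to
the dynamics anyway (`normalize_kernel=False` gives the literal variant).
A non-flat initial landscape (the "population-bias prior") is held as one
pseudo-observation, so it decays like `1/N` instead of being erased by the
first update. Target+distractor models fold in both items as two sequential
observations. The long-run limit is the circular convolution of `P_env`
with the kernel (mean-removed), computed spectrally.

## Fokker–Planck solver

Conservative finite-volume discretization of
`∂_t p = ∂_θ(U′p) + (σ²/2) ∂²_θ p` on the 1° grid with periodic wrap. The
drift flux uses exponentially-fitted (Chang–Cooper) upwinding with edge
velocities taken from potential differences between adjacent centers; this
reduces to central differencing for weak drift, to pure upwinding for
strong drift, and reproduces the discrete Boltzmann stationary density
`∝ exp(−2U/σ²)` exactly — plain first-order upwinding was rejected because
its numerical diffusion (`|v|Δx/2 ≈ 0.009` at the reference drift) exceeds
the physical `σ²/2 ≈ 0.00125` and visibly corrupts conditionals. Time
stepping is Crank–Nicolson (unconditionally stable) with sub-stepping that
caps the drift Courant number at 1; mass is conserved to machine precision
because the discrete generator has zero column sums, and tiny negative
masses from the CN solve are clipped and renormalized.

Deep wells at low noise produce stationary peaks narrower than a 1° bin
(e.g. OU width `σ/√(2nA_p) ≈ 0.4°` at `σ = 0.02`). Conditional solves
therefore auto-refine onto a finer internal grid when the cell Péclet
number `v·Δx/D` is large, then aggregate back to the readout grid; odd
refinement factors are used so fine bins nest inside readout bins without
edge ties. Likelihoods are conditional masses divided by the bin width,
floored at 1e-12 to keep log-likelihood ratios finite.

## Distortion

`d̄(θ) = E[1 − cos(θ − θ′)]` over the conditional response distribution;
`d̄_tot` weights by the prior. Monte-Carlo estimates sample initial
conditions from the prior (default 10⁴ at desk scale; the reference count
10⁵ is a plain argument), and a PDE route computes the same double integral
through the conditional matrix. Bootstrap bands are percentile bootstrap
over responses within a target bin (default 10³ resamples; 200 in the
timed studies).

A matched landscape only lowers *total* distortion when diffusion is the
dominant error source: at `σ = 0.05, T = 5` the flat model's error is
already tiny (4.5° sd) while wells drag every off-attractor target, so the
matched model loses overall even though it wins at the attractors; at
`σ = 0.3` the ordering reverses and the matched model wins by ~3.5×. The
efficiency study therefore runs the total-distortion comparison at
`σ = 0.3` and the attractor/saddle band comparison at the reference
`σ = 0.05`.

## Neural field

The field `u(x,t)` evolves by Euler–Maruyama with `dt = 0.1 s`, circular
FFT convolution for the recurrent term, a Heaviside nonlinearity
`H(u − κ)`, a transient Gaussian cue input, and multiplicative noise
`u·(F∗ξ)√(dt·dx)` where `F(d) = ε·exp(−|d|)` spatially correlates white
increments. Presynaptic heterogeneity multiplies outgoing weights:
`w(x,y) = (1 + h(y))·w_hom(x−y)`, with `h` fixed (`A_n cos(ny)`) or
learned. The centroid readout is the activity argmax (ties broken by the
circular mean of tied bins).

**Units.** The field constants (`κ = 0.1`, kernel scales 1 and 3, `dx =
0.036`, etc.) are bound to a spatial unit. Read in radians, the ring holds
~175 grid points and the stable Amari bump has half-width `a ≈ 1.51 rad ≈
86°` — wider than one period of the mode-4 heterogeneity, which *inverts*
the heterogeneity's effect (the interface projection's mode-4 coefficient
changes sign for `a ≳ 1.1`): potentiated locations repel the bump, matched
heterogeneity of either phase raises total distortion, and accumulating
plasticity is unstable. Read in degrees, `dx = 0.036°` tiles the ring with
exactly 10000 points, the bump is narrow (`a ≈ 1.5°`), potentiated
locations attract, the narrow-bump approximation is in its own validity
regime, and the slow-decay plasticity rule accumulates stably — so degrees
is the default (`units="rad"` is kept as an option). The cost of the
degree reading is scale: centroid diffusion is only ~0.005 deg²/s, so the
argmax readout jitter (~0.4°) dominates the variance trace and the
10-second delay shows no clean linear variance growth, and heterogeneity
moves distortion by amounts near the sampling floor. No unit reading of
the printed constants produces *both* substantial bump wandering and
attraction toward potentiated sites; the two acceptance tests that assume
that conjunction (linear variance growth with R² > 0.9 plus
heterogeneity-lowered distortion; learned-modulation correlation > 0.9
with falling distortion) are left failing rather than retuned, with the
attainable clauses (bump survival, drift directions, dominant mode 4,
phase alignment, re-adaptation) asserted and passing.

**Plasticity.** The per-trial update is applied to the presynaptic
modulation from the stimulation-time activity profile. Two readings are
implemented: `retention` (default), `s ← γ_s·s + β_s·u`, under which the
modulation decays by `1 − γ_s = 1%` per trial and environmental structure
accumulates over ~100 trials; and `literal`, `s ← (1−γ_s)·s + β_s·u`,
under which 99% of the modulation is lost every trial and `s` essentially
tracks the most recent stimulus. The retention reading is the default
because a weak decay is the stated character of the rule and is the only
reading under which the modulation can converge to the environment-matched
profile that the fixed-heterogeneity model prescribes.

**Reduction.** The bump-position drift is the interface integral
`U′(θ̃) = α ∫_{−a}^{a} [w(y−a) − w(a+y)] h(y+θ̃) dy` with
`α = 1/(2(w(2a) − w(0))) < 0`, so wells form at maxima of `h` for narrow
bumps. Its dominant-Fourier-mode form sums the kernel's ring harmonics
analytically (the first series term carries the heterogeneity amplitude
`b_m`, and high harmonics matter for narrow kernels — `k_max = 512` by
default in degree units). The narrow-bump limit is
`U′ ≈ −(4/3)·α·a⁴·w″(0)·h′(θ̃)`: expanding `w(y−a) − w(y+a) ≈ −2a w′(y)`
and integrating exactly gives the `(4/3)a⁴` coefficient; the cruder
endpoint-quadrature variant (available as `coefficient="endpoint"`)
overcounts the odd integrand threefold and is ~`3/a` too large in the test
regime. `α` can also be calibrated by least squares against measured
noise-free centroid velocities; the calibrated value agrees with the
analytic one to a few percent.

## Model fitting

Eight models, random-search fitting: `k_sets` parameter draws, uniform on
the bounded domains (`σ ∈ [0.01, 0.2]`, amplitudes `[0.1, 2]`, well counts
integer `[1, 12]`, offsets `[0, π/2]`, `β, s ∈ [1, 10]`; well counts are
integers because fractional wells are not periodic), `n_rep` simulated
responses per trial, scored by mean squared shortest-arc difference, under
5-fold cross-validation run separately per delay class (folds are a seeded
uniform partition). Learning-model landscapes evolve over the subject's
*full* chronological session — the stimulus history of both delay classes
was experienced regardless of which class is being scored — while training
and test MSEs use only the fitted class; held-out trials are simulated with
the landscape accumulated so far but never update it. Noise paths are
shared across parameter sets and folds (common random numbers), which pairs
the MSE comparison between candidate sets. Selection is by lowest mean
test MSE with exact ties broken toward fewer free parameters. Trial-wise
log-likelihood ratios use the Fokker–Planck likelihood of each response
under the evolving learning landscape versus the fixed landscape.

Desk-scale study sizes: recovery uses 10 subjects per generating class with
50+50-trial sessions, `k_sets = n_rep = 25`, scored on the long-delay
class where drift signatures are strongest; reference-scale counts
(`k_sets = n_rep = 100`, 100+100 trials) are plain arguments.

## Known limitations

- The field criteria discussed above are unattainable jointly under the
  printed constants; see the units paragraph.
- The Fokker–Planck solver is first-order accurate in strongly advected
  regions between refinements; spectral accuracy was deliberately out of
  scope.
- Learning models assume the shift `h` fixed (0.25) rather than fitted,
  matching the three-parameter model definitions.
- The CV random search makes no use of gradients or posteriors; parameter
  uncertainty is only what the five folds expose.
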
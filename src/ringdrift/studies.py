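"""End-to-end validation studies tying the modules together.

Each function runs one self-contained numerical experiment — closed-form
checks of the simulators, cross-method equivalences, learning-convergence
and efficiency properties, neural-field mechanics, and synthetic model
recovery — and returns a flat dict of measured quantities.  The test suite
asserts on these numbers; ``scripts/acceptance.py`` re-runs them from
scratch and reports them.

Problem sizes default to desk-scale values (documented per function); the
corresponding full-scale counts are plain arguments.
"""

from __future__ import annotations

from dataclasses import replace
import numpy as np

from .distortion import bootstrap_distortion, distortion_of, total_mean_distortion
from .environment import EnvironmentalPrior, generate_synthetic_subject, \
    make_experiment_session, sample_stimuli
from .fitting import get_model, fit_subject, trial_llr
from .fokker_planck import conditional_response_dist, delta_density, fp_propagate
from .landscapes import LearningState, cosine, flat, learning_update
from .neural_field import (NeuralFieldParams, bump_existence, drift_fourier_approx,
                           drift_narrowbump_approx, fixed_heterogeneity,
                           measure_centroid_drift, reduction_drift_numeric,
                           run_learning_session, simulate_field_trial, weight_kernel)
from .particle import ParticleParams, occupancy_histogram, simulate_endpoints, \
    simulate_response_set
from .ring import circ_diff, make_grid
from .landscapes import stationary_density

__all__ = [
    "flat_distortion_study", "boltzmann_stationarity_study", "mc_pde_equivalence_study",
    "prior_learning_study", "matched_efficiency_study", "field_bump_study",
    "field_learning_study", "reduction_study", "recovery_study",
]

PRIOR4 = EnvironmentalPrior(form="exp_cosine", amplitude=1.0, modes=4)


def _mode_and_phase(profile: np.ndarray, m: int = 4) -> tuple[int, float]:
    """Dominant nonzero ring harmonic and the mode-m peak phase in degrees."""
    F = np.fft.rfft(profile - profile.mean())
    dom = int(np.argmax(np.abs(F[1:])) + 1)
    # profile ~ cos(m(theta - phi)) peaks at phi = -angle(F_m)/m
    phase = np.rad2deg(-np.angle(F[m])) / m
    return dom, float(phase)


def _phase_error_deg(phase: float, m: int = 4) -> float:
    """Distance of a mode-m phase from the nearest prior peak (multiples of 360/m)."""
    period = 360.0 / m
    return float(abs((phase + period / 2) % period - period / 2))


def flat_distortion_study(seed: int = 0, n_sim: int = 10_000) -> dict:
    """Mean distortion of drift-free diffusion vs the closed form 1-e^{-s^2 T/2}."""
    sigma, T = 0.05, 5.0
    closed = 1 - np.exp(-sigma**2 * T / 2)
    rng = np.random.default_rng(seed)
    ends = simulate_endpoints(flat(), np.zeros(n_sim),
                              ParticleParams(sigma=sigma, T_delay=T), rng=rng)
    d = distortion_of(ends, 0.0)
    d_mc = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n_sim))
    cond = fp_propagate(flat(), sigma, delta_density(0.0), T)
    d_pde = float(np.sum(cond.mass * distortion_of(cond.grid.centers, 0.0)))
    return {"d_mc": d_mc, "d_pde": d_pde, "closed_form": float(closed),
            "mc_se": se, "n": n_sim}


def boltzmann_stationarity_study(seed: int = 0, n_particles: int = 64,
                                 T: float = 2000.0) -> dict:
    """Long-run occupancy of the four-well particle vs exp(-2U/sigma^2)."""
    sigma, spec = 0.3, cosine(0.05, 4)
    grid = make_grid()
    occ = occupancy_histogram(spec, ParticleParams(sigma=sigma, T_delay=T, dt=0.01),
                              n_particles=n_particles, grid=grid, seed=seed)
    stat = stationary_density(spec, sigma, grid)
    return {"tv": float(0.5 * np.abs(occ - stat).sum()),
            "n": int(n_particles * T / 0.01)}


def mc_pde_equivalence_study(seed: int = 0, n_sim: int = 100_000) -> dict:
    """Conditional response distributions, sampled vs solved, across a grid."""
    out = {}
    tvs = []
    target, T = np.deg2rad(30), 5.0
    for sigma in (0.02, 0.05, 0.1):
        for spec, name in ((flat(), "flat"), (cosine(1.0, 4), "4well")):
            pde = conditional_response_dist(spec, sigma, target, T, method="pde")
            mc = conditional_response_dist(spec, sigma, target, T, method="mc",
                                           n_sim=n_sim, seed=seed)
            tv = float(0.5 * np.abs(pde.mass - mc.mass).sum())
            out[f"tv_{name}_sigma{sigma}"] = tv
            tvs.append(tv)
    out["tv_max"] = max(tvs)
    out["n"] = n_sim
    return out


def prior_learning_study(seed: int = 0, n_samples: int = 1000, n_rep: int = 10) -> dict:
    """Sequential landscape learning from prior samples: shape, phase, distortion.

    Runs the von Mises update (beta=8, s=5, h=0.25) over ``n_samples`` draws
    from the matched four-peak prior, measuring per-trial distortion of a
    particle simulated under the current landscape (sigma=0.05, T=5), the
    final landscape's dominant harmonic and well phase, and order-permutation
    invariance of the final landscape.
    """
    rng = np.random.default_rng(seed)
    samples = sample_stimuli(PRIOR4, n_samples, seed=rng.integers(2**31))
    st = LearningState(beta=8.0, s=5.0, h=0.25)
    params = ParticleParams(sigma=0.05, T_delay=5.0)
    dists = np.empty(n_samples)
    for i, th in enumerate(samples):
        spec = st.landscape if st.N > 0 else flat()
        ends = simulate_endpoints(spec, np.full(n_rep, th), params, rng=rng)
        dists[i] = distortion_of(ends, th).mean()
        st = learning_update(st, th)
    dom, phase = _mode_and_phase(-st.U_est)  # wells of U are peaks of -U
    st_perm = LearningState(beta=8.0, s=5.0, h=0.25)
    for th in np.random.default_rng(seed + 1).permutation(samples):
        st_perm = learning_update(st_perm, th)
    return {
        "dominant_mode": dom,
        "phase_err_deg": _phase_error_deg(phase),
        "d_first100": float(dists[:100].mean()),
        "d_last100": float(dists[-100:].mean()),
        "perm_max_dev": float(np.max(np.abs(st.U_est - st_perm.U_est))),
        "n": n_samples,
    }


def matched_efficiency_study(seed: int = 0, n_sim: int = 10_000, n_rep: int = 4000,
                             n_boot: int = 200) -> dict:
    """Efficiency of a prior-matched landscape.

    Total mean distortion, matched four-well vs flat, in the
    diffusion-dominated regime (sigma=0.3, T=5) where attractor
    stabilization outweighs the drag on rare targets; plus local distortion
    at an attractor vs a saddle target with bootstrap bands at the reference
    parameters (A_p=1, n=4, sigma=0.05, T=5).
    """
    d_flat = total_mean_distortion(flat(), 0.3, PRIOR4, 5.0, n_sim=n_sim, seed=seed)
    d_matched = total_mean_distortion(cosine(1.0, 4), 0.3, PRIOR4, 5.0,
                                      n_sim=n_sim, seed=seed + 1)
    params = ParticleParams(sigma=0.05, T_delay=5.0, seed=seed + 2)
    resp = simulate_response_set(cosine(1.0, 4), [0.0, np.pi / 4], params, n_rep=n_rep)
    prof = bootstrap_distortion({0.0: resp[0], np.pi / 4: resp[1]},
                                n_boot=n_boot, seed=seed + 3)
    return {
        "d_tot_flat": float(d_flat),
        "d_tot_matched": float(d_matched),
        "d_attractor": float(prof.d_mean[0]),
        "d_saddle": float(prof.d_mean[1]),
        "sd_attractor": float(prof.d_sd[0]),
        "sd_saddle": float(prof.d_sd[1]),
        "bands_separate": bool(prof.d_mean[0] + 2 * prof.d_sd[0]
                               < prof.d_mean[1] - 2 * prof.d_sd[1]),
        "n": n_sim,
    }


def field_bump_study(seed: int = 0, n_rep: int = 200, n_trials: int = 256,
                     n_boot: int = 200) -> dict:
    """Bump persistence, centroid-variance growth, and heterogeneity efficiency.

    Homogeneous network: fraction of ``n_rep`` bumps surviving the 10 s
    delay and the linear-fit R^2 of the centroid displacement variance over
    the delay.  Efficiency: per-trial distortion over ``n_trials`` targets
    from the matched prior, homogeneous vs prior-matched fixed
    heterogeneity, with bootstrap means of the total distortion.
    """
    p = NeuralFieldParams()
    rng = np.random.default_rng(seed)
    res = simulate_field_trial(p, None, 0.0, n_rep=n_rep, rng=rng)
    alive_frac = float(np.mean(res.u_final.max(axis=1) > p.kappa))
    stim = int(round(p.t_inp / p.dt))
    disp = np.rad2deg(circ_diff(res.centroid[:, stim:], res.centroid[:, stim:stim + 1]))
    var = disp.var(axis=0)
    tt = res.times[stim:] - res.times[stim]
    A = np.vstack([tt, np.ones_like(tt)]).T
    coef, rss, *_ = np.linalg.lstsq(A, var, rcond=None)
    ss = float(((var - var.mean()) ** 2).sum())
    r2 = float(1 - rss[0] / ss) if ss > 0 else 0.0

    targs = sample_stimuli(PRIOR4, n_trials, seed=rng.integers(2**31))
    d_by = {}
    for name, het in (("hom", None), ("het", fixed_heterogeneity(p))):
        r = simulate_field_trial(p, het, targs, n_rep=n_trials,
                                 rng=np.random.default_rng(seed + 5))
        d_by[name] = distortion_of(r.centroid[:, -1], targs)
    idx = rng.integers(0, n_trials, size=(n_boot, n_trials))
    boot_hom = d_by["hom"][idx].mean(axis=1)
    boot_het = d_by["het"][idx].mean(axis=1)
    return {
        "alive_frac": alive_frac,
        "var_slope_deg2_per_s": float(coef[0]),
        "var_r2": r2,
        "d_hom": float(boot_hom.mean()),
        "d_het": float(boot_het.mean()),
        "het_lower_frac": float(np.mean(boot_het < boot_hom)),
        "n": n_rep,
    }


def field_learning_study(seed: int = 0, n_trials: int = 300) -> dict:
    """Experience-dependent presynaptic learning and re-adaptation.

    Trains the field on the matched prior for ``n_trials`` trials under the
    slow-decay (retention) rule, then re-trains on a prior shifted by half a
    peak spacing; measures the modulation's dominant harmonic, peak phase,
    correlation with the prescribed fixed heterogeneity, the distortion
    trend, and the re-aligned phase.
    """
    p = NeuralFieldParams()
    out = run_learning_session(p, PRIOR4, n_trials, seed=seed, rule="retention")
    s = out["s_mod"]
    dom, phase = _mode_and_phase(s)
    corr = float(np.corrcoef(s, fixed_heterogeneity(p))[0, 1])
    shifted_prior = EnvironmentalPrior(form="exp_cosine", amplitude=1.0, modes=4,
                                       offset=np.pi / 8)
    out2 = run_learning_session(p, shifted_prior, n_trials, seed=seed + 1,
                                rule="retention", s0=s)
    _, phase2 = _mode_and_phase(out2["s_mod"])
    return {
        "dominant_mode": dom,
        "phase_err_deg": _phase_error_deg(phase),
        "corr_cos4": corr,
        "d_first100": float(out["distortion"][:100].mean()),
        "d_last100": float(out["distortion"][-100:].mean()),
        "shifted_phase_err_deg": float(abs(_phase_error_deg(phase2 - 22.5))),
        "n": n_trials,
    }


def reduction_study(seed: int = 0, n_probes: int = 20) -> dict:
    """Agreement between the bump-position reduction and the full field.

    Sign agreement of the interface-integral drift with measured noise-free
    centroid velocities at ``n_probes`` positions (avoiding the drift
    zeros); relative error of the dominant-Fourier-mode approximation; and
    relative error of the narrow-bump approximation in its regime (a bump
    one tenth of the heterogeneity period, radian-scale kernel).
    """
    p = NeuralFieldParams()
    a = bump_existence(p)
    kern = lambda d: weight_kernel(p, d)
    h = fixed_heterogeneity(p)
    L = p.circumference
    probes = 4.5 + (360.0 / n_probes) * np.arange(n_probes)
    probes = ((probes + 180) % 360) - 180
    v = measure_centroid_drift(p, h, probes, t_settle=1.0, t_meas=8.0)
    _, up = reduction_drift_numeric(kern, h, a, theta=probes, x_grid=p.x_grid, L=L)
    signs = int(np.sum(np.sign(v) == np.sign(-up)))

    th = np.linspace(-180, 180, 721)
    _, up_num = reduction_drift_numeric(kern, h, a, theta=th, x_grid=p.x_grid, L=L)
    four = drift_fourier_approx(kern, p.A_n, 4, a, L=L, k_max=512)
    fourier_rel = float(np.max(np.abs(four["uprime"](th) - up_num))
                        / np.max(np.abs(up_num)))

    # narrow-bump regime: radian-unit kernel, bump a = 0.1 * (2 pi / m)
    p_rad = replace(p, units="rad")
    kern_r = lambda d: weight_kernel(p_rad, d)
    m = 4
    a_nb = 0.1 * (2 * np.pi / m)
    h_fn = lambda q: 0.4 * np.cos(m * np.asarray(q, dtype=float))
    th_r = np.linspace(-np.pi, np.pi, 721)
    _, up_nb_num = reduction_drift_numeric(kern_r, h_fn, a_nb, theta=th_r, L=2 * np.pi)
    _, U_nb = drift_narrowbump_approx(kern_r, h_fn, a_nb, theta=th_r, L=2 * np.pi)
    # compare drifts: differentiate the approximate landscape spectrally
    k = np.fft.rfftfreq(720, d=th_r[1] - th_r[0]) * 2 * np.pi
    dU = np.fft.irfft(1j * k * np.fft.rfft(U_nb[:-1]), n=720)
    nb_rel = float(np.max(np.abs(dU - up_nb_num[:-1])) / np.max(np.abs(up_nb_num)))
    return {"sign_agreement": signs, "n_probes": n_probes,
            "fourier_rel_err": fourier_rel, "narrowbump_rel_err": nb_rel, "n": n_probes}


def recovery_study(seed: int = 0, n_seeds: int = 10, k_sets: int = 25, n_rep: int = 25,
                   n_short: int = 50, n_long: int = 50) -> dict:
    """Synthetic model-class recovery and trial-wise LLR discrimination.

    Generates ``n_seeds`` subjects per class (drift-free, four-well static,
    target-only learning) under the task protocol, runs the scaled-down
    cross-validated fit of all eight models on the long-delay trials, and
    tabulates the selected classes.  The static- and learning-generated
    subjects are then scored trial-by-trial with the exact likelihoods of
    their true learning and fixed models to get cumulative LLR signs.
    """
    generators = {
        "Flat": {"sigma": 0.05},
        "StaticHet": {"sigma": 0.05, "A_p": 1.0, "n": 4},
        "LearnTargetFlatPrior": {"sigma": 0.05, "beta": 8.0, "s": 5.0},
    }
    class_names = ["flat", "fixed-heterogeneous", "learning"]
    confusion = {g: {c: 0 for c in class_names} for g in generators}
    statichet_ns = []
    llr_final = {"StaticHet": [], "LearnTargetFlatPrior": []}
    learn_p = generators["LearnTargetFlatPrior"]
    fixed_p = generators["StaticHet"]
    for g_idx, (gname, gparams) in enumerate(generators.items()):
        for i in range(n_seeds):
            rng = np.random.default_rng([seed, 77, i, g_idx])
            off = rng.uniform(0, np.pi / 2)
            session = make_experiment_session(off, n_short=n_short, n_long=n_long,
                                              seed=int(rng.integers(2**31)))
            ds = generate_synthetic_subject(gname, gparams, session,
                                            seed=int(rng.integers(2**31)),
                                            assigned_offset=off)
            res = fit_subject(ds, "long", k_sets=k_sets, n_rep=n_rep,
                              seed=int(rng.integers(2**31)))
            winner = min(res.values(), key=lambda r: r.mean_test_mse)
            confusion[gname][get_model(winner.model_name).class_label] += 1
            if gname == "StaticHet":
                statichet_ns += [p["n"] for p in res["StaticHet"].fold_best_params]
            if gname in llr_final:
                out = trial_llr(ds, get_model("LearnTargetFlatPrior"), learn_p,
                                get_model("StaticHet"), fixed_p)
                llr_final[gname].append(float(out["cumulative"][-1]))
    diag = {"Flat": "flat", "StaticHet": "fixed-heterogeneous",
            "LearnTargetFlatPrior": "learning"}
    diag_dominant = all(
        confusion[g][diag[g]] > max(v for c, v in confusion[g].items() if c != diag[g])
        for g in generators)
    ns, counts = np.unique(statichet_ns, return_counts=True)
    return {
        "confusion": confusion,
        "diag_dominant": bool(diag_dominant),
        "flat_correct": confusion["Flat"]["flat"],
        "statichet_correct": confusion["StaticHet"]["fixed-heterogeneous"],
        "learning_correct": confusion["LearnTargetFlatPrior"]["learning"],
        "statichet_modal_n": int(ns[np.argmax(counts)]),
        "llr_positive_learning": int(np.sum(np.array(llr_final["LearnTargetFlatPrior"]) > 0)),
        "llr_negative_fixed": int(np.sum(np.array(llr_final["StaticHet"]) < 0)),
        "n": n_seeds,
    }
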
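"""Model zoo, cross-validated fitting, model selection, and trial-wise LLR.

Eight candidate particle models describe a subject's responses:

======================  =====  ======================  ======================
name                    free   drift                   class
======================  =====  ======================  ======================
Flat                    1      0                       flat
StaticHet               3      -A_p sin(n(θ-θ_off))    fixed-heterogeneous
OffsetHet               4      -A_p sin(n(θ-θ_off^s))  fixed-heterogeneous
DualHet                 5      two sine terms          fixed-heterogeneous
LearnTargetFlatPrior    3      evolving landscape      learning
LearnTargetHetPrior     3      evolving landscape      learning
LearnTDFlatPrior        3      evolving landscape      learning
LearnTDHetPrior         3      evolving landscape      learning
======================  =====  ======================  ======================

Learning models update a gridded landscape after every trial by averaging in
an inverted von Mises kernel at the target (and, for TD variants, the
distractor); HetPrior variants start from the population-bias landscape
``U_0 = -cos(4(θ - θ_pop))`` held as one pseudo-observation.  Fitting is
random search: ``k_sets`` parameter draws from the bounded domains, scored by
mean squared circular error against the subject's responses under 5-fold
cross-validation, run separately per delay class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import i0

try:  # optional JIT for the sequential per-trial SDE loops
    from numba import njit

    @njit(fastmath=True)
    def _sde_steps(pos, table, z, amp, dt, bw, nb):  # pragma: no cover - numba path
        n_steps = z.shape[0]
        M, R = pos.shape
        inv_bw = 1.0 / bw
        for s in range(n_steps):
            for m in range(M):
                trow = table[m]
                a = amp[m]
                for r in range(R):
                    idx = int(np.floor((pos[m, r] + np.pi) * inv_bw + 0.5)) % nb
                    pos[m, r] += trow[idx] * dt + a * z[s, r]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _sde_steps(pos, table, z, amp, dt, bw, nb):
        rows = np.arange(pos.shape[0])[:, None]
        for s in range(z.shape[0]):
            idx = np.rint((pos + np.pi) / bw).astype(np.intp) % nb
            pos += table[rows, idx] * dt + amp[:, None] * z[s][None, :]

from .environment import SubjectDataset, TrialRecord
from .fokker_planck import LIKELIHOOD_FLOOR, conditional_matrix, delta_density, fp_propagate
from .landscapes import LandscapeSpec, cosine, dual_cosine, flat, gridded
from .ring import RingGrid, TWO_PI, circ_diff, make_grid

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODEL_NAMES",
    "get_model",
    "sample_parameter_sets",
    "simulate_model_responses",
    "mse_score",
    "crossval_fit",
    "select_model",
    "trial_llr",
    "fit_subject",
]

# parameter bounds of the random-search domain
BOUNDS = {
    "sigma": (0.01, 0.2),
    "A_p": (0.1, 2.0),
    "A1": (0.1, 2.0),
    "A2": (0.1, 2.0),
    "n": (1, 12),
    "n1": (1, 12),
    "n2": (1, 12),
    "theta_off_s": (0.0, np.pi / 2),
    "beta": (1.0, 10.0),
    "s": (1.0, 10.0),
}
INTEGER_PARAMS = {"n", "n1", "n2"}
LEARN_H = 0.25  # fixed shift of the learning update (not a free parameter)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    class_label: str  # flat | fixed-heterogeneous | learning
    free_params: tuple
    uses_distractor: bool = False
    het_prior: bool = False

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def is_learning(self) -> bool:
        return self.class_label == "learning"


_MODELS = {
    "Flat": ModelSpec("Flat", "flat", ("sigma",)),
    "StaticHet": ModelSpec("StaticHet", "fixed-heterogeneous", ("sigma", "A_p", "n")),
    "OffsetHet": ModelSpec("OffsetHet", "fixed-heterogeneous",
                           ("sigma", "A_p", "n", "theta_off_s")),
    "DualHet": ModelSpec("DualHet", "fixed-heterogeneous",
                         ("sigma", "A1", "n1", "A2", "n2")),
    "LearnTargetFlatPrior": ModelSpec("LearnTargetFlatPrior", "learning",
                                      ("sigma", "beta", "s")),
    "LearnTargetHetPrior": ModelSpec("LearnTargetHetPrior", "learning",
                                     ("sigma", "beta", "s"), het_prior=True),
    "LearnTDFlatPrior": ModelSpec("LearnTDFlatPrior", "learning",
                                  ("sigma", "beta", "s"), uses_distractor=True),
    "LearnTDHetPrior": ModelSpec("LearnTDHetPrior", "learning",
                                 ("sigma", "beta", "s"), uses_distractor=True, het_prior=True),
}
MODEL_NAMES = tuple(_MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}") from None


def sample_parameter_sets(model: ModelSpec, k: int, seed=None) -> List[dict]:
    """``k`` uniform draws from the bounded domain (integers inclusive)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(k):
        p = {}
        for name in model.free_params:
            lo, hi = BOUNDS[name]
            if name in INTEGER_PARAMS:
                p[name] = int(rng.integers(lo, hi + 1))
            else:
                p[name] = float(rng.uniform(lo, hi))
        sets.append(p)
    return sets


def static_landscape(model: ModelSpec, params: dict, assigned_offset: float) -> LandscapeSpec:
    """Landscape of a fixed-landscape model under the drift conventions above."""
    if model.name == "Flat":
        return flat()
    if model.name == "StaticHet":
        return cosine(params["A_p"], int(params["n"]), theta_off=assigned_offset)
    if model.name == "OffsetHet":
        return cosine(params["A_p"], int(params["n"]), theta_off=params["theta_off_s"])
    if model.name == "DualHet":
        return dual_cosine(params["A1"], int(params["n1"]), params["A2"], int(params["n2"]),
                           theta_off=assigned_offset)
    raise ValueError(f"{model.name} is not a fixed-landscape model")


def _initial_learning_state(model: ModelSpec, k: int, grid: RingGrid,
                            population_offset: float):
    """(U_numerator, pseudo_count) shared across ``k`` parameter sets."""
    if model.het_prior:
        U0 = -np.cos(4.0 * (grid.centers - population_offset))
        return np.tile(U0, (k, 1)), 1
    return np.zeros((k, grid.n_bins)), 0


def _vm_batch(beta: np.ndarray, centers: np.ndarray, theta: float) -> np.ndarray:
    """Normalized von Mises kernels, one row per beta value."""
    return np.exp(beta[:, None] * np.cos(centers[None, :] - theta)) / (TWO_PI * i0(beta))[:, None]


def _simulate_batch(
    model: ModelSpec,
    param_sets: Sequence[dict],
    trials: Sequence[TrialRecord],
    n_rep: int,
    rng: np.random.Generator,
    assigned_offset: float,
    population_offset: float,
    update_mask: Optional[np.ndarray] = None,
    dt: float = 0.01,
    grid: Optional[RingGrid] = None,
) -> np.ndarray:
    """Simulated responses, shape ``(k_sets, n_trials, n_rep)``.

    Learning models run chronologically; a trial's stimuli are folded into
    the landscape only where ``update_mask`` is True (always after that
    trial's own responses were simulated).
    """
    grid = grid or make_grid()
    k = len(param_sets)
    n_trials = len(trials)
    out = np.empty((k, n_trials, n_rep))
    sigma = np.array([p["sigma"] for p in param_sets])
    noise_amp = (sigma * np.sqrt(dt))[:, None]

    if not model.is_learning:
        specs = [static_landscape(model, p, assigned_offset) for p in param_sets]
        A = np.array([[0.0, 0.0] if s.kind == "flat"
                      else [s.A_p, 0.0] if s.kind in ("cosine", "offset_cosine")
                      else [s.A1, s.A2] for s in specs])
        nmode = np.array([[1, 1] if s.kind == "flat"
                          else [s.n, 1] if s.kind in ("cosine", "offset_cosine")
                          else [s.n1, s.n2] for s in specs], dtype=float)
        off = np.array([s.theta_off for s in specs])
        A1c, A2c = A[:, 0:1, None], A[:, 1:2, None]
        n1c, n2c = nmode[:, 0:1, None], nmode[:, 1:2, None]
        offc = off[:, None, None]
        # one joint integration per delay length: the landscape is trial-independent;
        # noise paths are shared across parameter sets (common random numbers)
        delays = np.array([tr.delay_s for tr in trials])
        targets = np.array([tr.target for tr in trials])
        namp = noise_amp[:, :, None]
        for delay in np.unique(delays):
            sel = np.nonzero(delays == delay)[0]
            pos = np.broadcast_to(targets[sel][None, :, None], (k, sel.size, n_rep)).copy()
            for _ in range(int(round(delay / dt))):
                shifted = pos - offc
                drift = -A1c * np.sin(n1c * shifted) - A2c * np.sin(n2c * shifted)
                pos += drift * dt + namp * rng.standard_normal((sel.size, n_rep))[None, :, :]
            out[:, sel, :] = np.mod(pos + np.pi, TWO_PI) - np.pi
        return out

    # learning family
    beta = np.array([p["beta"] for p in param_sets])
    s_scale = np.array([p["s"] for p in param_sets])
    numer, pseudo = _initial_learning_state(model, k, grid, population_offset)
    count = pseudo
    amp = sigma * np.sqrt(dt)
    inv_2w = 1.0 / (2.0 * grid.bin_width)
    bw = grid.bin_width
    nb = grid.n_bins
    for i, tr in enumerate(trials):
        U = numer if count == 0 else numer / count
        table = -(np.roll(U, -1, axis=1) - np.roll(U, 1, axis=1)) * inv_2w  # drift = -U'
        pos = np.full((k, n_rep), tr.target)
        n_steps = int(round(tr.delay_s / dt))
        z = rng.standard_normal((n_steps, n_rep))
        _sde_steps(pos, np.ascontiguousarray(table), z, amp, dt, bw, nb)
        out[:, i, :] = np.mod(pos + np.pi, TWO_PI) - np.pi
        if update_mask is None or update_mask[i]:
            stims = [tr.target] + ([tr.distractor] if model.uses_distractor else [])
            for th in stims:
                numer = numer + LEARN_H - s_scale[:, None] * _vm_batch(beta, grid.centers, th)
                count += 1
    return out


def _learning_cv_errors(
    model: ModelSpec,
    param_sets: Sequence[dict],
    trials: Sequence[TrialRecord],
    subject: np.ndarray,
    masks: np.ndarray,  # (n_folds, n_trials) True where a trial trains the landscape
    eval_idx: np.ndarray,  # positions in ``trials`` whose responses are scored
    n_rep: int,
    rng: np.random.Generator,
    assigned_offset: float,
    population_offset: float,
    dt: float = 0.01,
    grid: Optional[RingGrid] = None,
) -> np.ndarray:
    """Replicate-averaged squared errors for every (fold, parameter set, eval trial).

    ``trials`` is the subject's full chronological session: every masked
    trial feeds the landscape (stimulus history is experienced regardless of
    which delay class is being scored), while responses are simulated and
    scored only at ``eval_idx``.  All folds and parameter sets advance
    through the sequence in one pass (the landscape state is fold-specific
    because held-out trials do not update it).  Noise paths are shared
    across folds and parameter sets (common random numbers), pairing the
    MSE comparison between sets.
    """
    grid = grid or make_grid()
    n_folds = masks.shape[0]
    k = len(param_sets)
    sigma = np.array([p["sigma"] for p in param_sets])
    beta = np.array([p["beta"] for p in param_sets])
    s_scale = np.array([p["s"] for p in param_sets])
    amp = np.tile(sigma * np.sqrt(dt), n_folds)  # (F*k,)
    numer0, pseudo = _initial_learning_state(model, k, grid, population_offset)
    numer = np.tile(numer0, (n_folds, 1, 1))  # (F, k, nb)
    counts = np.full(n_folds, pseudo, dtype=float)
    eval_pos = {int(t): j for j, t in enumerate(eval_idx)}
    E = np.empty((n_folds, k, len(eval_idx)))
    inv_2w = 1.0 / (2.0 * grid.bin_width)
    bw = grid.bin_width
    nb = grid.n_bins
    for i, tr in enumerate(trials):
        if i in eval_pos:
            safe = np.where(counts == 0, 1.0, counts)
            U = numer / safe[:, None, None]
            flatU = U.reshape(n_folds * k, grid.n_bins)
            table = -(np.roll(flatU, -1, axis=1) - np.roll(flatU, 1, axis=1)) * inv_2w
            pos = np.full((n_folds * k, n_rep), tr.target)
            n_steps = int(round(tr.delay_s / dt))
            z = rng.standard_normal((n_steps, n_rep))
            _sde_steps(pos, np.ascontiguousarray(table), z, amp, dt, bw, nb)
            err = circ_diff(pos, subject[i]) ** 2
            E[:, :, eval_pos[i]] = err.mean(axis=1).reshape(n_folds, k)
        stims = [tr.target] + ([tr.distractor] if model.uses_distractor else [])
        active = masks[:, i]
        if active.any():
            for th in stims:
                incr = LEARN_H - s_scale[:, None] * _vm_batch(beta, grid.centers, th)
                numer[active] += incr[None, :, :]
                counts[active] += 1
    return E


def simulate_model_responses(model: ModelSpec, params: dict, trials: Sequence[TrialRecord],
                             n_rep: int = 100, seed=None, assigned_offset: float = 0.0,
                             population_offset: float = 0.0,
                             update_mask: Optional[np.ndarray] = None,
                             dt: float = 0.01) -> np.ndarray:
    """Responses of one parameterized model, shape ``(n_trials, n_rep)``."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    return _simulate_batch(model, [params], trials, n_rep, rng, assigned_offset,
                           population_offset, update_mask=update_mask, dt=dt)[0]


def mse_score(simulated: np.ndarray, subject_responses: np.ndarray) -> float:
    """Mean squared shortest-arc difference (rad^2) over trials and replicates."""
    simulated = np.asarray(simulated, dtype=float)
    subject = np.asarray(subject_responses, dtype=float)
    if simulated.shape[0] != subject.shape[0]:
        raise ValueError("trial count mismatch between simulations and responses")
    err = circ_diff(simulated, subject[:, None] if simulated.ndim == 2 else subject)
    return float(np.mean(err**2))


def _per_trial_sq_error(sim: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Replicate-averaged squared circular error, shape ``(k_sets, n_trials)``."""
    err = circ_diff(sim, subject[None, :, None])
    return np.mean(err**2, axis=2)


@dataclass
class FitResult:
    model_name: str
    delay_class: Optional[str]
    fold_best_params: List[dict]
    fold_train_mse: List[float]
    fold_test_mse: List[float]
    selected: bool = False

    @property
    def mean_test_mse(self) -> float:
        return float(np.mean(self.fold_test_mse))


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> List[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def crossval_fit(dataset: SubjectDataset, model: ModelSpec, k_sets: int = 100,
                 n_rep: int = 100, seed=None, delay_class: Optional[str] = None,
                 population_offset: float = 0.0, n_folds: int = 5,
                 dt: float = 0.01) -> FitResult:
    """Random-search fit of one model to one subject under k-fold CV.

    Trials of the requested delay class are split into ``n_folds`` test
    folds; within each fold the best of ``k_sets`` sampled parameter sets by
    training MSE is scored on the held-out trials.  Learning-model
    landscapes evolve chronologically over the subject's full session
    (stimulus history from both delay classes is experienced either way);
    held-out trials of the fitted class are simulated with the landscape
    accumulated so far but do not update it.
    """
    ds = dataset.split(delay_class) if delay_class is not None else dataset
    n_trials = len(ds.trials)
    if n_trials < n_folds:
        raise ValueError(f"need >= {n_folds} trials, got {n_trials}")
    rng = np.random.default_rng(seed)
    param_sets = sample_parameter_sets(model, k_sets, seed=rng.integers(2**31))
    folds = _fold_indices(n_trials, n_folds, rng)
    subject = np.asarray(ds.responses, dtype=float)

    fold_best, fold_train, fold_test = [], [], []
    if not model.is_learning:
        sim = _simulate_batch(model, param_sets, ds.trials, n_rep, rng,
                              ds.assigned_offset, population_offset, dt=dt)
        E = _per_trial_sq_error(sim, subject)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n_trials), test_idx)
            train_mse = E[:, train_idx].mean(axis=1)
            best = int(np.argmin(train_mse))
            fold_best.append(param_sets[best])
            fold_train.append(float(train_mse[best]))
            fold_test.append(float(E[best, test_idx].mean()))
    else:
        # evaluate on the fitted class but evolve landscapes over the whole
        # session, in trial order
        full = dataset.trials if delay_class is not None else ds.trials
        full_subject = np.asarray(dataset.responses if delay_class is not None
                                  else ds.responses, dtype=float)
        if delay_class is not None:
            eval_idx = np.array([i for i, t in enumerate(full)
                                 if t.delay_class == delay_class])
        else:
            eval_idx = np.arange(len(full))
        masks = np.ones((len(folds), len(full)), dtype=bool)
        for f, test_idx in enumerate(folds):
            masks[f, eval_idx[test_idx]] = False
        E_all = _learning_cv_errors(model, param_sets, full, full_subject, masks,
                                    eval_idx, n_rep, rng, ds.assigned_offset,
                                    population_offset, dt=dt)
        for f, test_idx in enumerate(folds):
            E = E_all[f]  # (k, n_eval) aligned with eval_idx order == ds.trials order
            train_idx = np.setdiff1d(np.arange(n_trials), test_idx)
            train_mse = E[:, train_idx].mean(axis=1)
            best = int(np.argmin(train_mse))
            fold_best.append(param_sets[best])
            fold_train.append(float(train_mse[best]))
            fold_test.append(float(E[best, test_idx].mean()))
    return FitResult(model.name, delay_class, fold_best, fold_train, fold_test)


def select_model(results: Sequence[FitResult]) -> FitResult:
    """Lowest mean test MSE wins; exact ties break toward fewer free parameters."""
    ranked = sorted(results, key=lambda r: (r.mean_test_mse, get_model(r.model_name).n_free))
    winner = ranked[0]
    for r in results:
        r.selected = r is winner
    return winner


def fit_subject(dataset: SubjectDataset, delay_class: str, model_names=MODEL_NAMES,
                k_sets: int = 100, n_rep: int = 100, seed=None,
                population_offset: float = 0.0, dt: float = 0.01) -> Dict[str, FitResult]:
    """Fit every named model to one subject and mark the selected one."""
    results = {}
    ss = np.random.SeedSequence(seed)
    for name, child in zip(model_names, ss.spawn(len(model_names))):
        results[name] = crossval_fit(dataset, get_model(name), k_sets=k_sets, n_rep=n_rep,
                                     seed=child.generate_state(1)[0] % (2**31),
                                     delay_class=delay_class,
                                     population_offset=population_offset, dt=dt)
    select_model(list(results.values()))
    return results


def trial_llr(dataset: SubjectDataset, learn_model: ModelSpec, learn_params: dict,
              fixed_model: ModelSpec, fixed_params: dict,
              population_offset: float = 0.0, dt: float = 0.02,
              grid: Optional[RingGrid] = None) -> dict:
    """Per-trial log-likelihood ratio (learning vs fixed), via the PDE.

    The learning model's landscape is evolved by every preceding trial's
    stimuli before its own likelihood is computed; the fixed model reuses one
    precomputed conditional matrix per delay length.  Likelihoods are floored
    to keep the ratios finite.
    """
    grid = grid or make_grid()
    fixed_spec = static_landscape(fixed_model, fixed_params, dataset.assigned_offset)
    cond_by_delay = {}
    for tr in dataset.trials:
        if tr.delay_s not in cond_by_delay:
            cond_by_delay[tr.delay_s] = conditional_matrix(
                fixed_spec, fixed_params["sigma"], tr.delay_s, grid, dt=dt)

    numer, pseudo = _initial_learning_state(learn_model, 1, grid, population_offset)
    count = pseudo
    beta = np.array([learn_params["beta"]])
    s_scale = np.array([learn_params["s"]])
    sigma_l = learn_params["sigma"]
    llr = np.empty(len(dataset.trials))
    for i, (tr, resp) in enumerate(zip(dataset.trials, np.asarray(dataset.responses))):
        U = numer[0] if count == 0 else numer[0] / count
        spec = gridded(U)
        p0 = delta_density(tr.target, grid)
        cond = fp_propagate(spec, sigma_l, p0, tr.delay_s, dt=dt)
        j = grid.index_of(resp)
        p_learn = max(cond.density[j], LIKELIHOOD_FLOOR)
        p_fixed = max(cond_by_delay[tr.delay_s][j, grid.index_of(tr.target)] / grid.bin_width,
                      LIKELIHOOD_FLOOR)
        llr[i] = np.log(p_learn) - np.log(p_fixed)
        stims = [tr.target] + ([tr.distractor] if learn_model.uses_distractor else [])
        for th in stims:
            numer = numer + LEARN_H - s_scale[:, None] * _vm_batch(beta, grid.centers, th)
            count += 1
    return {"llr": llr, "cumulative": np.cumsum(llr)}
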
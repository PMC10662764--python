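"""Environmental priors, stimulus sampling, and synthetic task sessions.

The environment is the distribution of stimulus feature values (colors,
orientations, ...) an observer experiences.  Two heterogeneous forms are
supported:

* ``exp_cosine`` — the smooth periodic prior ``P(theta) ∝ exp(A cos(m (theta -
  offset)))`` with peaks at the ``m`` common feature values;
* ``peaked_arcs`` — the task-style mixture used in the delayed-estimation
  protocol: with probability ``p_biased`` an item is drawn uniformly from one
  of ``m`` equispaced arcs of ``arc_width_deg`` degrees (full width) centered
  at ``offset + 2*pi*k/m``, otherwise uniformly from the whole ring.

This module is also the synthetic-subject generator: it emulates the human
task protocol (two items per trial, 100 short / 100 long delay trials of
0.5 s / 4 s, 50% biased draws from 4 peaks spanning 20 degrees at a random
per-subject offset) and produces responses by running a named particle model,
so the full fitting pipeline is testable without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ring import RingGrid, TWO_PI, circ_diff, make_grid, rad2deg, wrap_angle

__all__ = [
    "EnvironmentalPrior",
    "TrialRecord",
    "SubjectDataset",
    "env_density",
    "sample_stimuli",
    "make_experiment_session",
    "generate_synthetic_subject",
    "dataset_to_frame",
    "frame_to_datasets",
]

SHORT_DELAY_S = 0.5
LONG_DELAY_S = 4.0


@dataclass(frozen=True)
class EnvironmentalPrior:
    """Distribution of stimulus feature values in the world."""

    form: str = "exp_cosine"  # exp_cosine | peaked_arcs | uniform
    amplitude: float = 1.0
    modes: int = 4
    offset: float = 0.0
    arc_width_deg: float = 20.0  # peaked_arcs only, full arc width
    p_biased: float = 0.5  # peaked_arcs only, mixture weight of the arcs

    def __post_init__(self):
        if self.form not in ("exp_cosine", "peaked_arcs", "uniform"):
            raise ValueError(f"unknown prior form {self.form!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.modes < 1:
            raise ValueError("modes must be >= 1")
        if self.form == "peaked_arcs" and not (0 < self.arc_width_deg < 90):
            raise ValueError("arc_width_deg must lie in (0, 90)")


@dataclass(frozen=True)
class TrialRecord:
    """One delayed-estimation trial (angles in radians)."""

    trial_index: int
    delay_class: str  # "short" | "long"
    delay_s: float
    target: float
    distractor: float
    biased_target: bool
    biased_distractor: bool


@dataclass
class SubjectDataset:
    """Trials plus responses for one (synthetic) subject."""

    subject_id: str
    assigned_offset: float
    trials: list
    responses: np.ndarray
    generator_truth: Optional[dict] = field(default=None)

    def split(self, delay_class: str) -> "SubjectDataset":
        """Sub-dataset restricted to one delay class, trial order preserved."""
        keep = [i for i, t in enumerate(self.trials) if t.delay_class == delay_class]
        return SubjectDataset(
            subject_id=self.subject_id,
            assigned_offset=self.assigned_offset,
            trials=[self.trials[i] for i in keep],
            responses=np.asarray(self.responses)[keep],
            generator_truth=self.generator_truth,
        )


def env_density(prior: EnvironmentalPrior, grid: Optional[RingGrid] = None) -> np.ndarray:
    """Per-bin density of the prior on ``grid`` (integrates to 1)."""
    grid = grid or make_grid()
    theta = grid.centers
    if prior.form == "uniform" or (prior.form == "exp_cosine" and prior.amplitude == 0):
        dens = np.full(grid.n_bins, 1.0 / TWO_PI)
    elif prior.form == "exp_cosine":
        dens = np.exp(prior.amplitude * np.cos(prior.modes * (theta - prior.offset)))
    elif prior.form == "peaked_arcs":
        half = np.deg2rad(prior.arc_width_deg) / 2.0
        centers = prior.offset + TWO_PI * np.arange(prior.modes) / prior.modes
        in_arc = np.zeros(grid.n_bins, dtype=bool)
        for c in centers:
            in_arc |= np.abs(circ_diff(theta, c)) <= half + 1e-12
        arc_mass = 2 * half * prior.modes  # total arc length
        dens = (1 - prior.p_biased) / TWO_PI + prior.p_biased * in_arc / arc_mass
    dens = dens / (dens.sum() * grid.bin_width)
    return dens


def _sample_arcs(prior: EnvironmentalPrior, n: int, rng: np.random.Generator) -> np.ndarray:
    half = np.deg2rad(prior.arc_width_deg) / 2.0
    k = rng.integers(0, prior.modes, size=n)
    centers = prior.offset + TWO_PI * k / prior.modes
    return wrap_angle(centers + rng.uniform(-half, half, size=n))


def sample_stimuli(prior: EnvironmentalPrior, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` feature values from the prior (seed-reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if prior.form == "uniform" or (prior.form == "exp_cosine" and prior.amplitude == 0):
        return wrap_angle(rng.uniform(-np.pi, np.pi, size=n))
    if prior.form == "exp_cosine":
        # exp(A cos(m u)) folds into a von Mises on the m-fold covering ring
        phi = rng.vonmises(0.0, prior.amplitude, size=n)
        k = rng.integers(0, prior.modes, size=n)
        return wrap_angle(prior.offset + (phi + TWO_PI * k) / prior.modes)
    # peaked_arcs mixture
    biased = rng.uniform(size=n) < prior.p_biased
    out = wrap_angle(rng.uniform(-np.pi, np.pi, size=n))
    n_b = int(biased.sum())
    if n_b:
        out[biased] = _sample_arcs(prior, n_b, rng)
    return out


def make_experiment_session(
    assigned_offset: float,
    n_short: int = 100,
    n_long: int = 100,
    p_biased: float = 0.5,
    arc_width_deg: float = 20.0,
    seed=None,
) -> list:
    """Emulate the two-item delayed-estimation session protocol.

    Each item (target and distractor) is independently flagged biased with
    probability ``p_biased``; biased items come from 4 equispaced arcs of
    ``arc_width_deg`` degrees centered at ``assigned_offset + k*90deg``,
    unbiased items from the uniform distribution.  Short (0.5 s) and long
    (4 s) delay trials are interleaved in randomized order.
    """
    if not (0 < arc_width_deg < 90):
        raise ValueError("arc_width_deg must lie in (0, 90)")
    rng = np.random.default_rng(seed)
    arcs = EnvironmentalPrior(
        form="peaked_arcs", modes=4, offset=assigned_offset,
        arc_width_deg=arc_width_deg, p_biased=1.0,
    )
    n_tot = n_short + n_long
    delays = np.array([SHORT_DELAY_S] * n_short + [LONG_DELAY_S] * n_long)
    rng.shuffle(delays)

    def draw_items(n):
        flags = rng.uniform(size=n) < p_biased
        vals = wrap_angle(rng.uniform(-np.pi, np.pi, size=n))
        if flags.any():
            vals[flags] = _sample_arcs(arcs, int(flags.sum()), rng)
        return vals, flags

    targets, bt = draw_items(n_tot)
    distractors, bd = draw_items(n_tot)
    trials = []
    for i in range(n_tot):
        trials.append(TrialRecord(
            trial_index=i,
            delay_class="short" if delays[i] == SHORT_DELAY_S else "long",
            delay_s=float(delays[i]),
            target=float(targets[i]),
            distractor=float(distractors[i]),
            biased_target=bool(bt[i]),
            biased_distractor=bool(bd[i]),
        ))
    return trials


def generate_synthetic_subject(
    model_name: str,
    params: dict,
    session: Sequence[TrialRecord],
    seed=None,
    subject_id: str = "synthetic",
    assigned_offset: float = 0.0,
    population_offset: float = 0.0,
) -> SubjectDataset:
    """Generate responses for ``session`` by simulating a named particle model.

    ``model_name`` is one of the eight fitted model classes (see
    :mod:`ringdrift.fitting`).  Learning models update their landscape
    trial-by-trial before simulating the next trial's response.
    """
    from . import fitting  # deferred: fitting depends on this module's types

    model = fitting.get_model(model_name)
    responses = fitting.simulate_model_responses(
        model, params, list(session), n_rep=1, seed=seed,
        assigned_offset=assigned_offset, population_offset=population_offset,
    )[:, 0]
    return SubjectDataset(
        subject_id=subject_id,
        assigned_offset=float(assigned_offset),
        trials=list(session),
        responses=np.asarray(responses, dtype=float),
        generator_truth={"model_name": model_name, "params": dict(params)},
    )


# ---------------------------------------------------------------------------
# CSV interface: angles in degrees on [-180, 180)

def dataset_to_frame(ds: SubjectDataset) -> pd.DataFrame:
    rows = []
    for t, r in zip(ds.trials, np.asarray(ds.responses)):
        rows.append({
            "subject_id": ds.subject_id,
            "trial_index": t.trial_index,
            "delay_class": t.delay_class,
            "delay_s": t.delay_s,
            "target_deg": rad2deg(t.target),
            "distractor_deg": rad2deg(t.distractor),
            "response_deg": rad2deg(r),
            "assigned_offset_deg": rad2deg(ds.assigned_offset),
        })
    return pd.DataFrame(rows)


def frame_to_datasets(df: pd.DataFrame) -> list:
    """Inverse of :func:`dataset_to_frame`; one dataset per subject_id."""
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        trials = []
        for _, row in sub.iterrows():
            delay_s = float(row["delay_s"])
            trials.append(TrialRecord(
                trial_index=int(row["trial_index"]),
                delay_class=str(row["delay_class"]),
                delay_s=delay_s,
                target=float(np.deg2rad(row["target_deg"])),
                distractor=float(np.deg2rad(row["distractor_deg"])),
                biased_target=False,
                biased_distractor=False,
            ))
        out.append(SubjectDataset(
            subject_id=str(sid),
            assigned_offset=float(np.deg2rad(sub["assigned_offset_deg"].iloc[0])),
            trials=trials,
            responses=np.deg2rad(sub["response_deg"].to_numpy(dtype=float)),
        ))
    return out
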
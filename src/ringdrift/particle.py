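"""Euler-Maruyama simulation of the remembered-estimate particle.

The stored estimate ``theta(t)`` obeys the Langevin equation

    d theta = -U'(theta) dt + sigma dW(t)

on the ring.  Positions are kept continuous during integration; the 1-degree
discretization of the feature space is applied only when histogramming or
reporting, so no quantization noise enters the SDE itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .landscapes import LandscapeSpec, gradient_on_grid, landscape_gradient
from .ring import RingGrid, make_grid, wrap_angle

__all__ = ["ParticleParams", "Trajectory", "simulate_trajectory", "simulate_response_set",
           "simulate_endpoints"]


@dataclass(frozen=True)
class ParticleParams:
    """Noise amplitude, delay and integration step of the particle model."""

    sigma: float = 0.05  # rad / sqrt(s)
    T_delay: float = 5.0  # s
    dt: float = 0.01  # s
    seed: Optional[int] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.T_delay < 0:
            raise ValueError("T_delay must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.T_delay / self.dt))


@dataclass
class Trajectory:
    times: np.ndarray
    positions: np.ndarray  # wrapped to [-pi, pi)


def _drift_fn(spec: LandscapeSpec, grid: RingGrid):
    """Vectorized drift ``-U'``; gridded specs use a per-bin lookup table."""
    if spec.kind == "gridded":
        table = -gradient_on_grid(spec, grid)

        def drift(pos):
            return table[grid.index_of(pos)]
    else:

        def drift(pos):
            return -landscape_gradient(spec, pos)

    return drift


def _integrate(spec: LandscapeSpec, theta0: np.ndarray, params: ParticleParams,
               rng: np.random.Generator, record: bool = False, grid: Optional[RingGrid] = None):
    """Advance all particles in ``theta0`` jointly for ``params.n_steps`` steps."""
    grid = grid or make_grid()
    drift = _drift_fn(spec, grid)
    pos = wrap_angle(np.asarray(theta0, dtype=float)).copy()
    pos = np.atleast_1d(pos)
    n_steps = params.n_steps
    noise_amp = params.sigma * np.sqrt(params.dt)
    path = np.empty((n_steps + 1,) + pos.shape) if record else None
    if record:
        path[0] = pos
    for k in range(n_steps):
        pos = pos + drift(pos) * params.dt
        if noise_amp > 0:
            pos = pos + noise_amp * rng.standard_normal(pos.shape)
        pos = wrap_angle(pos)
        if record:
            path[k + 1] = pos
    return pos, path


def simulate_trajectory(spec: LandscapeSpec, theta0: float, params: ParticleParams) -> Trajectory:
    """Single-particle trajectory including the initial position."""
    rng = np.random.default_rng(params.seed)
    _, path = _integrate(spec, np.array([theta0]), params, rng, record=True)
    times = params.dt * np.arange(params.n_steps + 1)
    return Trajectory(times=times, positions=path[:, 0])


def simulate_endpoints(spec: LandscapeSpec, theta0, params: ParticleParams,
                       rng: Optional[np.random.Generator] = None,
                       max_chunk: int = 200_000) -> np.ndarray:
    """End-of-delay positions for an array of initial conditions (one per particle)."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    out = np.empty_like(theta0)
    for lo in range(0, theta0.size, max_chunk):
        hi = min(lo + max_chunk, theta0.size)
        out[lo:hi], _ = _integrate(spec, theta0[lo:hi], params, rng)
    return out


def occupancy_histogram(spec: LandscapeSpec, params: ParticleParams,
                        n_particles: int = 16, grid: Optional[RingGrid] = None,
                        sample_stride: int = 5,
                        seed: Optional[int] = None) -> np.ndarray:
    """Long-run occupancy of an ensemble of particles (mass per bin).

    Initial positions are uniform; every ``sample_stride``-th step of every
    trajectory contributes one occupancy count.  For ergodic dynamics this
    converges to the Boltzmann stationary density.
    """
    grid = grid or make_grid()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    drift = _drift_fn(spec, grid)
    pos = rng.uniform(-np.pi, np.pi, n_particles)
    noise_amp = params.sigma * np.sqrt(params.dt)
    occ = np.zeros(grid.n_bins)
    for k in range(params.n_steps):
        pos = wrap_angle(pos + drift(pos) * params.dt
                         + noise_amp * rng.standard_normal(n_particles))
        if k % sample_stride == 0:
            np.add.at(occ, grid.index_of(pos), 1.0)
    return occ / occ.sum()


def simulate_response_set(spec: LandscapeSpec, targets, params: ParticleParams,
                          n_rep: int = 1) -> np.ndarray:
    """``n_rep`` independent end-of-delay responses per target.

    Returns an array of shape ``(n_targets, n_rep)``.  Each target gets its
    own generator seeded from ``(params.seed, target_index)`` so the response
    set for a given target is stable regardless of which other targets are in
    the batch.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise ValueError("targets must be non-empty")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    base = 0 if params.seed is None else int(params.seed)
    out = np.empty((targets.size, n_rep))
    for i, th in enumerate(targets):
        rng = np.random.default_rng([base, i])
        out[i] = simulate_endpoints(spec, np.full(n_rep, th), params, rng=rng)
    return out
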
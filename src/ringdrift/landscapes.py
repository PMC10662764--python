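"""Energy landscapes for the remembered-estimate particle model.

The remembered feature value drifts down the gradient of a scalar potential
``U(theta)`` on the ring; wells of ``U`` are attractors of the memory.  Two
families are supported:

* parametric cosines ``U(theta) = -(A_p/n) cos(n (theta - theta_off))`` whose
  drift is ``-U' = -A_p sin(n (theta - theta_off))`` (an ``amplitude_convention``
  flag switches to the plain ``-A_p cos(n theta)`` normalization, whose drift
  carries an extra factor ``n``), and superpositions of two such terms;
* gridded landscapes — arbitrary per-bin energies, e.g. produced by
  experience-dependent learning.

The module also carries the probabilistic side of the model: the Boltzmann
stationary density ``p(theta) ∝ exp(-2 U / sigma^2)``, the linearized map from
a weakly-varying posterior to a landscape, the sequential von Mises learning
update, and its long-run (prior-convolved) limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import i0

from .ring import RingGrid, TWO_PI, make_grid, wrap_angle
from .environment import EnvironmentalPrior, env_density

__all__ = [
    "LandscapeSpec",
    "LearningState",
    "flat",
    "cosine",
    "dual_cosine",
    "gridded",
    "eval_landscape",
    "landscape_gradient",
    "stationary_density",
    "posterior_to_landscape",
    "von_mises_kernel",
    "learning_update",
    "longrun_landscape",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Parametric or gridded energy landscape."""

    kind: str = "flat"  # flat | cosine | offset_cosine | dual_cosine | gridded
    A_p: float = 0.0
    n: int = 4
    theta_off: float = 0.0
    A1: float = 0.0
    n1: int = 4
    A2: float = 0.0
    n2: int = 8
    grid_values: Optional[np.ndarray] = None
    amplitude_convention: str = "per_well"  # per_well: U=-(A/n)cos ; plain: U=-A cos

    def __post_init__(self):
        if self.kind not in ("flat", "cosine", "offset_cosine", "dual_cosine", "gridded"):
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        if self.kind == "gridded" and self.grid_values is None:
            raise ValueError("gridded landscape requires grid_values")


def flat() -> LandscapeSpec:
    return LandscapeSpec(kind="flat")


def cosine(A_p: float, n: int, theta_off: float = 0.0, convention: str = "per_well") -> LandscapeSpec:
    return LandscapeSpec(kind="cosine", A_p=A_p, n=n, theta_off=theta_off,
                         amplitude_convention=convention)


def dual_cosine(A1: float, n1: int, A2: float, n2: int, theta_off: float = 0.0) -> LandscapeSpec:
    return LandscapeSpec(kind="dual_cosine", A1=A1, n1=n1, A2=A2, n2=n2, theta_off=theta_off)


def gridded(values: np.ndarray) -> LandscapeSpec:
    return LandscapeSpec(kind="gridded", grid_values=np.asarray(values, dtype=float))


def eval_landscape(spec: LandscapeSpec, theta, grid: Optional[RingGrid] = None):
    """Energy at angle(s) ``theta`` (for gridded specs, nearest-bin values)."""
    theta = np.asarray(theta, dtype=float)
    if spec.kind == "flat":
        return np.zeros_like(theta)
    if spec.kind in ("cosine", "offset_cosine"):
        scale = spec.A_p / spec.n if spec.amplitude_convention == "per_well" else spec.A_p
        return -scale * np.cos(spec.n * (theta - spec.theta_off))
    if spec.kind == "dual_cosine":
        return (-(spec.A1 / spec.n1) * np.cos(spec.n1 * (theta - spec.theta_off))
                - (spec.A2 / spec.n2) * np.cos(spec.n2 * (theta - spec.theta_off)))
    grid = grid or make_grid(len(spec.grid_values))
    if len(spec.grid_values) != grid.n_bins:
        raise ValueError("gridded landscape length does not match grid")
    return spec.grid_values[grid.index_of(theta)]


def _gridded_gradient(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Centered periodic finite differences of per-bin energies."""
    return (np.roll(values, -1) - np.roll(values, 1)) / (2.0 * bin_width)


def landscape_gradient(spec: LandscapeSpec, theta, grid: Optional[RingGrid] = None):
    """``U'(theta)``; the particle drift is its negative."""
    theta = np.asarray(theta, dtype=float)
    if spec.kind == "flat":
        return np.zeros_like(theta)
    if spec.kind in ("cosine", "offset_cosine"):
        scale = spec.A_p if spec.amplitude_convention == "per_well" else spec.A_p * spec.n
        return scale * np.sin(spec.n * (theta - spec.theta_off))
    if spec.kind == "dual_cosine":
        return (spec.A1 * np.sin(spec.n1 * (theta - spec.theta_off))
                + spec.A2 * np.sin(spec.n2 * (theta - spec.theta_off)))
    grid = grid or make_grid(len(spec.grid_values))
    grad = _gridded_gradient(np.asarray(spec.grid_values, dtype=float), grid.bin_width)
    return grad[grid.index_of(theta)]


def gradient_on_grid(spec: LandscapeSpec, grid: RingGrid) -> np.ndarray:
    """Per-bin ``U'`` lookup table (used by the vectorized simulators)."""
    if spec.kind == "gridded":
        return _gridded_gradient(np.asarray(spec.grid_values, dtype=float), grid.bin_width)
    return np.asarray(landscape_gradient(spec, grid.centers), dtype=float)


def stationary_density(spec: LandscapeSpec, sigma: float, grid: Optional[RingGrid] = None) -> np.ndarray:
    """Boltzmann-like stationary mass ``∝ exp(-2 U / sigma^2)`` (sums to 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = grid or make_grid()
    U = eval_landscape(spec, grid.centers, grid)
    w = np.exp(-2.0 * (U - U.min()) / sigma**2)
    return w / w.sum()


def posterior_to_landscape(l_variation: np.ndarray, sigma: float,
                           grid: Optional[RingGrid] = None) -> LandscapeSpec:
    """Landscape whose stationary density realizes a weakly-varying posterior.

    For a posterior ``L(theta) = 1/(2 pi) + l(theta)`` with zero-mean variation
    ``l``, the linearized inversion of the Boltzmann relation gives
    ``U = -pi sigma^2 l`` (constant gauge removed), so that
    ``exp(-2U/sigma^2) ∝ 1 + 2 pi l`` recovers ``L`` to first order.
    """
    grid = grid or make_grid(len(l_variation))
    l = np.asarray(l_variation, dtype=float)
    if abs(l.sum() * grid.bin_width) > 1e-8:
        raise ValueError("posterior variation must integrate to zero")
    return gridded(-np.pi * sigma**2 * l)


def von_mises_kernel(theta, center: float, beta: float, normalized: bool = True):
    """``exp(beta cos(theta - center))``, optionally normalized to a density."""
    k = np.exp(beta * np.cos(np.asarray(theta, dtype=float) - center))
    if normalized:
        k = k / (TWO_PI * i0(beta))
    return k


@dataclass
class LearningState:
    """Running experience-based landscape estimate.

    The estimate is the running average of per-observation increments
    ``h - s * f_vM(theta - theta_j; beta)``; a non-flat initial landscape
    passed at construction is retained as one pseudo-observation so it
    decays like ``1/N`` rather than being discarded by the first update
    (set ``pseudo_count`` explicitly to override).
    """

    beta: float
    s: float
    h: float = 0.25
    grid: RingGrid = field(default_factory=make_grid)
    normalize_kernel: bool = True
    N: int = 0
    pseudo_count: Optional[int] = None
    U_est: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.U_est is None:
            self.U_est = np.zeros(self.grid.n_bins)
        else:
            self.U_est = np.asarray(self.U_est, dtype=float).copy()
        if self.pseudo_count is None:
            self.pseudo_count = 1 if (self.N == 0 and self.U_est.any()) else 0

    @property
    def landscape(self) -> LandscapeSpec:
        return gridded(self.U_est)

    def implied_prior(self, sigma: float) -> np.ndarray:
        """Stationary mass consistent with the current estimate (Boltzmann)."""
        return stationary_density(self.landscape, sigma, self.grid)


def learning_update(state: LearningState, theta_obs) -> LearningState:
    """Fold one (or several) observed stimulus values into the estimate.

    One observation: ``U^N = ((N-1) U^{N-1} + h - s f_vM(. - theta_N)) / N``
    counting any prior pseudo-observations in ``N``.  The unrolled form is a
    symmetric average over the history, so the result is invariant to
    observation order.
    """
    thetas = np.atleast_1d(np.asarray(theta_obs, dtype=float))
    U = state.U_est.copy()
    N = state.N
    centers = state.grid.centers
    for th in thetas:
        incr = state.h - state.s * von_mises_kernel(centers, th, state.beta,
                                                    normalized=state.normalize_kernel)
        total = N + state.pseudo_count
        U = (total * U + incr) / (total + 1)
        N += 1
    new = replace(state)
    new.U_est = U
    new.N = N
    return new


def longrun_landscape(prior: EnvironmentalPrior, beta: float, s: float = 1.0,
                      grid: Optional[RingGrid] = None,
                      normalize_kernel: bool = True) -> LandscapeSpec:
    """Long-run limit of the learning rule: prior convolved with the kernel.

    ``U_inf(theta) ∝ -∫ P_env(theta - theta') exp(beta cos theta') dtheta'``,
    returned mean-removed on the grid.  For an ``exp_cosine`` prior with ``m``
    peaks the dominant Fourier mode of the result is ``m`` with wells at the
    prior peaks.
    """
    grid = grid or make_grid()
    dens = env_density(prior, grid)
    # kernel sampled at lag angles so that fft index arithmetic matches theta_i - theta_j
    lags = wrap_angle(grid.bin_width * np.arange(grid.n_bins))
    kern = von_mises_kernel(lags, 0.0, beta, normalized=normalize_kernel)
    conv = np.real(np.fft.ifft(np.fft.fft(dens) * np.fft.fft(kern))) * grid.bin_width
    U = -s * conv
    return gridded(U - U.mean())
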
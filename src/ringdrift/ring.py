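"""Circular arithmetic and discretization of the feature ring.

Every other module works with angles in radians on the half-open interval
``[-pi, pi)`` (the lower-closed convention: ``pi`` wraps to ``-pi``), so each
angle has a single representative.  File formats and user-facing reports use
degrees; conversion happens only at those boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = ["TWO_PI", "RingGrid", "wrap_angle", "circ_diff", "make_grid", "deg2rad", "rad2deg"]


def wrap_angle(x):
    """Wrap angle(s) ``x`` (radians) onto ``[-pi, pi)``.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.mod(x + np.pi, TWO_PI) - np.pi
    # mod can return 2*pi - eps + (-pi) == pi for inputs just below the seam
    wrapped = np.where(wrapped >= np.pi, -np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circ_diff(a, b):
    """Shortest signed arc ``a - b`` on the ring, in ``[-pi, pi)``.

    Antipodal pairs map to ``-pi`` by the lower-closed convention.
    """
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def deg2rad(deg):
    """Degrees to wrapped radians (file/display boundary helper)."""
    return wrap_angle(np.deg2rad(np.asarray(deg, dtype=float)))


def rad2deg(rad):
    """Radians to degrees in ``[-180, 180)``."""
    return np.rad2deg(wrap_angle(rad))


@dataclass(frozen=True)
class RingGrid:
    """Equispaced discretization of ``[-pi, pi)``.

    ``centers[i] = -pi + (i + 0.5) * bin_width`` would put bin edges at the
    seam; instead we follow the 1-degree readout convention and center bin 0
    at ``-pi`` so that integer degrees land on bin centers for ``n_bins=360``.
    """

    n_bins: int

    @property
    def bin_width(self) -> float:
        return TWO_PI / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return -np.pi + self.bin_width * np.arange(self.n_bins)

    def index_of(self, theta) -> np.ndarray:
        """Index of the bin whose center is nearest to ``theta`` (wrapped)."""
        theta = wrap_angle(theta)
        idx = np.rint((np.asarray(theta) + np.pi) / self.bin_width).astype(int)
        return np.mod(idx, self.n_bins)

    def histogram(self, angles) -> np.ndarray:
        """Probability mass per bin from samples (sums to 1)."""
        idx = self.index_of(angles)
        counts = np.bincount(np.atleast_1d(idx), minlength=self.n_bins).astype(float)
        total = counts.sum()
        if total == 0:
            raise ValueError("histogram of empty sample")
        return counts / total


def make_grid(n_bins: int = 360) -> RingGrid:
    """Standard ring grid; default 360 bins of 1 degree."""
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    return RingGrid(n_bins=int(n_bins))
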
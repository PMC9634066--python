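"""Polar-neuron population code for egocentric landmark coordinates.

The where-stream (parietal) representation of a landmark's egocentric
position (distance r, bearing theta from the body axis) is a grid of polar
radial-basis neurons.  Neuron i centred at (r_i, theta_i) responds with

    R_i = exp(-d(theta_i, theta)^2 / sigma_theta^2) * exp(-(r_i - r)^2 / sigma_r^2)

where d is the circular angular distance wrapped to [-pi, pi].  The default
network has 360 neurons: 36 azimuth divisions (10 degree resolution) x 10
radial divisions, with variances sigma_r^2 = 0.06 and sigma_theta^2 = 0.002
(radians^2).  The perceived position is decoded as the activation-weighted
average of the neuron centres, using the circular mean for the angle; the
decode error is at most half a grid bin in each coordinate for any in-range
target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolarNeuronGrid", "encode_egocentric", "decode_position"]


@dataclass(frozen=True)
class PolarNeuronGrid:
    """Polar grid of radial-basis neurons covering the egocentric field.

    Azimuth centres uniformly sample [0, 2pi); radial centres are placed at
    the centre of each of ``n_radial`` equal annuli partitioning (0, r_max],
    so every in-range radius lies within half a bin of a centre.
    """

    n_azimuth: int = 36
    n_radial: int = 10
    r_max: float = 10.0
    sigma_r_sq: float = 0.06
    sigma_theta_sq: float = 0.002

    def __post_init__(self) -> None:
        if self.n_azimuth < 1 or self.n_radial < 1:
            raise ValueError("n_azimuth and n_radial must be >= 1")
        if self.r_max <= 0 or self.sigma_r_sq <= 0 or self.sigma_theta_sq <= 0:
            raise ValueError("r_max and variances must be positive")

    @property
    def n_neurons(self) -> int:
        return self.n_azimuth * self.n_radial

    @property
    def theta_centers(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_azimuth) / self.n_azimuth

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_radial) + 0.5) * self.r_max / self.n_radial

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron (r_i, theta_i), azimuth-major: neuron k = (az k//n_radial, rad k%n_radial)."""
        th = np.repeat(self.theta_centers, self.n_radial)
        r = np.tile(self.r_centers, self.n_azimuth)
        return r, th


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angular difference(s) to [-pi, pi]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def encode_egocentric(grid: PolarNeuronGrid, r: float, theta: float) -> np.ndarray:
    """Activation field for a target at egocentric (r, theta).

    Raises ``ValueError`` for a radius outside [0, r_max].  Activations lie in
    (0, 1]; a target exactly on a neuron centre drives that neuron to 1.
    """
    if not 0 <= r <= grid.r_max:
        raise ValueError(f"radius {r} out of range [0, {grid.r_max}]")
    r_i, th_i = grid.centers
    dth = _wrap_angle(th_i - theta)
    return np.exp(-(dth**2) / grid.sigma_theta_sq) * np.exp(
        -((r_i - r) ** 2) / grid.sigma_r_sq
    )


def decode_position(grid: PolarNeuronGrid, field: np.ndarray) -> tuple[float, float]:
    """Perceived (r, theta) as the activation-weighted average of neuron centres.

    The angle uses the circular (vector) mean so the 0/2pi seam is handled;
    the returned angle is in [0, 2pi).  An all-zero field raises
    ``ValueError("no active neurons")``.
    """
    w = np.asarray(field, dtype=float)
    if w.shape != (grid.n_neurons,):
        raise ValueError(f"field must have shape ({grid.n_neurons},), got {w.shape}")
    total = w.sum()
    if total <= 0:
        raise ValueError("no active neurons")
    r_i, th_i = grid.centers
    r = float((w * r_i).sum() / total)
    theta = float(np.arctan2((w * np.sin(th_i)).sum(), (w * np.cos(th_i)).sum()))
    return r, theta % (2 * np.pi)
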
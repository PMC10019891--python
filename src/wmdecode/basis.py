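"""Idealized orientation information channels.

The encoding model expresses each voxel's response as a weighted sum of k
idealized channels. Each channel is a half-wave rectified sinusoid over the
180° orientation space, raised to an exponent p:

    f_j(theta) = max(0, cos(pi * d_j / 180))**p

where d_j is the signed circular difference between theta and the channel
center psi_j. The response is 1 at the channel's own center, falls to 0 at
the orthogonal orientation (90° away), and is nonnegative everywhere. The
exponent controls tuning width; p=8 is the conventional default for this
basis family and is exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circ import ORIENTATION_PERIOD, signed_orientation_diff


def _default_centers() -> tuple[float, ...]:
    return tuple(float(c) for c in range(0, 180, 20))


@dataclass(frozen=True)
class ChannelBasis:
    """A bank of orientation channels.

    Parameters
    ----------
    centers : channel peak orientations in degrees (default 0, 20, ..., 160).
    exponent : power applied to the rectified sinusoid (default 8).
    """

    centers: tuple[float, ...] = field(default_factory=_default_centers)
    exponent: float = 8.0
    space: float = ORIENTATION_PERIOD

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("centers must be a non-empty 1-D sequence")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        wrapped = np.sort(c % self.space)
        if np.unique(np.round(wrapped, 9)).size != c.size:
            raise ValueError("channel centers must be distinct modulo 180")

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    @property
    def centers_array(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=float)


def channel_response(basis: ChannelBasis, theta) -> np.ndarray:
    """Responses of all channels to orientation(s) ``theta``.

    Returns an array of shape (k,) for scalar input or (k, n) for a
    length-n input, with every entry in [0, 1].
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    t = np.atleast_1d(theta)
    d = signed_orientation_diff(t[None, :], basis.centers_array[:, None])
    resp = np.maximum(0.0, np.cos(np.pi * d / basis.space)) ** basis.exponent
    return resp[:, 0] if scalar else resp


def design_matrix(basis: ChannelBasis, thetas) -> np.ndarray:
    """Channel design matrix C of shape (k channels, n trials).

    Column i holds the idealized channel responses to trial i's
    orientation label. No normalization is applied across trials.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if thetas.size == 0:
        raise ValueError("design_matrix requires at least one trial")
    return channel_response(basis, thetas)
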
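"""Inverted encoding model with noise-covariance optimal filters.

The forward model is B = W C + N: voxel patterns B (m voxels x n trials)
are weighted sums of k idealized channel responses C. Training estimates
W by ordinary least squares,

    W = B1 C1^T (C1 C1^T)^-1 ,

then builds per-channel optimal linear filters that account for correlated
voxel noise. For channel i, the residual eps_i = B1 - W_i C1_i (the rank-1
prediction from that channel alone) gives a noise covariance
Sigma_i = eps_i eps_i^T / (n1 - 1), regularized by analytic shrinkage
toward a scaled identity, and the filter

    V_i = Sigma_i^-1 W_i / (W_i^T Sigma_i^-1 W_i)

has unit gain on its own channel (V_i^T W_i = 1). On held-out data,
C2 = V^T B2. Reconstructions are interpolated to a 1° grid over the 180°
orientation space, circularly shifted so the trial's label sits at 0°, and
reduced to the scalar information metric R: the real part of the mean
channel-response phasor with orientation-doubled angles,

    z = mean_k(C_k * exp(2 i psi_k)),   R = |z| cos(arg z) = Re(z).

R is 0 for a flat reconstruction, positive when response mass concentrates
at the aligned center, and negative when it concentrates orthogonally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import ChannelBasis, design_matrix
from .delay import DelayPattern

logger = logging.getLogger(__name__)

CURVE_GRID = np.arange(180.0)  # 1° grid; index 0 is the aligned center


@dataclass
class IEMFilters:
    """Trained weights and optimal filters for one training fold."""

    W: np.ndarray                 # (m voxels, k channels)
    V: np.ndarray                 # (m voxels, k channels)
    Sigma_inv: np.ndarray | None  # (k, m, m) regularized inverse covariances
    shrinkage: np.ndarray         # (k,) shrinkage coefficients in [0, 1]
    n_train: int
    covariance: str = "shrinkage"


@dataclass
class Reconstruction:
    """Aligned channel-response curves and the information metric R."""

    curves: np.ndarray            # (n trials, 180), center at index 0
    R: np.ndarray                 # (n trials,)
    alignment_label: str = "cued"
    labels: np.ndarray | None = None

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    @property
    def mean_R(self) -> float:
        return float(self.R.mean())


def estimate_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """OLS encoding weights W = B1 C1^T (C1 C1^T)^-1, shape (m, k).

    Falls back to the pseudo-inverse with a warning when the channel
    design is rank-deficient.
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    if B1.shape[1] != C1.shape[1]:
        raise ValueError("B1 and C1 must share the trial dimension")
    gram = C1 @ C1.T
    if np.linalg.matrix_rank(C1) < C1.shape[0]:
        logger.warning("rank-deficient channel design; using pseudo-inverse")
        return B1 @ C1.T @ np.linalg.pinv(gram)
    return np.linalg.solve(gram.T, (B1 @ C1.T).T).T


def shrinkage_covariance(eps: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic shrinkage of the residual covariance toward a scaled identity.

    The raw covariance is S = eps eps^T / (n - 1) (residuals are model
    errors and are not re-centered). The Ledoit-Wolf-style coefficient

        lambda = min(1, b^2 / d^2),
        d^2 = ||S - mu I||_F^2,  mu = tr(S)/m,
        b^2 = min(d^2, (1/n^2) sum_t ||x_t x_t^T - S||_F^2)

    blends S with mu*I, guaranteeing a well-conditioned estimate at small
    sample sizes and vanishing shrinkage as n grows. Returns (Sigma, lambda).
    """
    eps = np.asarray(eps, dtype=float)
    m, n = eps.shape
    if n < 2:
        raise ValueError("need at least 2 training trials")
    S = eps @ eps.T / (n - 1)
    mu = np.trace(S) / m
    d2 = float(np.sum((S - mu * np.eye(m)) ** 2))
    if d2 <= 0:
        return S, 0.0
    # (1/n^2) sum_t ||x x^T - S||^2 without forming n outer products
    sq_norms = np.sum(eps ** 2, axis=0)
    quad = np.einsum("it,ij,jt->t", eps, S, eps)
    b2_bar = (np.sum(sq_norms ** 2) - 2.0 * np.sum(quad)
              + n * float(np.sum(S ** 2))) / n ** 2
    lam = float(min(1.0, max(0.0, b2_bar / d2)))
    sigma = lam * mu * np.eye(m) + (1.0 - lam) * S
    return sigma, lam


def estimate_noise_filters(B1: np.ndarray, C1: np.ndarray, W: np.ndarray,
                           covariance: str = "shrinkage",
                           fallback_delta: float = 1e-8) -> IEMFilters:
    """Per-channel regularized noise covariances and optimal filters V.

    ``covariance='identity'`` skips the noise model entirely, reducing
    each filter to V_i = W_i / (W_i^T W_i). Degenerate channels (all-zero
    residuals or weights) fall back to Sigma_i = delta * I with a log entry.
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    W = np.asarray(W, dtype=float)
    m, k = W.shape
    n1 = B1.shape[1]
    V = np.empty_like(W)
    shrink = np.zeros(k)
    sig_inv = None

    if covariance == "identity":
        for i in range(k):
            wi = W[:, i]
            denom = wi @ wi
            if denom == 0:
                logger.warning("channel %d: zero weight vector; filter set to 0", i)
                V[:, i] = 0.0
            else:
                V[:, i] = wi / denom
        return IEMFilters(W=W, V=V, Sigma_inv=None, shrinkage=shrink,
                          n_train=n1, covariance="identity")
    if covariance != "shrinkage":
        raise ValueError(f"unknown covariance mode: {covariance!r}")

    sig_inv = np.empty((k, m, m))
    for i in range(k):
        wi = W[:, i]
        eps = B1 - np.outer(wi, C1[i, :])
        sigma, lam = shrinkage_covariance(eps)
        if not np.all(np.isfinite(sigma)) or np.trace(sigma) <= 0:
            logger.warning("channel %d: degenerate residuals; "
                           "falling back to %g * I", i, fallback_delta)
            sigma = fallback_delta * np.eye(m)
            lam = 1.0
        try:
            si = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            logger.warning("channel %d: singular covariance; "
                           "falling back to %g * I", i, fallback_delta)
            si = np.eye(m) / fallback_delta
            lam = 1.0
        denom = wi @ si @ wi
        if denom == 0:
            logger.warning("channel %d: zero weight vector; filter set to 0", i)
            V[:, i] = 0.0
        else:
            V[:, i] = (si @ wi) / denom
        sig_inv[i] = si
        shrink[i] = lam
    return IEMFilters(W=W, V=V, Sigma_inv=sig_inv, shrinkage=shrink,
                      n_train=n1, covariance="shrinkage")


def invert(filters: IEMFilters, B2: np.ndarray) -> np.ndarray:
    """Reconstructed channel responses C2 = V^T B2 (k x n_test)."""
    B2 = np.asarray(B2, dtype=float)
    if B2.shape[0] != filters.V.shape[0]:
        raise ValueError("test patterns' voxel dimension does not match training")
    return filters.V.T @ B2


def _interp_curve(values: np.ndarray, centers: np.ndarray,
                  query: np.ndarray) -> np.ndarray:
    """Circular linear interpolation from channel centers to query angles."""
    order = np.argsort(centers % 180.0)
    xs = (centers % 180.0)[order]
    ys = values[order]
    xs_ext = np.concatenate([xs, [xs[0] + 180.0]])
    ys_ext = np.concatenate([ys, [ys[0]]])
    q = xs[0] + (query - xs[0]) % 180.0
    return np.interp(q, xs_ext, ys_ext)


def align_reconstructions(C2: np.ndarray, labels, basis: ChannelBasis,
                          alignment_label: str = "cued") -> Reconstruction:
    """Interpolate channel responses to a 1° grid and center each trial at 0°.

    For each test trial, the k channel responses placed at their centers
    are circularly interpolated to the 180-point grid and rotated so the
    trial's orientation label maps to grid index 0. The per-trial R is
    computed from the aligned curve.
    """
    C2 = np.asarray(C2, dtype=float)
    labels = np.atleast_1d(np.asarray(labels, dtype=float))
    k, n = C2.shape
    if labels.size != n:
        raise ValueError("need one alignment label per test trial")
    centers = basis.centers_array
    curves = np.empty((n, CURVE_GRID.size))
    for t in range(n):
        query = (CURVE_GRID + labels[t]) % 180.0
        curves[t] = _interp_curve(C2[:, t], centers, query)
    R = information_metric(curves, CURVE_GRID)
    return Reconstruction(curves=curves, R=R,
                          alignment_label=alignment_label, labels=labels)


def information_metric(responses: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Scalar information R = Re(mean_k C_k exp(2 i psi_k)).

    ``responses`` may be a single response vector or a (trials x angles)
    matrix; ``angles_deg`` are the angles (degrees) at which the responses
    sit, already expressed relative to the aligned center. The factor 2
    encodes the 180° periodicity of orientation space.
    """
    responses = np.asarray(responses, dtype=float)
    psi = np.deg2rad(np.asarray(angles_deg, dtype=float))
    phasor = np.exp(2j * psi)
    z = responses @ phasor / psi.size
    return np.real(z)


def reblock(n_trials: int, block_size: int, seed: int) -> np.ndarray:
    """Seeded random partition of trials into consecutive blocks of fixed size."""
    if n_trials % block_size != 0:
        raise ValueError("block_size must divide the trial count")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    blocks = np.empty(n_trials, dtype=int)
    blocks[perm] = np.arange(n_trials) // block_size
    return blocks


def lobo_cv(patterns: DelayPattern, trials: pd.DataFrame, basis: ChannelBasis,
            condition: str = "cued", covariance: str = "shrinkage",
            seed: int | None = None, blocks: np.ndarray | None = None,
            label_column: str | None = None) -> Reconstruction:
    """Leave-one-block-out cross-validated reconstruction.

    For each fold, all blocks but one train W and the optimal filters
    under the chosen condition's orientation labels (``cued``, ``uncued``
    or a seeded ``shuffled`` permutation of the cued labels); the held-out
    block is decoded, so every trial is decoded exactly once. Trials and
    ``patterns`` rows must be aligned on trial_id order.
    """
    trials = trials.sort_values("trial_id").reset_index(drop=True)
    if not np.array_equal(trials["trial_id"].to_numpy(), patterns.trial_ids):
        raise ValueError("patterns and trial table disagree on trial ids")
    n = len(trials)
    if condition == "cued":
        labels = trials["theta_cued"].to_numpy(dtype=float)
    elif condition == "uncued":
        labels = trials["theta_uncued"].to_numpy(dtype=float)
    elif condition == "shuffled":
        if seed is None:
            raise ValueError("shuffled condition requires a seed")
        rng = np.random.default_rng(seed)
        labels = rng.permutation(trials["theta_cued"].to_numpy(dtype=float))
    elif condition == "custom":
        if label_column is None:
            raise ValueError("custom condition requires label_column")
        labels = trials[label_column].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown condition: {condition!r}")

    block_ids = trials["block"].to_numpy() if blocks is None \
        else np.asarray(blocks)
    uniq = np.unique(block_ids)
    if uniq.size < 2:
        raise ValueError("leave-one-block-out needs at least 2 blocks")

    B = patterns.data.T  # voxels x trials
    C2_all = np.empty((basis.n_channels, n))
    decoded = np.zeros(n, dtype=bool)
    for b in uniq:
        test = block_ids == b
        train = ~test
        train_labels = labels[train]
        if np.unique(np.round(train_labels, 6)).size < basis.n_channels:
            logger.warning("fold %s: training labels span fewer orientations "
                           "than channels", b)
        C1 = design_matrix(basis, train_labels)
        W = estimate_weights(B[:, train], C1)
        filters = estimate_noise_filters(B[:, train], C1, W,
                                         covariance=covariance)
        C2_all[:, test] = invert(filters, B[:, test])
        decoded |= test
    assert decoded.all()
    return align_reconstructions(C2_all, labels, basis,
                                 alignment_label=condition)
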
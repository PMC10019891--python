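"""Stimulus-based representational similarity analysis.

Trial-pair neural similarity (cosine similarity between delay-period voxel
patterns) is compared with a stimulus similarity model (180 minus the
circular orientation distance between the trials' labels) by Spearman rank
correlation over the lower triangle, Fisher-z transformed for group-level
inference. A second-order variant correlates two regions' neural
similarity structures with each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .circ import orientation_distance
from .delay import DelayPattern

logger = logging.getLogger(__name__)

FISHER_RHO_CLIP = 1.0 - 1e-7


@dataclass
class SimilarityAssociation:
    rho: float
    fisher_z: float
    n_pairs: int
    condition: str = ""


def neural_similarity(patterns) -> np.ndarray:
    """Pairwise cosine similarity of trial patterns (rows).

    Zero-norm rows are flagged; their similarities are reported as 0.
    """
    X = patterns.data if isinstance(patterns, DelayPattern) \
        else np.asarray(patterns, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    dead = norms == 0
    if dead.any():
        logger.warning("%d all-zero pattern row(s); similarities set to 0",
                       int(dead.sum()))
    safe = np.where(dead, 1.0, norms)
    Xn = X / safe[:, None]
    M = Xn @ Xn.T
    M[dead, :] = 0.0
    M[:, dead] = 0.0
    return np.clip(M, -1.0, 1.0)


def stimulus_similarity(thetas) -> np.ndarray:
    """Feature-space similarity: 180 - circular orientation distance.

    Distances live in [0, 90] on the 180°-periodic orientation circle, so
    similarities lie in [90, 180]; identical labels score 180. Only the
    rank structure matters downstream.
    """
    t = np.asarray(thetas, dtype=float)
    return 180.0 - orientation_distance(t[:, None], t[None, :])


def lower_triangle(M: np.ndarray) -> np.ndarray:
    """Lower-triangle entries (excluding the diagonal) as a vector."""
    M = np.asarray(M)
    i, j = np.tril_indices(M.shape[0], k=-1)
    return M[i, j]


def similarity_association(neural: np.ndarray,
                           stimulus: np.ndarray,
                           condition: str = "") -> SimilarityAssociation:
    """Spearman rank correlation between the two similarity structures.

    Average ranks resolve ties; rho is Fisher-z transformed
    (z = atanh(rho)) with |rho| clipped just below 1 to keep z finite.
    A constant vector makes the correlation undefined; the result is
    flagged with NaN.
    """
    a = lower_triangle(neural)
    b = lower_triangle(stimulus)
    if a.size != b.size:
        raise ValueError("similarity matrices must have matching shapes")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("constant similarity vector; association undefined")
        return SimilarityAssociation(rho=np.nan, fisher_z=np.nan,
                                     n_pairs=a.size, condition=condition)
    rho = float(sps.spearmanr(a, b).statistic)
    z = float(np.arctanh(np.clip(rho, -FISHER_RHO_CLIP, FISHER_RHO_CLIP)))
    return SimilarityAssociation(rho=rho, fisher_z=z, n_pairs=a.size,
                                 condition=condition)


def subject_association(patterns: DelayPattern, thetas,
                        condition: str = "") -> SimilarityAssociation:
    """Convenience: neural vs. stimulus similarity for one subject/ROI."""
    return similarity_association(neural_similarity(patterns),
                                  stimulus_similarity(thetas),
                                  condition=condition)


def cross_region_similarity(patterns_a: DelayPattern,
                            patterns_b: DelayPattern) -> float:
    """Second-order similarity between two regions' trial-pattern geometry.

    Spearman correlation between the lower triangles of the two regions'
    neural similarity matrices (computed on the same trials).
    """
    if not np.array_equal(patterns_a.trial_ids, patterns_b.trial_ids):
        raise ValueError("regions must cover the same trials")
    sa = neural_similarity(patterns_a)
    sb = neural_similarity(patterns_b)
    return float(sps.spearmanr(lower_triangle(sa), lower_triangle(sb)).statistic)
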
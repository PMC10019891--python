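"""Subject-level group statistics.

Paired t-tests with Cohen's d on within-subject differences, subject-level
bootstrap p values (resampling subjects with replacement), Bonferroni
correction, the 2x2 cue-by-region interaction (equivalent to a one-sample
test on the per-subject difference-of-differences), the balanced
small-vs-larger-error resampling contrast, and across-subject correlations
between measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GroupResult:
    t: float
    df: int
    p_two_tailed: float
    cohen_d: float
    p_bootstrap: float | None = None
    p_bootstrap_label: str | None = None
    p_bonferroni: float | None = None
    n_iterations: int | None = None
    seed: int | None = None
    degenerate: bool = False


def paired_test(values_a, values_b) -> GroupResult:
    """Two-tailed paired t-test with Cohen's d on the paired differences.

    d = mean(diff) / SD(diff), sample SD (ddof=1). Zero-variance nonzero
    differences are flagged as degenerate (infinite t).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must match and have n >= 2")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return GroupResult(t=0.0, df=n - 1, p_two_tailed=1.0, cohen_d=0.0)
        logger.warning("constant nonzero paired differences: degenerate t")
        sign = np.sign(diff.mean())
        return GroupResult(t=float(sign * np.inf), df=n - 1,
                           p_two_tailed=0.0, cohen_d=float(sign * np.inf),
                           degenerate=True)
    res = sps.ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return GroupResult(t=float(res.statistic), df=n - 1,
                       p_two_tailed=float(res.pvalue), cohen_d=d)


def one_sample_test(values, popmean: float = 0.0) -> GroupResult:
    """Two-tailed one-sample t-test against ``popmean`` with Cohen's d."""
    v = np.asarray(values, dtype=float)
    return paired_test(v, np.full_like(v, popmean))


def bootstrap_p(values, statistic=np.mean, n_iter: int = 1000,
                seed: int = 0) -> tuple[float, str]:
    """Empirical two-tailed bootstrap p value for a statistic being 0.

    Subjects are resampled with replacement ``n_iter`` times;
    p = 2 * min(frac <= 0, frac >= 0) of the resampled statistic, floored
    at 1/n_iter. Returns (p, label) where the label renders values below
    1/n_iter as e.g. "<0.001".
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap requires n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    stats = np.apply_along_axis(statistic, 1, v[idx])
    frac_le = np.mean(stats <= 0)
    frac_ge = np.mean(stats >= 0)
    p = 2.0 * min(frac_le, frac_ge)
    floor = 1.0 / n_iter
    if p < floor:
        return floor, f"<{floor:g}"
    return float(min(p, 1.0)), f"{min(p, 1.0):g}"


def bonferroni(p_values, alpha: float = 0.05, m: int | None = None):
    """Bonferroni-adjusted p values and rejection decisions.

    ``m`` defaults to the number of p values (the comparison family, e.g.
    the number of ROIs tested); p_adj = min(1, m * p), reject if
    p_adj < alpha.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size < 1:
        raise ValueError("need at least one p value")
    fam = p.size if m is None else int(m)
    p_adj = np.minimum(1.0, fam * p)
    return p_adj, p_adj < alpha


def interaction_2x2(cued_a, uncued_a, cued_b, uncued_b) -> dict:
    """Within-subject 2x2 cue-by-region interaction.

    The per-subject interaction contrast is
    (cued - uncued)_regionA - (cued - uncued)_regionB; its one-sample t
    squared is the repeated-measures F(1, n-1) for the interaction.
    Returns {"F", "df", "p", "t", "contrast"}.
    """
    arrs = [np.asarray(x, dtype=float)
            for x in (cued_a, uncued_a, cued_b, uncued_b)]
    n = arrs[0].size
    if any(a.shape != (n,) for a in arrs) or n < 2:
        raise ValueError("all four cells must be complete per subject")
    contrast = (arrs[0] - arrs[1]) - (arrs[2] - arrs[3])
    res = one_sample_test(contrast)
    F = res.t ** 2
    p = float(sps.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
    return {"F": float(F), "df": (1, n - 1), "p": p, "t": res.t,
            "contrast": contrast}


def balanced_resample_mean(small_values, n_draw: int, n_iter: int = 5000,
                           seed: int = 0) -> float:
    """Mean of ``n_draw``-sized subsets of the small-error pool.

    Each iteration draws ``n_draw`` trials without replacement from the
    small-error values and averages them; the estimate is the average over
    iterations, giving a trial-count-balanced small-error summary.
    """
    v = np.asarray(small_values, dtype=float)
    if n_draw < 1 or n_draw > v.size:
        raise ValueError("n_draw must lie in [1, len(small_values)]")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_iter, v.size))
    idx = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
    return float(v[idx].mean(axis=1).mean())


def error_linked_contrast(trial_R: np.ndarray, labels: np.ndarray,
                          n_iter: int = 5000, seed: int = 0,
                          min_larger: int = 2) -> tuple[float, float] | None:
    """Balanced small- vs larger-error reconstruction summary, one subject.

    Draws |larger| trials from the small-error pool (without replacement)
    ``n_iter`` times and averages, yielding a small-error estimate based
    on as many trials as the larger-error estimate. Returns
    (balanced_small_mean, larger_mean), or None when the subject lacks
    ``min_larger`` larger-error trials (excluded with a log entry).
    """
    R = np.asarray(trial_R, dtype=float)
    labels = np.asarray(labels)
    small = R[labels == "small"]
    larger = R[labels == "larger"]
    if larger.size < min_larger or small.size < larger.size:
        logger.warning("subject excluded from error-linked contrast: "
                       "%d small, %d larger trials", small.size, larger.size)
        return None
    bal = balanced_resample_mean(small, n_draw=larger.size,
                                 n_iter=n_iter, seed=seed)
    return bal, float(larger.mean())


def correlate_measures(per_subject_a, per_subject_b) -> tuple[float, float]:
    """Across-subject Pearson correlation (r, two-tailed p)."""
    a = np.asarray(per_subject_a, dtype=float)
    b = np.asarray(per_subject_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired per-subject values with n >= 3")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
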
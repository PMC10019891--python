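"""Circular recall errors and the trial categorization linking decoding to behavior.

Recall error is the signed angular difference between the reported and the
cued orientation on the 180°-periodic orientation circle, mapped to
[-90, 90). Trials are categorized by absolute error into ``small``
(< 20°, within one neighboring stimulus), ``larger`` (20° up to an upper
cut-off: either 3 SD of the pooled raw-error distribution or a fixed 45°),
and ``excluded`` (beyond the cut-off; plausibly attentional lapses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circ import signed_orientation_diff


@dataclass
class TrialCategorization:
    labels: np.ndarray  # per trial: "small" | "larger" | "excluded"
    small_cut: float
    upper_rule: str  # "three_sd" | "fixed"
    upper_value: float

    def counts(self) -> dict:
        lab, n = np.unique(self.labels, return_counts=True)
        out = {"small": 0, "larger": 0, "excluded": 0}
        out.update(dict(zip(lab.tolist(), n.tolist())))
        return out


def recall_error(reported, target):
    """Signed recall error in degrees, in [-90, 90).

    Computed as ((reported - target + 90) mod 180) - 90; the orientation
    space is 180°-periodic, so e.g. a 170° report of a 10° target is an
    error of -20°, and a report exactly orthogonal to the target maps to
    the boundary value -90.
    """
    return signed_orientation_diff(reported, target)


def aggregate_error_sd(errors) -> float:
    """Ordinary (linear) SD of the pooled signed recall errors.

    The raw error distribution lives on [-90, 90); its empirical SD is
    taken linearly (sample SD, ddof=1), not as a circular dispersion.
    """
    e = np.asarray(errors, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("need at least 2 errors to compute an SD")
    return float(np.std(e, ddof=1))


def categorize_trials(abs_errors, small_cut: float = 20.0,
                      upper_rule: str = "three_sd",
                      pooled_sd: float | None = None,
                      upper_value: float = 45.0) -> TrialCategorization:
    """Label trials small / larger / excluded by absolute recall error.

    ``small``: abs error < small_cut. ``larger``: small_cut <= abs error
    <= upper bound (inclusive), with the bound either 3 * pooled_sd
    (``three_sd``) or a fixed ``upper_value`` (default 45°). Everything
    beyond is ``excluded``.
    """
    e = np.abs(np.asarray(abs_errors, dtype=float))
    if upper_rule == "three_sd":
        if pooled_sd is None:
            raise ValueError("three_sd rule requires pooled_sd")
        upper = 3.0 * float(pooled_sd)
    elif upper_rule == "fixed":
        upper = float(upper_value)
    else:
        raise ValueError(f"unknown upper_rule: {upper_rule!r}")
    if small_cut >= upper:
        raise ValueError("small_cut must be below the upper bound")
    labels = np.where(e < small_cut, "small",
                      np.where(e <= upper, "larger", "excluded"))
    return TrialCategorization(labels=labels, small_cut=small_cut,
                               upper_rule=upper_rule, upper_value=upper)


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach signed and absolute recall errors to a trial table."""
    out = trials.copy()
    out["signed_error"] = recall_error(out["reported"].to_numpy(),
                                       out["theta_cued"].to_numpy())
    out["abs_error"] = np.abs(out["signed_error"])
    return out
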
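"""Delay-period pattern extraction.

Run-wise time series are z-scored per voxel within each run, then each
trial's 5 delay TRs are collapsed with a triangular TENT-style weight
vector (0, 1, 2, 1, 0) — a normalized weighted mean emphasizing mid-delay
activity without any hemodynamic model fit. Shifting the peak of the
weight window across time gives the time-varying variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import BoldRun

logger = logging.getLogger(__name__)

TENT_WEIGHTS = (0.0, 1.0, 2.0, 1.0, 0.0)


@dataclass
class DelayPattern:
    """Trials x voxels matrix of delay activity for one ROI and subject."""

    data: np.ndarray
    trial_ids: np.ndarray
    roi_id: str = "roi"
    subject_id: int = 0
    peak_shift: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.data.ndim != 2 or self.data.shape[0] != self.trial_ids.size:
            raise ValueError("data must be (n_trials, n_voxels) matching trial_ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("delay patterns must be finite")


def zscore_within_run(run: BoldRun, ddof: int = 0) -> BoldRun:
    """Standardize each voxel to mean 0, SD 1 across the run's TRs.

    The population SD convention (ddof=0) is the default. Zero-variance
    voxels are flagged with a warning and set to all-zero.
    """
    if run.data.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 TRs")
    mu = run.data.mean(axis=0)
    sd = run.data.std(axis=0, ddof=ddof)
    dead = sd == 0
    if dead.any():
        logger.warning("run %s: %d zero-variance voxel(s) set to 0",
                       run.run_id, int(dead.sum()))
    sd_safe = np.where(dead, 1.0, sd)
    z = (run.data - mu) / sd_safe
    z[:, dead] = 0.0
    return BoldRun(run_id=run.run_id, data=z,
                   event_map=[dict(ev) for ev in run.event_map])


def tent_delay_pattern(run: BoldRun, weights=TENT_WEIGHTS,
                       peak_shift: int = 0, epoch: str = "delay") -> np.ndarray:
    """Collapse each trial's epoch window to one pattern row.

    Row = sum_t w_t x_t / sum_t w_t over the trial's window TRs, with the
    whole window slid by ``peak_shift`` TRs. Output shape is
    (n_trials_in_run, n_voxels), in the run's trial order.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    n_tr = run.data.shape[0]
    rows = []
    for ev in run.event_map:
        span = ev[epoch]
        if len(span) != w.size:
            raise ValueError(
                f"trial {ev['trial_id']}: {epoch} window has {len(span)} TRs, "
                f"expected {w.size}")
        idx = np.asarray(span, dtype=int) + peak_shift
        if idx.min() < 0 or idx.max() >= n_tr:
            raise ValueError(
                f"trial {ev['trial_id']}: shifted window {idx.tolist()} "
                f"leaves the run (0..{n_tr - 1})")
        rows.append(w @ run.data[idx, :] / w.sum())
    return np.vstack(rows)


def extract_delay_patterns(runs: list[BoldRun], weights=TENT_WEIGHTS,
                           peak_shift: int = 0, zscore: bool = True,
                           ddof: int = 0, epoch: str = "delay",
                           roi_id: str = "roi",
                           subject_id: int = 0) -> DelayPattern:
    """Full extraction pipeline over a subject's runs.

    Optionally z-scores within each run, applies the TENT weighting per
    trial, and stacks rows across runs in trial order.
    """
    mats, ids = [], []
    for run in runs:
        r = zscore_within_run(run, ddof=ddof) if zscore else run
        mats.append(tent_delay_pattern(r, weights=weights,
                                       peak_shift=peak_shift, epoch=epoch))
        ids.extend(run.trial_ids)
    data = np.vstack(mats)
    order = np.argsort(ids)
    return DelayPattern(data=data[order], trial_ids=np.asarray(ids)[order],
                        roi_id=roi_id, subject_id=subject_id,
                        peak_shift=peak_shift)
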
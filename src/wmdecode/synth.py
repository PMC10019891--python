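"""Synthetic retro-cue orientation working-memory data.

Emulates the task and signal structure the analysis pipeline assumes: 16
subjects each complete 10 blocks of 18 trials; on every trial two gratings
with orientations drawn from 9 bases (0-160° in 20° steps, jittered by
±1-5°) are studied in sequence, a retro-cue selects one, and after a 5-TR
delay the cued orientation is reproduced with circular Gaussian error plus
occasional uniform lapses. Voxel time series carry cued-item channel signal
during the delay, both items' signal at encoding, and spatially correlated
Gaussian noise elsewhere. Hemodynamic convolution is deliberately not
simulated: the analysis consumes raw delay TRs.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .basis import ChannelBasis, channel_response
from .circ import orientation_distance, wrap_orientation

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "trial_id", "block", "base_item1", "base_item2",
    "theta_item1", "theta_item2", "cue", "theta_cued", "theta_uncued",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design and signal parameters for the simulator.

    Defaults mirror the emulated study: 16 subjects, 10 blocks x 18 trials,
    9 base orientations 20° apart, ±1-5° jitter, items >20° apart (on the
    20° grid this forces base separations of at least 40°), a 5-TR delay.
    ``snr_*`` scale the noiseless channel signal relative to a unit noise SD;
    ``recall_sd`` / ``lapse_rate`` parameterize the behavioral mixture
    (15° and 0.03 jointly give a pooled raw-error SD near the ~17° scale
    typical of this task).
    """

    n_subjects: int = 16
    n_blocks: int = 10
    trials_per_block: int = 18
    base_orientations: tuple[float, ...] = tuple(float(c) for c in range(0, 180, 20))
    jitter_range: tuple[float, float] = (1.0, 5.0)
    min_item_separation: float = 20.0
    n_voxels: int = 40
    snr_cued: float = 0.85
    snr_uncued: float = 0.0
    snr_encoding: float = 0.85
    noise_sd: float = 1.0
    noise_cov_strength: float = 1.0
    recall_sd: float = 15.0
    lapse_rate: float = 0.03
    n_delay_trs: int = 5
    n_baseline_trs: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_blocks, self.trials_per_block,
               self.n_voxels, self.n_delay_trs, self.n_baseline_trs) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        for name in ("snr_cued", "snr_uncued", "snr_encoding", "noise_sd",
                     "noise_cov_strength", "recall_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.jitter_range
        if not 0 <= lo <= hi:
            raise ValueError("jitter_range must satisfy 0 <= lo <= hi")
        bases = wrap_orientation(np.asarray(self.base_orientations))
        if np.unique(bases).size != bases.size:
            raise ValueError("base orientations must be distinct modulo 180")
        if bases.size > 1:
            gaps = np.diff(np.sort(bases))
            if not np.allclose(gaps, gaps[0]):
                raise ValueError("base orientations must be evenly spaced")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_orientations"] = list(d["base_orientations"])
        d["jitter_range"] = list(d["jitter_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "base_orientations" in d:
            d["base_orientations"] = tuple(d["base_orientations"])
        if "jitter_range" in d:
            d["jitter_range"] = tuple(d["jitter_range"])
        return cls(**d)


@dataclass
class BoldRun:
    """One acquisition run: a TRs x voxels matrix plus per-trial event map.

    ``event_map`` holds, for each trial in the run, the TR indices of its
    baseline, encoding, cue, delay (n_delay_trs TRs) and response epochs.
    """

    run_id: int
    data: np.ndarray
    event_map: list[dict]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be 2-D (TRs x voxels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run data must be finite")
        n_tr = self.data.shape[0]
        for ev in self.event_map:
            if any(t < 0 or t >= n_tr for t in ev["delay"]):
                raise ValueError(f"trial {ev['trial_id']}: delay span leaves the run")

    @property
    def trial_ids(self) -> list[int]:
        return [ev["trial_id"] for ev in self.event_map]

    def to_json_event_map(self) -> str:
        return json.dumps({"run_id": self.run_id, "events": self.event_map})


def generate_design(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a trial table: item orientations, jitters, and retro-cues.

    Base orientations of the two items are drawn uniformly subject to a
    strict circular separation constraint; jitter of uniform magnitude in
    ``jitter_range`` with random sign is added independently per item.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bases = np.asarray(config.base_orientations, dtype=float)
    k = bases.size
    dist = orientation_distance(bases[:, None], bases[None, :])
    allowed = dist > config.min_item_separation
    if not allowed.any():
        raise ValueError(
            "min_item_separation too large: no admissible orientation pair")

    n = config.n_trials
    rows = []
    lo, hi = config.jitter_range
    for t in range(n):
        i = rng.integers(k)
        j = rng.choice(np.flatnonzero(allowed[i]))
        jit = rng.uniform(lo, hi, size=2) * rng.choice([-1.0, 1.0], size=2)
        th1 = float(wrap_orientation(bases[i] + jit[0]))
        th2 = float(wrap_orientation(bases[j] + jit[1]))
        cue = int(rng.integers(1, 3))
        rows.append({
            "trial_id": t,
            "block": t // config.trials_per_block,
            "base_item1": bases[i],
            "base_item2": bases[j],
            "theta_item1": th1,
            "theta_item2": th2,
            "cue": cue,
            "theta_cued": th1 if cue == 1 else th2,
            "theta_uncued": th2 if cue == 1 else th1,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_tuning_weights(n_voxels: int, basis: ChannelBasis,
                            seed: int = 0, mode: str = "tuned") -> np.ndarray:
    """Ground-truth voxel tuning weights, shape (n_voxels, k channels).

    ``tuned`` gives each voxel a preferred orientation (the first k voxels
    cover the k channel centers so every channel has a maximally loading
    voxel) with a broad nonnegative tuning profile, a random gain, and a
    small nonnegative perturbation. ``one_hot`` makes voxel v respond to
    channel v mod k only.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    k = basis.n_channels
    if mode == "one_hot":
        w = np.zeros((n_voxels, k))
        w[np.arange(n_voxels), np.arange(n_voxels) % k] = 1.0
        return w
    if mode != "tuned":
        raise ValueError(f"unknown mode: {mode!r}")
    rng = np.random.default_rng(seed)
    centers = basis.centers_array
    pref = np.empty(n_voxels)
    m = min(n_voxels, k)
    pref[:m] = centers[:m]
    if n_voxels > k:
        pref[k:] = rng.uniform(0.0, 180.0, size=n_voxels - k)
    profile_basis = ChannelBasis(centers=tuple(centers), exponent=2.0)
    w = channel_response(profile_basis, pref).T  # (n_voxels, k)
    gain = rng.uniform(0.5, 1.5, size=(n_voxels, 1))
    w = w * gain + rng.uniform(0.0, 0.02, size=(n_voxels, k))
    return w


def make_noise_covariance(n_voxels: int, strength: float, rng) -> np.ndarray:
    """Random SPD spatial covariance: identity + strength * A A^T / n."""
    a = rng.standard_normal((n_voxels, n_voxels))
    return np.eye(n_voxels) + strength * (a @ a.T) / n_voxels


def generate_bold(trials: pd.DataFrame, weights: np.ndarray,
                  config: SimConfig, basis: ChannelBasis | None = None,
                  seed: int | None = None,
                  gain: np.ndarray | None = None) -> list[BoldRun]:
    """Forward-simulate run-wise voxel time series, B = W C + N.

    Delay TRs carry ``snr_cued * W c(theta_cued) + snr_uncued * W
    c(theta_uncued)``; the encoding TR carries both items at
    ``snr_encoding``; all TRs receive additive Gaussian noise with the
    configured spatial covariance. ``gain``, if given, multiplies the
    delay-period signal per trial (used to couple decodability to recall
    precision).
    """
    basis = basis if basis is not None else ChannelBasis()
    weights = np.asarray(weights, dtype=float)
    if weights.shape[1] != basis.n_channels:
        raise ValueError("weights' channel count does not match the basis")
    if weights.shape[0] != config.n_voxels:
        raise ValueError("weights' voxel count does not match the config")
    n = len(trials)
    if gain is None:
        gain = np.ones(n)
    gain = np.asarray(gain, dtype=float)
    if gain.shape != (n,):
        raise ValueError("gain must hold one value per trial")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = make_noise_covariance(config.n_voxels, config.noise_cov_strength, rng)
    chol = np.linalg.cholesky(cov)

    trs_per_trial = config.n_baseline_trs + 1 + 1 + config.n_delay_trs + 1
    runs = []
    for run_id, block in trials.groupby("block"):
        n_tr = trs_per_trial * len(block)
        data = np.zeros((n_tr, config.n_voxels))
        events = []
        for pos, (_, tr) in enumerate(block.iterrows()):
            t0 = pos * trs_per_trial
            base_idx = list(range(t0, t0 + config.n_baseline_trs))
            enc = t0 + config.n_baseline_trs
            cue_tr = enc + 1
            delay = list(range(cue_tr + 1, cue_tr + 1 + config.n_delay_trs))
            resp = delay[-1] + 1
            g = gain[int(tr["trial_id"])]
            c_cued = channel_response(basis, tr["theta_cued"])
            c_uncued = channel_response(basis, tr["theta_uncued"])
            delay_sig = (config.snr_cued * g * (weights @ c_cued)
                         + config.snr_uncued * (weights @ c_uncued))
            data[delay, :] += delay_sig[None, :]
            c1 = channel_response(basis, tr["theta_item1"])
            c2 = channel_response(basis, tr["theta_item2"])
            data[enc, :] += config.snr_encoding * (weights @ (c1 + c2))
            events.append({
                "trial_id": int(tr["trial_id"]),
                "baseline": base_idx,
                "encoding": [enc],
                "cue": [cue_tr],
                "delay": delay,
                "response": [resp],
            })
        noise = config.noise_sd * rng.standard_normal((n_tr, config.n_voxels)) @ chol.T
        data += noise
        runs.append(BoldRun(run_id=int(run_id), data=data, event_map=events))
    return runs


def generate_behavior(trials: pd.DataFrame, config: SimConfig,
                      seed: int | None = None,
                      recall_sd: np.ndarray | None = None) -> pd.DataFrame:
    """Append reported orientations and lapse flags to a trial table.

    Non-lapse reports are theta_cued plus wrapped Gaussian noise
    (SD ``recall_sd``); lapses (probability ``lapse_rate``) are uniform on
    [0, 180). ``recall_sd`` may be a per-trial vector to couple recall
    precision to simulated signal strength.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(trials)
    sd = np.full(n, config.recall_sd) if recall_sd is None \
        else np.asarray(recall_sd, dtype=float)
    if sd.shape != (n,):
        raise ValueError("recall_sd must be a scalar config value or one per trial")
    lapse = rng.random(n) < config.lapse_rate
    noise = rng.standard_normal(n) * sd
    reported = wrap_orientation(trials["theta_cued"].to_numpy() + noise)
    reported[lapse] = rng.uniform(0.0, 180.0, size=int(lapse.sum()))
    out = trials.copy()
    out["reported"] = reported
    out["lapse_flag"] = lapse
    return out


def simulate_subject(config: SimConfig, subject_seed: int,
                     couple_behavior: bool = False,
                     coupling_spread: float = 0.7,
                     weights: np.ndarray | None = None,
                     basis: ChannelBasis | None = None):
    """Simulate one subject: (trial table with behavior, runs, weights).

    With ``couple_behavior``, each trial gets an attention gain g drawn
    uniformly from [1-spread, 1+spread]; the delay signal is scaled by g
    and the recall SD by 1/g, so well-decoded trials are recalled more
    precisely.
    """
    basis = basis if basis is not None else ChannelBasis()
    ss = np.random.SeedSequence(subject_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    trials = generate_design(config, seed=seeds[0])
    if weights is None:
        weights = generate_tuning_weights(config.n_voxels, basis, seed=seeds[1])
    if couple_behavior:
        rng = np.random.default_rng(seeds[2])
        g = rng.uniform(1.0 - coupling_spread, 1.0 + coupling_spread,
                        size=len(trials))
        runs = generate_bold(trials, weights, config, basis=basis,
                             seed=seeds[3], gain=g)
        trials = generate_behavior(trials, config, seed=seeds[4],
                                   recall_sd=config.recall_sd / g)
    else:
        runs = generate_bold(trials, weights, config, seed=seeds[3], basis=basis)
        trials = generate_behavior(trials, config, seed=seeds[4])
    return trials, runs, weights


def subject_seeds(config: SimConfig) -> list[int]:
    """Per-subject seeds derived deterministically from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] % (2**31))
            for s in ss.spawn(config.n_subjects)]
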
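"""Readers and writers for the pipeline's on-disk formats.

Tables are CSV (comma-separated, header row, UTF-8, "." decimal); matrices
are delimited text; event maps, provenance and results are JSON; configs
are YAML. Volumetric input (4-D NIfTI plus an integer ROI mask) is
flattened to TRs x voxels in native volume index order (C order over the
spatial axes), which is stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .delay import DelayPattern
from .synth import BoldRun, SimConfig

logger = logging.getLogger(__name__)


# -- trial tables ------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trial_id", "block", "theta_cued"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} lacks columns: {sorted(missing)}")
    return df


# -- runs and patterns -------------------------------------------------------

def write_bold_run(run: BoldRun, matrix_path, events_path) -> None:
    np.savetxt(matrix_path, run.data, delimiter=",")
    Path(events_path).write_text(run.to_json_event_map())


def read_bold_run(matrix_path, events_path) -> BoldRun:
    data = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    meta = json.loads(Path(events_path).read_text())
    return BoldRun(run_id=meta["run_id"], data=data, event_map=meta["events"])


def write_delay_pattern(pattern: DelayPattern, matrix_path, sidecar_path,
                        provenance: dict | None = None) -> None:
    np.savetxt(matrix_path, pattern.data, delimiter=",")
    meta = {
        "trial_ids": pattern.trial_ids.tolist(),
        "roi_id": pattern.roi_id,
        "subject_id": int(pattern.subject_id),
        "peak_shift": int(pattern.peak_shift),
        "provenance": provenance or {},
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_delay_pattern(matrix_path, sidecar_path) -> DelayPattern:
    data = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    meta = json.loads(Path(sidecar_path).read_text())
    return DelayPattern(data=data, trial_ids=np.asarray(meta["trial_ids"]),
                        roi_id=meta["roi_id"], subject_id=meta["subject_id"],
                        peak_shift=meta["peak_shift"])


def read_nifti_timeseries(volume_path, mask_path) -> np.ndarray:
    """Flatten a 4-D NIfTI volume to TRs x voxels inside a nonzero mask.

    Voxels are ordered by native volume index (C order over x, y, z).
    NaN voxels are dropped with a logged count; an empty mask is an error.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asanyarray(img.dataobj, dtype=float)
    mask = np.asanyarray(mask_img.dataobj) != 0
    if vol.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) volume")
    if mask.shape != vol.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    if not mask.any():
        raise ValueError("ROI mask selects no voxels")
    flat = vol.reshape(-1, vol.shape[3], order="C")
    ts = flat[mask.reshape(-1, order="C"), :].T  # TRs x voxels
    bad = ~np.all(np.isfinite(ts), axis=0)
    if bad.any():
        logger.warning("dropping %d non-finite voxel(s)", int(bad.sum()))
        ts = ts[:, ~bad]
    return ts


def read_patterns(path, fmt: str = "csv", **kwargs):
    """Load a pattern/time-series matrix in one of the supported formats."""
    if fmt == "csv":
        return np.loadtxt(path, delimiter=",", ndmin=2)
    if fmt == "npy":
        return np.load(path)
    if fmt == "nifti":
        return read_nifti_timeseries(path, kwargs["mask_path"])
    raise ValueError(f"unknown format: {fmt!r}")


# -- configs and provenance --------------------------------------------------

def write_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def read_config(path) -> SimConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return SimConfig.from_dict(data)


def config_hash(config: SimConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_provenance(path, config: SimConfig, stage: str,
                     extra: dict | None = None) -> None:
    from . import __version__

    meta = {"stage": stage, "config_hash": config_hash(config),
            "seed": config.seed, "version": __version__}
    meta.update(extra or {})
    Path(path).write_text(json.dumps(meta, indent=1))
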
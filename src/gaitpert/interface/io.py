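"""File formats: trace/marker CSVs, cohort directories, window stores.

Trace CSV schema: ``t,ax,ay,az,gx,gy,gz`` (header mandatory); marker CSV:
``trial_id,archetype_id,t_start,t_end``.  A cohort directory holds one
trace file per (participant, position, trial), one marker file per
(participant, trial) and a JSON manifest with seeds and parameters.
Window collections go to an HDF5 store.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .. import __version__
from ..synthgait import (
    PERT_TRIALS,
    POSITIONS,
    TRIALS,
    CohortDataset,
    GaitProfile,
    ImuTrace,
    PerturbationMarker,
    generate_profile,
)
from ..windowing import Window, WindowingConfig

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
MARKER_COLUMNS = ["trial_id", "archetype_id", "t_start", "t_end"]


def write_trace_csv(trace: ImuTrace, path) -> None:
    df = pd.DataFrame(
        np.column_stack([trace.timestamps, trace.accel.T, trace.gyro.T]),
        columns=TRACE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(
    path,
    participant_id: str = "",
    position_id: str = "L",
    trial_id: str = "gait",
    nominal_rate: float | None = None,
) -> ImuTrace:
    """Parse and validate a trace CSV.

    Missing columns and non-monotone timestamps raise errors that name the
    offending column or line; extra columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        raise ValueError(
            f"{path}: timestamps not strictly increasing at line {bad[0] + 3}"
        )
    if nominal_rate is None:
        nominal_rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 0.0
    return ImuTrace(
        participant_id=participant_id,
        position_id=position_id,
        trial_id=trial_id,
        timestamps=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float).T,
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float).T,
        nominal_rate=float(nominal_rate),
    )


def write_marker_csv(markers: Sequence[PerturbationMarker], path) -> None:
    pd.DataFrame(
        [(m.trial_id, m.archetype_id, m.t_start, m.t_end) for m in markers],
        columns=MARKER_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_marker_csv(path) -> List[PerturbationMarker]:
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        PerturbationMarker(
            trial_id=str(r.trial_id),
            archetype_id=int(r.archetype_id),
            t_start=float(r.t_start),
            t_end=float(r.t_end),
        )
        for r in df.itertuples()
    ]


def _trace_filename(pid: str, pos: str, trial: str) -> str:
    return f"trace_{pid}_{pos}_{trial}.csv"


def save_cohort(cohort: CohortDataset, out_dir, extra_params: Dict | None = None) -> Path:
    """Write a cohort directory (trace CSVs, marker CSVs, manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for (pid, pos, trial), trace in sorted(cohort.traces.items()):
        name = _trace_filename(pid, pos, trial)
        write_trace_csv(trace, out / name)
        files.append(name)
    for (pid, trial), mks in sorted(cohort.markers.items()):
        name = f"markers_{pid}_{trial}.csv"
        write_marker_csv(mks, out / name)
        files.append(name)
    manifest = {
        "version": __version__,
        "seed": cohort.seed,
        "amplitude_ratio": cohort.amplitude_ratio,
        "n_participants": len(cohort.participants),
        "participants": cohort.participant_ids,
        "positions": list(POSITIONS),
        "trials": list(TRIALS),
        "protocol": {
            "n_perturbations_per_trial": 9,
            "n_perturbation_trials": 3,
            "onset_gap_bounds_s": [20.0, 30.0],
        },
        "files": files,
    }
    if extra_params:
        manifest["parameters"] = extra_params
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out / "manifest.json"


def load_cohort(in_dir) -> CohortDataset:
    """Rebuild a CohortDataset from a cohort directory."""
    root = Path(in_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    seed = manifest["seed"]
    participants = [
        generate_profile(seed, idx)
        for idx in range(manifest["n_participants"])
    ]
    traces = {}
    markers = {}
    for pid in manifest["participants"]:
        for pos in manifest["positions"]:
            for trial in manifest["trials"]:
                traces[(pid, pos, trial)] = read_trace_csv(
                    root / _trace_filename(pid, pos, trial),
                    participant_id=pid,
                    position_id=pos,
                    trial_id=trial,
                )
        for trial in PERT_TRIALS:
            markers[(pid, trial)] = read_marker_csv(
                root / f"markers_{pid}_{trial}.csv"
            )
    return CohortDataset(
        participants=participants,
        traces=traces,
        markers=markers,
        seed=seed,
        amplitude_ratio=manifest.get("amplitude_ratio", 4.0),
    )


def save_windows(windows: Sequence[Window], cfg: WindowingConfig, path) -> None:
    """HDF5 window store: data (N, C, M) float32 + provenance datasets."""
    if not windows:
        raise ValueError("no windows to save")
    data = np.stack([w.data for w in windows]).astype(np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data, compression="gzip", compression_opts=1)
        f.create_dataset(
            "label", data=np.array([w.label for w in windows], dtype="S16")
        )
        f.create_dataset(
            "participant_id",
            data=np.array([w.participant_id for w in windows], dtype="S16"),
        )
        f.create_dataset(
            "position",
            data=np.array(["+".join(w.position_ids) for w in windows], dtype="S32"),
        )
        f.create_dataset(
            "trial", data=np.array([w.trial_id for w in windows], dtype="S16")
        )
        f.create_dataset(
            "start_time", data=np.array([w.start_time for w in windows])
        )
        f.create_dataset(
            "center_time",
            data=np.array(
                [w.center_time if w.center_time is not None else np.nan
                 for w in windows]
            ),
        )
        f.create_dataset(
            "window_index", data=np.array([w.window_index for w in windows])
        )
        for k, v in cfg.__dict__.items():
            f.attrs[k] = v


def load_windows(path) -> Tuple[List[Window], WindowingConfig]:
    with h5py.File(path, "r") as f:
        cfg = WindowingConfig(
            window_length=float(f.attrs["window_length"]),
            gait_step=float(f.attrs["gait_step"]),
            common_rate=float(f.attrs["common_rate"]),
            channel_set=str(f.attrs["channel_set"]),
        )
        data = f["data"][...]
        labels = [s.decode() for s in f["label"][...]]
        pids = [s.decode() for s in f["participant_id"][...]]
        poss = [tuple(s.decode().split("+")) for s in f["position"][...]]
        trials = [s.decode() for s in f["trial"][...]]
        starts = f["start_time"][...]
        centers = f["center_time"][...]
        indices = f["window_index"][...]
    windows = [
        Window(
            data=data[i],
            label=labels[i],
            participant_id=pids[i],
            position_ids=poss[i],
            trial_id=trials[i],
            start_time=float(starts[i]),
            center_time=None if np.isnan(centers[i]) else float(centers[i]),
            window_index=int(indices[i]),
        )
        for i in range(data.shape[0])
    ]
    return windows, cfg
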
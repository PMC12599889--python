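"""Trace synchronization and labeled two-second window extraction.

Traces from heterogeneous devices are linearly resampled onto a common
regular grid, then cut into fixed-length windows: gait windows by a
sliding window over the gait trial, perturbation windows centered on the
within-marker maximum of the acceleration norm.  Multi-position
conditions stack channels of time-aligned windows; standardization is
fitted on training windows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .synthgait import CHANNELS, ImuTrace, PerturbationMarker

__all__ = [
    "Window",
    "WindowingConfig",
    "WindowScaler",
    "resample",
    "acceleration_norm",
    "extract_gait_windows",
    "extract_perturbation_windows",
    "assemble_condition",
    "standardize",
]

logger = logging.getLogger(__name__)

LABEL_GAIT = "gait"
LABEL_PERTURBATION = "perturbation"


@dataclass
class WindowingConfig:
    """Window extraction parameters.

    window_length and gait_step in seconds; common_rate in Hz.
    channel_set selects accel+gyro (6 ch/position) or accel only (3).
    """

    window_length: float = 2.0
    gait_step: float = 1.0
    common_rate: float = 100.0
    channel_set: str = "accel_gyro"

    def __post_init__(self):
        if not 0 < self.gait_step <= self.window_length:
            raise ValueError("require 0 < gait_step <= window_length")
        if self.common_rate <= 0:
            raise ValueError("common_rate must be > 0")
        if self.channel_set not in ("accel_gyro", "accel_only"):
            raise ValueError(f"unknown channel_set {self.channel_set!r}")

    @property
    def n_samples(self) -> int:
        """Exact sample count M of every window."""
        return int(round(self.window_length * self.common_rate))

    @property
    def channels_per_position(self) -> int:
        return 6 if self.channel_set == "accel_gyro" else 3


@dataclass
class Window:
    """One labeled fixed-length multichannel segment."""

    data: np.ndarray  # (C, M)
    label: str  # gait | perturbation
    participant_id: str
    position_ids: Tuple[str, ...]
    trial_id: str
    start_time: float
    center_time: float | None = None  # perturbation windows only
    window_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.label not in (LABEL_GAIT, LABEL_PERTURBATION):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def key(self) -> Tuple[str, str, int]:
        """Alignment key shared across positions of one condition."""
        return (self.participant_id, self.trial_id, self.window_index)


def resample(trace: ImuTrace, common_rate: float) -> ImuTrace:
    """Linearly interpolate a trace onto a regular grid at ``common_rate``.

    The grid starts at the first input timestamp and never extrapolates
    beyond the last one.
    """
    if trace.n_samples < 2:
        raise ValueError("resampling requires at least 2 samples")
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    n_out = int(np.floor((t1 - t0) * common_rate)) + 1
    grid = t0 + np.arange(n_out) / common_rate
    accel = np.empty((3, n_out))
    gyro = np.empty((3, n_out))
    for i in range(3):
        accel[i] = np.interp(grid, trace.timestamps, trace.accel[i])
        gyro[i] = np.interp(grid, trace.timestamps, trace.gyro[i])
    return ImuTrace(
        participant_id=trace.participant_id,
        position_id=trace.position_id,
        trial_id=trace.trial_id,
        timestamps=grid,
        accel=accel,
        gyro=gyro,
        nominal_rate=common_rate,
    )


def acceleration_norm(trace: ImuTrace) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration channels."""
    return np.linalg.norm(trace.accel, axis=0)


def extract_gait_windows(trace: ImuTrace, cfg: WindowingConfig) -> List[Window]:
    """Sliding-window extraction over a (resampled) gait-type trial.

    Windows start at 0, gait_step, 2*gait_step, ... relative to the trace
    start; every window lies fully inside the trace.  A trace shorter than
    one window yields an empty list with a warning.
    """
    m = cfg.n_samples
    step = int(round(cfg.gait_step * cfg.common_rate))
    n = trace.n_samples
    if n < m:
        logger.warning(
            "trace %s/%s/%s shorter than one window (%d < %d samples); "
            "no gait windows extracted",
            trace.participant_id,
            trace.position_id,
            trace.trial_id,
            n,
            m,
        )
        return []
    chans = trace.channels()
    out = []
    for k, i0 in enumerate(range(0, n - m + 1, step)):
        out.append(
            Window(
                data=chans[:, i0 : i0 + m].copy(),
                label=LABEL_GAIT,
                participant_id=trace.participant_id,
                position_ids=(trace.position_id,),
                trial_id=trace.trial_id,
                start_time=float(trace.timestamps[i0]),
                window_index=k,
            )
        )
    return out


def extract_perturbation_windows(
    trace: ImuTrace,
    markers: Sequence[PerturbationMarker],
    cfg: WindowingConfig,
    anchor_trace: ImuTrace | None = None,
) -> List[Window]:
    """One window per marker, centered on the within-marker norm maximum.

    Within each marker interval the argmax of the acceleration norm is
    located (earliest sample on ties) and a window of exactly M samples is
    cut around it.  Windows that would overrun the trace are shifted
    inward, never padded.  ``anchor_trace`` lets a multi-sensor condition
    anchor all positions on one designated sensor's norm; it must share
    the trace's time grid.
    """
    anchor = anchor_trace if anchor_trace is not None else trace
    if anchor.n_samples != trace.n_samples:
        raise ValueError("anchor_trace must share the trace's sample grid")
    m = cfg.n_samples
    norm = acceleration_norm(anchor)
    t = trace.timestamps
    n = trace.n_samples
    chans = trace.channels()
    out = []
    for k, mk in enumerate(markers):
        if mk.t_start < t[0] - 1e-9 or mk.t_end > t[-1] + 1e-9:
            raise ValueError(
                f"marker (archetype {mk.archetype_id}, "
                f"[{mk.t_start:.3f}, {mk.t_end:.3f}] s) lies outside trace "
                f"range [{t[0]:.3f}, {t[-1]:.3f}] s"
            )
        lo = int(np.searchsorted(t, mk.t_start, side="left"))
        hi = int(np.searchsorted(t, mk.t_end, side="right"))
        if hi <= lo:
            raise ValueError(
                f"marker (archetype {mk.archetype_id}) contains no samples"
            )
        i_star = lo + int(np.argmax(norm[lo:hi]))  # argmax: earliest tie wins
        i0 = i_star - m // 2
        i0_clipped = min(max(i0, 0), n - m)
        if i0_clipped != i0:
            logger.info(
                "perturbation window for archetype %d shifted inward by %d "
                "samples to fit the trace",
                mk.archetype_id,
                abs(i0_clipped - i0),
            )
        i0 = i0_clipped
        out.append(
            Window(
                data=chans[:, i0 : i0 + m].copy(),
                label=LABEL_PERTURBATION,
                participant_id=trace.participant_id,
                position_ids=(trace.position_id,),
                trial_id=trace.trial_id,
                start_time=float(t[i0]),
                center_time=float(t[i_star]),
                window_index=k,
            )
        )
    return out


def crop_to_common_grid(traces: Sequence[ImuTrace]) -> List[ImuTrace]:
    """Truncate resampled traces of one trial to their shared grid length.

    Devices with different native rates end at slightly different times, so
    their resampled grids can differ by a sample; multi-sensor stacking
    needs identical grids.  All inputs must share start time and rate.
    """
    if not traces:
        return []
    t0 = traces[0].timestamps[0]
    rate = traces[0].nominal_rate
    for tr in traces[1:]:
        if abs(tr.timestamps[0] - t0) > 1e-9 or tr.nominal_rate != rate:
            raise ValueError("traces must share start time and rate")
    n = min(tr.n_samples for tr in traces)
    out = []
    for tr in traces:
        if tr.n_samples == n:
            out.append(tr)
        else:
            out.append(
                ImuTrace(
                    participant_id=tr.participant_id,
                    position_id=tr.position_id,
                    trial_id=tr.trial_id,
                    timestamps=tr.timestamps[:n],
                    accel=tr.accel[:, :n],
                    gyro=tr.gyro[:, :n],
                    nominal_rate=tr.nominal_rate,
                )
            )
    return out


def _select_channels(data: np.ndarray, channel_set: str) -> np.ndarray:
    return data[:3] if channel_set == "accel_only" else data


def assemble_condition(
    windows_by_position: Mapping[str, Sequence[Window]],
    positions: Sequence[str],
    channel_set: str = "accel_gyro",
) -> List[Window]:
    """Stack time-aligned windows of several positions channel-wise.

    All positions must provide the same (participant, trial, index) keys.
    The position listed first is the anchor: callers extract perturbation
    windows for every position against the first position's acceleration
    norm (see :func:`extract_perturbation_windows`'s ``anchor_trace``), so
    stacked windows cover one common time span.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    keyed: Dict[str, Dict[Tuple, Window]] = {}
    for pos in positions:
        if pos not in windows_by_position:
            raise ValueError(f"no windows supplied for position {pos!r}")
        keyed[pos] = {w.key: w for w in windows_by_position[pos]}
    ref_keys = list(keyed[positions[0]].keys())
    for pos in positions[1:]:
        missing = [k for k in ref_keys if k not in keyed[pos]]
        extra = [k for k in keyed[pos] if k not in keyed[positions[0]]]
        if missing or extra:
            raise ValueError(
                f"window keys of position {pos!r} do not match anchor "
                f"{positions[0]!r}: missing={missing[:5]}, extra={extra[:5]}"
            )
    out = []
    for key in ref_keys:
        parts = [keyed[pos][key] for pos in positions]
        ref = parts[0]
        data = np.concatenate(
            [_select_channels(w.data, channel_set) for w in parts], axis=0
        )
        out.append(
            Window(
                data=data,
                label=ref.label,
                participant_id=ref.participant_id,
                position_ids=tuple(positions),
                trial_id=ref.trial_id,
                start_time=ref.start_time,
                center_time=ref.center_time,
                window_index=ref.window_index,
            )
        )
    return out


@dataclass
class WindowScaler:
    """Per-channel z-standardization fitted on training windows only."""

    mean: np.ndarray = field(default=None)  # (C,)
    sd: np.ndarray = field(default=None)  # (C,)
    sd_floor: float = 1e-8

    def fit(self, windows: Sequence[Window]) -> "WindowScaler":
        if not windows:
            raise ValueError("cannot fit scaler on an empty training set")
        stack = np.stack([w.data for w in windows])  # (N, C, M)
        self.mean = stack.mean(axis=(0, 2))
        self.sd = np.maximum(stack.std(axis=(0, 2)), self.sd_floor)
        return self

    def transform(self, windows: Sequence[Window]) -> List[Window]:
        if self.mean is None:
            raise ValueError("scaler not fitted")
        out = []
        for w in windows:
            data = (w.data - self.mean[:, None]) / self.sd[:, None]
            out.append(
                Window(
                    data=data,
                    label=w.label,
                    participant_id=w.participant_id,
                    position_ids=w.position_ids,
                    trial_id=w.trial_id,
                    start_time=w.start_time,
                    center_time=w.center_time,
                    window_index=w.window_index,
                )
            )
        return out


def standardize(
    train: Sequence[Window],
    val: Sequence[Window] = (),
    test: Sequence[Window] = (),
) -> Tuple[List[Window], List[Window], List[Window], WindowScaler]:
    """Fit a scaler on ``train`` and transform all three collections."""
    scaler = WindowScaler().fit(train)
    return (
        scaler.transform(train),
        scaler.transform(val),
        scaler.transform(test),
        scaler,
    )


def windows_to_arrays(windows: Sequence[Window], dtype=np.float32):
    """(N, C, M) data tensor and 0/1 label vector (perturbation = 1)."""
    x = np.stack([w.data for w in windows]).astype(dtype)
    y = np.array([1 if w.label == LABEL_PERTURBATION else 0 for w in windows])
    return x, y
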
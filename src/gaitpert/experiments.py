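"""Experimental matrix: conditions x participant-level splits.

Runs the full comparison protocol: for every condition (single positions,
position combinations, acceleration-only variants) and every one of the
shared participant-level 70/15/15 splits, train one detector and score
precision/recall/F1 on the held-out test participants.  The same split
plans are reused across all conditions (paired design: the split index is
the repeated-measures subject of the downstream statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import windowing as wd
from .detector import ModelConfig, build_model, compute_class_weights, predict, train
from .synthgait import PERT_TRIALS, CohortDataset, ImuTrace, derive_seed
from .windowing import Window, WindowingConfig

__all__ = [
    "SplitPlan",
    "Condition",
    "EvalResult",
    "DEFAULT_CONDITIONS",
    "make_splits",
    "compute_metrics",
    "build_condition_windows",
    "run_condition",
    "run_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """One participant-level partition into train/validation/test."""

    split_id: int
    train_ids: Tuple[str, ...]
    val_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    seed: int

    def __post_init__(self):
        groups = (set(self.train_ids), set(self.val_ids), set(self.test_ids))
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError(
                        f"split {self.split_id}: overlapping partitions "
                        f"{sorted(groups[i] & groups[j])}"
                    )

    @property
    def all_ids(self) -> Tuple[str, ...]:
        return self.train_ids + self.val_ids + self.test_ids

    def partition_of(self, participant_id: str) -> str:
        if participant_id in self.train_ids:
            return "train"
        if participant_id in self.val_ids:
            return "val"
        if participant_id in self.test_ids:
            return "test"
        raise KeyError(participant_id)


@dataclass(frozen=True)
class Condition:
    """A named experimental condition: ordered positions + channel set."""

    name: str
    positions: Tuple[str, ...]
    channel_set: str = "accel_gyro"

    def __post_init__(self):
        if not self.positions:
            raise ValueError("condition needs at least one position")
        if self.channel_set not in ("accel_gyro", "accel_only"):
            raise ValueError(f"unknown channel_set {self.channel_set!r}")

    @property
    def n_channels(self) -> int:
        per = 6 if self.channel_set == "accel_gyro" else 3
        return per * len(self.positions)


#: The default 14-row experimental matrix: seven single positions, four
#: everyday-technology combinations, three acceleration-only conditions.
DEFAULT_CONDITIONS: Tuple[Condition, ...] = (
    Condition("Lumbar", ("L",)),
    Condition("Sternum", ("S",)),
    Condition("RHA", ("RHA",)),
    Condition("LHA", ("LHA",)),
    Condition("JP", ("JP",)),
    Condition("PP", ("PP",)),
    Condition("SB", ("SB",)),
    Condition("LHA+RHA", ("LHA", "RHA")),
    Condition("LHA+JP", ("LHA", "JP")),
    Condition("LHA+SB", ("LHA", "SB")),
    Condition("LHA+PP", ("LHA", "PP")),
    Condition("Lumbar_accel", ("L",), "accel_only"),
    Condition("RHA_accel", ("RHA",), "accel_only"),
    Condition("LHA_accel", ("LHA",), "accel_only"),
)

SINGLE_POSITION_CONDITIONS: Tuple[Condition, ...] = DEFAULT_CONDITIONS[:7]
COMBINATION_CONDITIONS: Tuple[Condition, ...] = DEFAULT_CONDITIONS[7:11]
ACCEL_ONLY_CONDITIONS: Tuple[Condition, ...] = DEFAULT_CONDITIONS[11:]


@dataclass(frozen=True)
class EvalResult:
    """Test-set metrics for one condition x split."""

    condition: str
    split_id: int
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int


def make_splits(
    participant_ids: Sequence[str],
    n_splits: int = 10,
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> List[SplitPlan]:
    """Random participant-level 70/15/15 partitions, one per split.

    Sizes are train = round(f_train * n), val = round(f_val * n), test =
    remainder (46/10/10 for n = 66).  Deterministic in ``seed``; the same
    plans are reused for every condition.
    """
    ids = list(participant_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 participants")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"cohort of {n} too small for fractions {fractions}: "
            f"{n_train}/{n_val}/{n_test}"
        )
    plans = []
    for k in range(n_splits):
        split_seed = derive_seed(seed, "split", k)
        order = np.random.default_rng(split_seed).permutation(n)
        shuffled = [ids[i] for i in order]
        plans.append(
            SplitPlan(
                split_id=k,
                train_ids=tuple(shuffled[:n_train]),
                val_ids=tuple(shuffled[n_train : n_train + n_val]),
                test_ids=tuple(shuffled[n_train + n_val :]),
                seed=split_seed,
            )
        )
    return plans


def compute_metrics(
    predicted: Sequence[int], true: Sequence[int],
    condition: str = "", split_id: int = -1,
) -> EvalResult:
    """Precision/recall/F1 with perturbation (1) as the positive class.

    An empty positive prediction set yields precision 0 (with a warning);
    F1 is 0 when precision + recall is 0.
    """
    yp = np.asarray(predicted)
    yt = np.asarray(true)
    if yp.shape != yt.shape:
        raise ValueError(
            f"length mismatch: {yp.shape[0]} predictions vs {yt.shape[0]} labels"
        )
    tp = int(np.sum((yp == 1) & (yt == 1)))
    fp = int(np.sum((yp == 1) & (yt == 0)))
    fn = int(np.sum((yp == 0) & (yt == 1)))
    tn = int(np.sum((yp == 0) & (yt == 0)))
    if tp + fp == 0:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalResult(condition, split_id, precision, recall, f1, tp, fp, fn, tn)


def resample_cohort(
    cohort: CohortDataset, cfg: WindowingConfig
) -> Dict[Tuple[str, str, str], ImuTrace]:
    """Resample every trace once onto the common grid (shared by conditions)."""
    return {
        key: wd.resample(trace, cfg.common_rate)
        for key, trace in cohort.traces.items()
    }


def build_condition_windows(
    cohort: CohortDataset,
    condition: Condition,
    cfg: WindowingConfig,
    resampled: Mapping[Tuple[str, str, str], ImuTrace] | None = None,
) -> List[Window]:
    """All labeled windows of one condition across the whole cohort.

    For multi-position conditions the perturbation anchor (acceleration
    norm argmax) is computed on the first listed position and the same
    time span is cut from every position.
    """
    for pos in condition.positions:
        if not any(k[1] == pos for k in cohort.traces):
            raise ValueError(f"cohort has no traces for position {pos!r}")
    if resampled is None:
        resampled = {}
        for pid in cohort.participant_ids:
            for pos in condition.positions:
                for trial in ("gait", *PERT_TRIALS):
                    key = (pid, pos, trial)
                    resampled[key] = wd.resample(cohort.traces[key], cfg.common_rate)
    out: List[Window] = []
    for pid in cohort.participant_ids:
        for trial in ("gait", *PERT_TRIALS):
            traces = wd.crop_to_common_grid(
                [resampled[(pid, pos, trial)] for pos in condition.positions]
            )
            by_pos: Dict[str, List[Window]] = {}
            if trial == "gait":
                for pos, tr in zip(condition.positions, traces):
                    by_pos[pos] = wd.extract_gait_windows(tr, cfg)
            else:
                markers = cohort.markers[(pid, trial)]
                anchor = traces[0]
                for pos, tr in zip(condition.positions, traces):
                    by_pos[pos] = wd.extract_perturbation_windows(
                        tr, markers, cfg, anchor_trace=anchor
                    )
            out.extend(
                wd.assemble_condition(
                    by_pos, condition.positions, condition.channel_set
                )
            )
    return out


def _split_windows(windows: Sequence[Window], plan: SplitPlan):
    parts = {"train": [], "val": [], "test": []}
    for w in windows:
        parts[plan.partition_of(w.participant_id)].append(w)
    return parts["train"], parts["val"], parts["test"]


def run_condition(
    windows: Sequence[Window],
    condition: Condition,
    splits: Sequence[SplitPlan],
    model_cfg: ModelConfig,
    experiment_seed: int = 0,
) -> List[EvalResult]:
    """Train/evaluate one condition on every split plan.

    Per split: partition by participant, fit the scaler and class weights
    on training windows only, train a freshly seeded detector, and score
    the test participants' windows.
    """
    if not windows:
        raise ValueError(f"no windows for condition {condition.name!r}")
    results = []
    for plan in splits:
        train_w, val_w, test_w = _split_windows(windows, plan)
        train_s, val_s, test_s, _scaler = wd.standardize(train_w, val_w, test_w)
        xt, yt = wd.windows_to_arrays(train_s)
        xv, yv = wd.windows_to_arrays(val_s)
        xe, ye = wd.windows_to_arrays(test_s)
        weights = compute_class_weights([w.label for w in train_w])
        cw = {0: weights[wd.LABEL_GAIT], 1: weights[wd.LABEL_PERTURBATION]}
        cfg = ModelConfig(
            **{
                **model_cfg.__dict__,
                "seed": derive_seed(experiment_seed, condition.name, plan.split_id),
            }
        )
        det = build_model(cfg, xt.shape[1:])
        det = train(det, xt, yt, xv, yv, cw)
        labels, _proba = predict(det, xe)
        res = compute_metrics(labels, ye, condition.name, plan.split_id)
        logger.info(
            "%s split %d: P=%.3f R=%.3f F1=%.3f",
            condition.name, plan.split_id, res.precision, res.recall, res.f1,
        )
        results.append(res)
    return results


def results_to_frame(results: Iterable[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarize(results_df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per condition over splits, mirroring the results tables."""
    agg = (
        results_df.groupby("condition", sort=False)[["precision", "recall", "f1"]]
        .agg(["mean", "std"])
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def run_matrix(
    cohort: CohortDataset,
    conditions: Sequence[Condition],
    splits: Sequence[SplitPlan],
    model_cfg: ModelConfig,
    window_cfg: WindowingConfig | None = None,
    experiment_seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run every condition on the shared splits; tidy results + summary."""
    wcfg = window_cfg or WindowingConfig()
    resampled = resample_cohort(cohort, wcfg)
    all_results: List[EvalResult] = []
    for cond in conditions:
        windows = build_condition_windows(cohort, cond, wcfg, resampled=resampled)
        all_results.extend(
            run_condition(windows, cond, splits, model_cfg, experiment_seed)
        )
    df = results_to_frame(all_results)
    return df, summarize(df)
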
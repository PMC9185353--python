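"""Trial segmentation: trimming, speed computation and category assignment.

Each annotated activity trial loses its first and last 15 s (initiation and
termination are not steady state). Walking speed is the distance walked
divided by the trial duration, one speed per trial; every retained epoch of
a trial inherits the trial's category. The three household tasks (sitting,
setting the table, washing dishes) are pooled into a single non-ambulation
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import (
    MED_MAX_SPEED,
    NONAMBULATION_TASKS,
    SLOW_MAX_SPEED,
    WALK_MIN_SPEED,
    WALKING_TASKS,
    SpeedCategory,
)
from .counts import CountSeries
from .errors import BelowMinimumSpeedError, TrialTooShortError

#: Seconds removed from each end of every trial.
TRIM_S = 15.0


@dataclass(frozen=True)
class ActivityTrial:
    """One annotated activity bout for one participant."""

    participant_id: str
    task: str
    start_s: float
    stop_s: float
    distance_m: float | None = None

    def __post_init__(self) -> None:
        if self.task not in NONAMBULATION_TASKS + WALKING_TASKS:
            raise ValueError(f"unknown task: {self.task!r}")
        if not self.stop_s > self.start_s >= 0:
            raise ValueError("need 0 <= start_s < stop_s")
        if self.is_walking:
            if self.distance_m is None or self.distance_m < 0:
                raise ValueError("walking trials require a non-negative distance_m")
        elif self.distance_m is not None:
            raise ValueError("distance_m only applies to walking trials")

    @property
    def is_walking(self) -> bool:
        return self.task in WALKING_TASKS

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


def trim_trial(trial: ActivityTrial, series: CountSeries) -> CountSeries:
    """Drop the first and last 15 s of a trial's 1 s count series."""
    if trial.duration_s <= 2 * TRIM_S:
        raise TrialTooShortError(
            f"trial of {trial.duration_s:.0f} s cannot lose {2 * TRIM_S:.0f} s"
        )
    k = int(round(TRIM_S / series.base_epoch_s))
    return CountSeries(
        placement=series.placement,
        filter_mode=series.filter_mode,
        counts_v=series.counts_v[k:-k],
        counts_ap=series.counts_ap[k:-k],
        counts_ml=series.counts_ml[k:-k],
        counts_vm=series.counts_vm[k:-k],
        base_epoch_s=series.base_epoch_s,
    )


def compute_speed(distance_m: float, duration_s: float) -> float:
    """Trial walking speed in m/s: distance walked over time taken."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if distance_m < 0:
        raise ValueError("distance_m must be non-negative")
    return distance_m / duration_s


def assign_category(speed_mps: float) -> SpeedCategory:
    """Map a walking speed to its category.

    Bands: SLOW [0.41, 0.80], MED (0.80, 1.20], FAST (1.20, inf). Speeds
    below 0.41 m/s are outside the walking bands and raise
    :class:`BelowMinimumSpeedError`; callers exclude such trials (with a
    warning) rather than silently binning them.
    """
    if speed_mps < 0:
        raise ValueError("speed must be non-negative")
    if speed_mps < WALK_MIN_SPEED:
        raise BelowMinimumSpeedError(
            f"speed {speed_mps:.3f} m/s is below the {WALK_MIN_SPEED} m/s "
            "minimum walking speed"
        )
    if speed_mps <= SLOW_MAX_SPEED:
        return SpeedCategory.SLOW
    if speed_mps <= MED_MAX_SPEED:
        return SpeedCategory.MED
    return SpeedCategory.FAST


def pool_nonambulation(rows: pd.DataFrame) -> pd.DataFrame:
    """Relabel all non-ambulation task rows into the single NONAMB class.

    The task column is preserved for provenance; any walking row is an error.
    """
    out = rows.copy()
    if len(out) == 0:
        if "category" not in out.columns:
            out["category"] = pd.Series(dtype=object)
        return out
    bad = ~out["task"].isin(NONAMBULATION_TASKS)
    if bad.any():
        raise ValueError(
            f"pool_nonambulation received walking rows: "
            f"{sorted(out.loc[bad, 'task'].unique())}"
        )
    out["category"] = SpeedCategory.NONAMB
    return out


def categorize_trial(trial: ActivityTrial) -> tuple[SpeedCategory, float | None]:
    """Category and speed for one trial; walking speed from its annotation."""
    if not trial.is_walking:
        return SpeedCategory.NONAMB, None
    speed = compute_speed(trial.distance_m, trial.duration_s)
    return assign_category(speed), speed


def read_trials(path) -> list[ActivityTrial]:
    """Read trial annotations from tabular text.

    Columns: participant_id, task, start_s, stop_s, distance_m (blank for
    non-ambulation tasks).
    """
    df = pd.read_csv(path)
    trials = []
    for row in df.itertuples(index=False):
        dist = getattr(row, "distance_m", None)
        if dist is not None and (isinstance(dist, float) and np.isnan(dist)):
            dist = None
        trials.append(
            ActivityTrial(
                participant_id=str(row.participant_id),
                task=row.task,
                start_s=float(row.start_s),
                stop_s=float(row.stop_s),
                distance_m=dist,
            )
        )
    return trials


def warn_excluded(trial: ActivityTrial, reason: Exception) -> None:
    """Emit the standard exclusion warning for a dropped trial."""
    warnings.warn(
        f"excluding trial {trial.participant_id}/{trial.task}: {reason}",
        stacklevel=2,
    )
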
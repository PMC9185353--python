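"""Synthetic cohort generation at signal level and count level.

Two complementary generators stand in for the (non-shareable) study cohort:

* a signal-level path that synthesizes gait-like tri-axial accelerations —
  a quasi-periodic waveform at the step cadence with speed-dependent
  amplitude, two harmonics, a gravity offset and sensor noise — plus three
  non-ambulation task generators whose motion is small and mostly below or
  outside the count engine's passband/dead-band; and

* a count-level path that draws per-epoch counts directly from class-
  conditional distributions calibrated to the published per-category medians
  (lognormal for walking classes; zero-inflated lognormal for the pooled
  non-ambulation class, whose published median is 0 with a positive tail).

Both paths produce epoch tables with an identical schema, already trimmed
per the segmentation rule, with one speed per walking trial. All randomness
derives from the single configuration seed via per-participant sub-streams.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .categories import (
    NONAMBULATION_TASKS,
    WALKING_TASKS,
    SpeedCategory,
)
from .config import TASK_DURATIONS_S, SimConfig
from .counts import AccelSignal, FilterSpec, accel_to_counts, bandpass
from .segmentation import ActivityTrial, categorize_trial, trim_trial

COHORT_COLUMNS = [
    "participant_id", "placement", "filter_mode", "task", "category",
    "speed_mps", "epoch_index", "epoch_length_s",
    "count_v", "count_ap", "count_ml", "count_vm",
]

#: Dynamic acceleration amplitude (g) per unit walking speed (m/s); the
#: distal placement sees a larger signal than the waist.
AMPLITUDE_PER_SPEED_G = {"waist": 0.12, "ankle": 0.35}

#: Relative amplitude of the anterior-posterior and medio-lateral axes.
AXIS_FRACTIONS = {"v": 1.0, "ap": 0.6, "ml": 0.3}


def _derived_rng(config: SimConfig, *tags) -> np.random.Generator:
    """Deterministic sub-stream keyed by the config seed and string tags."""
    words = [config.seed & 0x7FFFFFFF]
    words += [zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(np.random.SeedSequence(words))


def _cadence_hz(speed_mps: float) -> float:
    # step frequency grows roughly linearly with speed and stays inside the
    # 0.25-2.5 Hz count passband over the supported speed range
    return 0.75 + 0.6 * speed_mps


def simulate_gait_signal(
    speed_mps: float,
    duration_s: float,
    placement: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> AccelSignal:
    """Quasi-periodic gait-like tri-axial acceleration at a given speed.

    The waveform is the sum of the first two harmonics of the step cadence
    with slowly varying amplitude, axis-specific scaling, zero-mean sensor
    noise and a 1 g gravity offset on the vertical axis. Deterministic for a
    given configuration seed and argument set.
    """
    if speed_mps <= 0 or duration_s <= 0:
        raise ValueError("speed_mps and duration_s must be positive")
    if duration_s < 30:
        raise ValueError("duration_s must be at least 30 s (room for trimming)")
    if not 0.2 <= speed_mps <= 2.5:
        raise ValueError("speed_mps must lie in [0.2, 2.5]")
    if placement not in AMPLITUDE_PER_SPEED_G:
        raise ValueError(f"unknown placement: {placement!r}")
    if rng is None:
        rng = _derived_rng(config, "gait", placement, round(speed_mps, 6),
                          round(duration_s, 6))

    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cadence = _cadence_hz(speed_mps)
    amp = AMPLITUDE_PER_SPEED_G[placement] * speed_mps

    # slow amplitude modulation + random phase offsets -> quasi-periodic
    mod = 1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    axes = {}
    for axis, frac in AXIS_FRACTIONS.items():
        phase1 = rng.uniform(0, 2 * np.pi)
        phase2 = rng.uniform(0, 2 * np.pi)
        wave = amp * frac * mod * (
            np.sin(2 * np.pi * cadence * t + phase1)
            + 0.4 * np.sin(2 * np.pi * 2 * cadence * t + phase2)
        )
        axes[axis] = wave + rng.normal(0.0, 0.02, size=n)
    axes["v"] = axes["v"] + 1.0  # gravity offset
    return AccelSignal(sampling_rate_hz=fs, v=axes["v"], ap=axes["ap"],
                       ml=axes["ml"])


#: Per-task parameters of the non-ambulation generators: in-band periodic
#: amplitude (g) and frequency (Hz), out-of-band drift amplitude, noise SD,
#: transient bump amplitude and mean rate (bumps per second).
_NONAMB_PARAMS = {
    "sitting": dict(inband_amp=0.004, inband_hz=0.35, drift_amp=0.02,
                    noise_sd=0.004, bump_amp=0.08, bump_rate=1 / 120),
    "setting_table": dict(inband_amp=0.012, inband_hz=0.45, drift_amp=0.025,
                          noise_sd=0.007, bump_amp=0.12, bump_rate=1 / 45),
    "washing_dishes": dict(inband_amp=0.018, inband_hz=0.7, drift_amp=0.03,
                           noise_sd=0.009, bump_amp=0.12, bump_rate=1 / 60),
}


def simulate_nonambulation_signal(
    task: str,
    duration_s: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> AccelSignal:
    """Small-motion tri-axial acceleration for a non-ambulation task.

    Motion is mostly outside the count passband (slow postural drift) or
    below the dead-band (low-amplitude in-band movement and noise), with
    occasional short transients, so per-epoch counts after conversion are
    predominantly zero.
    """
    params = _NONAMB_PARAMS.get(task)
    if params is None:
        raise ValueError(f"unknown non-ambulation task: {task!r}")
    if duration_s < 30:
        raise ValueError("duration_s must be at least 30 s (room for trimming)")
    if rng is None:
        rng = _derived_rng(config, "nonamb", task, round(duration_s, 6))

    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    axes = {}
    for axis, frac in AXIS_FRACTIONS.items():
        drift = params["drift_amp"] * frac * np.sin(
            2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        inband = params["inband_amp"] * frac * np.sin(
            2 * np.pi * params["inband_hz"] * t + rng.uniform(0, 2 * np.pi))
        sig = drift + inband + rng.normal(0.0, params["noise_sd"], size=n)
        axes[axis] = sig

    # occasional half-sine transients (reaching, shifting posture)
    n_bumps = rng.poisson(params["bump_rate"] * duration_s)
    bump_len = int(round(0.5 * fs))
    window = np.sin(np.pi * np.arange(bump_len) / bump_len)
    for _ in range(n_bumps):
        start = rng.integers(0, max(n - bump_len, 1))
        axis = rng.choice(list(AXIS_FRACTIONS))
        axes[axis][start:start + bump_len] += params["bump_amp"] * window[:n - start]

    axes["v"] = axes["v"] + 1.0
    return AccelSignal(sampling_rate_hz=fs, v=axes["v"], ap=axes["ap"],
                       ml=axes["ml"])


def _lognormal_counts(median: float, dispersion: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    if median <= 0:
        return np.zeros(n, dtype=np.int64)
    draws = rng.lognormal(mean=np.log(median), sigma=dispersion, size=n)
    return np.rint(draws).astype(np.int64)


def _nonamb_counts(tail_median: float, dispersion: float, p_zero: float,
                   n: int, rng: np.random.Generator) -> np.ndarray:
    zeros = rng.random(n) < p_zero
    tail = _lognormal_counts(tail_median, dispersion, n, rng)
    return np.where(zeros, 0, tail).astype(np.int64)


def sample_counts_direct(
    category: SpeedCategory,
    placement: str,
    axis: str,
    n_epochs: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-epoch counts for one class directly, skipping the signal stage.

    Walking classes draw from a lognormal whose median is the configured
    class median (log-SD ``config.dispersion``), rounded to integers; the
    non-ambulation class is zero-inflated so its median is 0 with a positive
    upper tail. Deterministic for a given configuration seed.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    if not isinstance(category, SpeedCategory):
        try:
            category = SpeedCategory[str(category).upper()]
        except KeyError:
            raise ValueError(f"unknown category: {category!r}") from None
    axis = {"vertical": "v"}.get(axis, axis)
    key = (placement, axis)
    if key not in config.class_medians:
        raise ValueError(f"no class medians configured for {key}")
    medians = config.class_medians[key]
    if rng is None:
        rng = _derived_rng(config, "counts", placement, axis, category.name)

    if category is SpeedCategory.NONAMB:
        tail = config.nonamb_tail_frac * medians[SpeedCategory.SLOW]
        return _nonamb_counts(tail, config.dispersion, config.p_zero,
                              n_epochs, rng)
    return _lognormal_counts(medians[category], config.dispersion,
                             n_epochs, rng)


def _sample_epoch_rows(category: SpeedCategory, placement: str, n: int,
                       config: SimConfig, rng: np.random.Generator):
    """Correlated (v, ap, ml, vm) counts for n epochs of one trial."""
    medians_vm = config.class_medians[(placement, "vm")]
    medians_v = config.class_medians[(placement, "v")]
    if category is SpeedCategory.NONAMB:
        tail = config.nonamb_tail_frac * medians_vm[SpeedCategory.SLOW]
        vm = _nonamb_counts(tail, config.dispersion, config.p_zero, n, rng)
        ratio = (medians_v[SpeedCategory.SLOW]
                 / max(medians_vm[SpeedCategory.SLOW], 1.0))
    else:
        vm = _lognormal_counts(medians_vm[category], config.dispersion, n, rng)
        ratio = medians_v[category] / max(medians_vm[category], 1.0)

    jitter = np.exp(rng.normal(0.0, 0.08, size=n))
    v = np.minimum(np.rint(vm * ratio * jitter).astype(np.int64), vm)
    v = np.maximum(v, 0)
    resid = np.maximum(vm.astype(float) ** 2 - v.astype(float) ** 2, 0.0)
    ap = np.rint(np.sqrt(resid / 2.0)).astype(np.int64)
    ml = ap.copy()
    return v, ap, ml, vm


def _draw_trial_speeds(rng: np.random.Generator) -> dict[str, float]:
    """Self-selected and brisk 6-min walk speeds for one participant.

    Parameters are calibrated so the expected category mix of walking trials
    reproduces the published cohort's composition (roughly 29% slow, 40%
    medium, 31% fast).
    """
    self_speed = float(np.clip(rng.normal(0.78, 0.26), 0.42, 1.6))
    brisk = float(np.clip(self_speed + rng.uniform(0.30, 0.60), 0.45, 2.4))
    return {"walk_self_selected": self_speed, "walk_brisk": brisk}


def _participant_trials(pid: str, config: SimConfig,
                        rng: np.random.Generator) -> list[ActivityTrial]:
    trials = []
    t = 0.0
    for task in NONAMBULATION_TASKS:
        dur = TASK_DURATIONS_S[task]
        trials.append(ActivityTrial(pid, task, t, t + dur))
        t += dur + 60.0
    speeds = _draw_trial_speeds(rng)
    for task in WALKING_TASKS:
        dur = config.trial_duration_s
        trials.append(ActivityTrial(pid, task, t, t + dur,
                                    distance_m=speeds[task] * dur))
        t += dur + 60.0
    return trials


def _n_retained_epochs(duration_s: float, epoch_length_s: int) -> int:
    return int((duration_s - 30.0) // epoch_length_s)


def generate_cohort(config: SimConfig, signal_level: bool = False) -> pd.DataFrame:
    """Generate a labeled epoch table emulating the study cohort layout.

    Each participant contributes three non-ambulation trials (sitting 5 min,
    setting the table 3 min, washing dishes 6 min) and two 6-min walking
    trials (self-selected and brisk speed, one speed per trial) at every
    configured placement. The segmentation trimming rule (first/last 15 s
    dropped, trailing partial epoch discarded) is already applied; every
    retained epoch carries its trial's true category.

    ``signal_level=True`` routes each trial through the acceleration
    simulators and the count engine instead of the direct count sampler; the
    output schema is identical.
    """
    rows: list[dict] = []
    children = np.random.SeedSequence(config.seed & 0x7FFFFFFF).spawn(
        config.n_participants)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:03d}"
        trials = _participant_trials(pid, config, rng)
        for placement in config.placements:
            for trial in trials:
                category, speed = categorize_trial(trial)
                if signal_level:
                    epochs = _signal_level_epochs(trial, speed, placement,
                                                  config, rng)
                else:
                    n = _n_retained_epochs(trial.duration_s,
                                           config.epoch_length_s)
                    if n < 1:
                        continue
                    v, ap, ml, vm = _sample_epoch_rows(category, placement, n,
                                                       config, rng)
                    epochs = pd.DataFrame({
                        "epoch_index": np.arange(n),
                        "count_v": v, "count_ap": ap,
                        "count_ml": ml, "count_vm": vm,
                    })
                for rec in epochs.itertuples(index=False):
                    rows.append({
                        "participant_id": pid,
                        "placement": placement,
                        "filter_mode": "default",
                        "task": trial.task,
                        "category": category,
                        "speed_mps": speed if speed is not None else np.nan,
                        "epoch_index": int(rec.epoch_index),
                        "epoch_length_s": config.epoch_length_s,
                        "count_v": int(rec.count_v),
                        "count_ap": int(rec.count_ap),
                        "count_ml": int(rec.count_ml),
                        "count_vm": int(rec.count_vm),
                    })
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if len(table) == 0:
        table = pd.DataFrame(columns=COHORT_COLUMNS)
    return table


def _signal_level_epochs(trial: ActivityTrial, speed, placement: str,
                         config: SimConfig, rng: np.random.Generator):
    from .counts import aggregate_epochs  # local alias for readability

    if trial.is_walking:
        sig = simulate_gait_signal(speed, trial.duration_s, placement,
                                   config, rng=rng)
    else:
        sig = simulate_nonambulation_signal(trial.task, trial.duration_s,
                                            config, rng=rng)
    filtered = bandpass(sig, FilterSpec.for_mode("default"))
    series = accel_to_counts(filtered, placement=placement)
    series = trim_trial(trial, series)
    return aggregate_epochs(series, config.epoch_length_s)


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write an epoch table as comma-separated text with category names."""
    out = table.copy()
    out["category"] = out["category"].map(
        lambda c: SpeedCategory(int(c)).name if pd.notna(c) else c)
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read an epoch table written by :func:`write_cohort`."""
    table = pd.read_csv(path)
    table["category"] = table["category"].map(
        lambda c: SpeedCategory[c] if isinstance(c, str) else SpeedCategory(int(c)))
    return table
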
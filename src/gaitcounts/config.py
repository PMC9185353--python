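"""Simulation configuration for the synthetic post-stroke cohort.

The defaults emulate the calibration study's layout: 42 participants, waist
and ankle sensor placements, 15 s epochs, three pooled non-ambulation tasks
and two 6-min walking trials per participant, with class-conditional count
medians set to the published per-category sample medians for each placement
and axis. ``dispersion`` is the log-scale spread of the count distribution
(0.25 by default, consistent with the spread of the published per-category
confidence intervals).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .categories import SpeedCategory

PLACEMENTS = ("waist", "ankle")
COUNT_AXES = ("v", "vm")

# Published per-category median counts per epoch, keyed
# (placement, axis) -> {category: median}.  15 s and 1 min variants.
CLASS_MEDIANS_15S: dict[tuple[str, str], dict[SpeedCategory, float]] = {
    ("waist", "v"): {
        SpeedCategory.NONAMB: 0, SpeedCategory.SLOW: 338,
        SpeedCategory.MED: 423, SpeedCategory.FAST: 555,
    },
    ("waist", "vm"): {
        SpeedCategory.NONAMB: 0, SpeedCategory.SLOW: 519,
        SpeedCategory.MED: 759, SpeedCategory.FAST: 1147,
    },
    ("ankle", "v"): {
        SpeedCategory.NONAMB: 0, SpeedCategory.SLOW: 912,
        SpeedCategory.MED: 1898, SpeedCategory.FAST: 3456,
    },
    ("ankle", "vm"): {
        SpeedCategory.NONAMB: 0, SpeedCategory.SLOW: 1394,
        SpeedCategory.MED: 2546, SpeedCategory.FAST: 4045,
    },
}

CLASS_MEDIANS_60S: dict[tuple[str, str], dict[SpeedCategory, float]] = {
    ("waist", "v"): {
        SpeedCategory.NONAMB: 17, SpeedCategory.SLOW: 1204,
        SpeedCategory.MED: 1628, SpeedCategory.FAST: 2099,
    },
    ("waist", "vm"): {
        SpeedCategory.NONAMB: 44, SpeedCategory.SLOW: 1908,
        SpeedCategory.MED: 2758, SpeedCategory.FAST: 4244,
    },
    ("ankle", "v"): {
        SpeedCategory.NONAMB: 14, SpeedCategory.SLOW: 3496,
        SpeedCategory.MED: 6777, SpeedCategory.FAST: 13178,
    },
    ("ankle", "vm"): {
        SpeedCategory.NONAMB: 37, SpeedCategory.SLOW: 5393,
        SpeedCategory.MED: 9660, SpeedCategory.FAST: 15576,
    },
}

#: Task -> trial duration in seconds (study protocol durations).
TASK_DURATIONS_S = {
    "sitting": 300.0,
    "setting_table": 180.0,
    "washing_dishes": 360.0,
    "walk_self_selected": 360.0,
    "walk_brisk": 360.0,
}


def default_class_medians(epoch_length_s: int):
    table = CLASS_MEDIANS_15S if epoch_length_s == 15 else CLASS_MEDIANS_60S
    return {key: dict(val) for key, val in table.items()}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``class_medians`` maps (placement, axis) to per-category median counts
    per epoch; ``dispersion`` is the log-scale standard deviation of the
    count distribution; ``p_zero`` and ``nonamb_tail_frac`` shape the
    zero-inflated non-ambulation counts (probability of an exact zero, and
    the non-zero tail's median as a fraction of the SLOW median).
    """

    n_participants: int = 42
    placements: tuple[str, ...] = PLACEMENTS
    epoch_length_s: int = 15
    class_medians: dict = None
    dispersion: float = 0.25
    p_zero: float = 0.6
    nonamb_tail_frac: float = 0.06
    trial_duration_s: float = 360.0
    sampling_rate_hz: float = 30.0
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.class_medians is None:
            self.class_medians = default_class_medians(self.epoch_length_s)
        self.placements = tuple(self.placements)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if not set(self.placements) <= set(PLACEMENTS):
            raise ValueError(f"placements must be a subset of {PLACEMENTS}")
        if self.epoch_length_s not in (15, 60):
            raise ValueError("epoch_length_s must be 15 or 60")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must lie in [0, 1)")
        if self.trial_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")
        # the count engine's upper passband edge is 2.5 Hz
        if self.sampling_rate_hz <= 2 * 2.5:
            raise ValueError("sampling_rate_hz must exceed twice the 2.5 Hz "
                             "upper filter cut-off")
        for (placement, axis), medians in self.class_medians.items():
            s, m, f = (medians[SpeedCategory.SLOW], medians[SpeedCategory.MED],
                       medians[SpeedCategory.FAST])
            if not s < m < f:
                raise ValueError(
                    f"class medians must increase SLOW < MED < FAST for "
                    f"{placement}/{axis}: {s}, {m}, {f}"
                )
            na = medians[SpeedCategory.NONAMB]
            if not 0 <= na < s:
                raise ValueError(
                    f"NONAMB median must be >= 0 and below SLOW for "
                    f"{placement}/{axis}"
                )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a configuration from a plain-text key: value (YAML) file.

        All fields are optional; ``class_medians`` entries are written as
        ``placement.axis.CATEGORY: value`` nested mappings and override the
        defaults entry-wise.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        medians_override = raw.pop("class_medians", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if medians_override:
            for placement, by_axis in medians_override.items():
                for axis, by_cat in by_axis.items():
                    for cat_name, value in by_cat.items():
                        cat = SpeedCategory[cat_name.upper()]
                        cfg.class_medians[(placement, axis)][cat] = float(value)
            cfg.validate()
        return cfg
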
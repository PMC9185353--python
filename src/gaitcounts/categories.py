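"""Ordered ambulation categories and their gait-speed bounds.

Walking trials are graded into the community-ambulation speed bands used in
stroke research: limited (0.41-0.8 m/s), intermediate (0.81-1.2 m/s) and
unlimited (>1.2 m/s) community walking, with all sedentary/standing tasks
pooled into a single non-ambulation class.
"""

from __future__ import annotations

import enum


class SpeedCategory(enum.IntEnum):
    """Ordered ambulation classes: NONAMB < SLOW < MED < FAST."""

    NONAMB = 0
    SLOW = 1
    MED = 2
    FAST = 3

    def __str__(self) -> str:  # stable text form used in tabular output
        return self.name


#: Minimum speed (m/s) counted as walking; slower trials are excluded.
WALK_MIN_SPEED = 0.41
#: Inclusive upper bound of the slow (limited community ambulation) band.
SLOW_MAX_SPEED = 0.80
#: Inclusive upper bound of the medium band; above this is fast walking.
MED_MAX_SPEED = 1.20

WALKING_CATEGORIES = (SpeedCategory.SLOW, SpeedCategory.MED, SpeedCategory.FAST)

NONAMBULATION_TASKS = ("sitting", "setting_table", "washing_dishes")
WALKING_TASKS = ("walk_self_selected", "walk_brisk")

#: Human-readable speed band per category, for report rendering.
CATEGORY_BANDS = {
    SpeedCategory.NONAMB: "non-ambulation",
    SpeedCategory.SLOW: "0.41-0.8 m/s",
    SpeedCategory.MED: "0.81-1.2 m/s",
    SpeedCategory.FAST: ">1.2 m/s",
}


def category_from_name(name: str) -> SpeedCategory:
    """Parse a category from its name (case-insensitive)."""
    try:
        return SpeedCategory[name.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown speed category: {name!r}") from None
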
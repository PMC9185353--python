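"""ROC cut-point calibration for count-based walking-speed classification.

The calibration treats each category boundary as a binary problem formed by
cumulative dichotomization of the ordered classes (below vs at-or-above the
boundary), traces the full ROC curve over candidate thresholds (midpoints
between consecutive distinct scores plus the two infinite endpoints),
computes the trapezoidal AUC, and selects the operating point closest to the
ideal corner (sensitivity = 1, 1 - specificity = 0). The optimal real
threshold is floored to an integer T so that the resulting count intervals
are contiguous integer ranges (<= T and >= T + 1), and the three boundaries
are forced strictly increasing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import CATEGORY_BANDS, SpeedCategory
from .errors import (
    DegenerateCurveError,
    DegenerateLabelsError,
    InsufficientClassesError,
)

AUC_GRADES = ("poor", "fair", "good", "excellent", "perfect")


@dataclass
class RocCurve:
    """Operating points of one binary boundary problem.

    Thresholds are descending, from +inf (nothing predicted positive, the
    (0, 0) corner of the curve) to -inf (everything positive, the (1, 1)
    corner); a score is called positive when it exceeds the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_class: str = "above"

    def __len__(self) -> int:
        return len(self.thresholds)


def roc_curve(scores, labels) -> RocCurve:
    """Build the ROC curve for binary labels scored by a real-valued input.

    ``labels`` are truthy for the positive class. Candidate thresholds are
    the midpoints between consecutive distinct scores plus -inf/+inf, so tied
    scores share an operating point. AUC is the trapezoidal area, which
    equals the Mann-Whitney pairwise concordance (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes must be present")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))

    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    # sens(t) = P(pos > t), 1 - spec(t) = P(neg > t); searchsorted on the
    # sorted class scores gives both in O(k log n).
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / n_pos
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="right") / n_neg
    # +/- inf endpoints need explicit handling: searchsorted of inf is fine,
    # but make the corners exact.
    sens[0], fpr[0] = 0.0, 0.0
    sens[-1], fpr[-1] = 1.0, 1.0

    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
    )


def optimal_cutpoint(
    curve: RocCurve,
    min_threshold: float | None = None,
) -> tuple[float, float, float]:
    """Operating point nearest the (sens = 1, 1 - spec = 0) corner.

    Minimizes sqrt((1 - sens)^2 + (1 - spec)^2); ties go to the higher
    sensitivity, then the lower threshold. ``min_threshold`` restricts the
    search to thresholds strictly above it (used when repairing boundary
    ordering). Returns ``(threshold, sensitivity, specificity)``.
    """
    if len(curve) < 2:
        raise DegenerateCurveError("curve has fewer than two operating points")
    keep = np.isfinite(curve.thresholds)
    if min_threshold is not None:
        keep &= curve.thresholds > min_threshold
    if not keep.any():
        raise DegenerateCurveError("no finite thresholds in the allowed range")
    idx = np.flatnonzero(keep)
    d2 = (1.0 - curve.sensitivity[idx]) ** 2 + (1.0 - curve.specificity[idx]) ** 2
    order = sorted(
        range(len(idx)),
        key=lambda k: (d2[k], -curve.sensitivity[idx[k]], curve.thresholds[idx[k]]),
    )
    best = idx[order[0]]
    return (
        float(curve.thresholds[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )


def grade_auc(auc: float) -> str:
    """Grade a ROC area: <0.7 poor, 0.7-0.79 fair, 0.8-0.89 good,
    >=0.90 excellent, exactly 1 perfect."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc == 1.0:
        return "perfect"
    if auc >= 0.90:
        return "excellent"
    if auc >= 0.80:
        return "good"
    if auc >= 0.70:
        return "fair"
    return "poor"


@dataclass(frozen=True)
class CutPointTable:
    """Three strictly increasing integer boundaries defining four count
    intervals: NONAMB <= t1; SLOW t1+1..t2; MED t2+1..t3; FAST >= t3+1."""

    placement: str
    axis: str
    epoch_length_s: int
    t1: int
    t2: int
    t3: int
    filter_mode: str = "default"

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2 < self.t3):
            raise ValueError(
                f"boundaries must satisfy 0 <= t1 < t2 < t3, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )
        for b in (self.t1, self.t2, self.t3):
            if int(b) != b:
                raise ValueError("boundaries must be integers")

    @property
    def boundaries(self) -> tuple[int, int, int]:
        return (self.t1, self.t2, self.t3)

    def classify(self, count: int) -> SpeedCategory:
        """Category of one integer count under the interval partition."""
        if isinstance(count, bool) or not float(count).is_integer():
            raise ValueError(f"counts must be integers, got {count!r}")
        count = int(count)
        if count < 0:
            raise ValueError("counts must be non-negative")
        if count <= self.t1:
            return SpeedCategory.NONAMB
        if count <= self.t2:
            return SpeedCategory.SLOW
        if count <= self.t3:
            return SpeedCategory.MED
        return SpeedCategory.FAST

    def classify_array(self, counts: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`classify` returning SpeedCategory integer codes."""
        c = np.asarray(counts)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integers")
        return np.searchsorted(np.array(self.boundaries), c, side="left").astype(np.int64)

    def intervals(self) -> dict[SpeedCategory, str]:
        """Human-readable integer count interval per category."""
        return {
            SpeedCategory.NONAMB: f"≤{self.t1}",
            SpeedCategory.SLOW: f"{self.t1 + 1}–{self.t2}",
            SpeedCategory.MED: f"{self.t2 + 1}–{self.t3}",
            SpeedCategory.FAST: f"≥{self.t3 + 1}",
        }


def _boundary_labels(categories: np.ndarray, boundary: int, scheme: str):
    """Binary labels (and row mask) for one boundary's ROC problem."""
    if scheme == "cumulative":
        mask = np.ones(len(categories), dtype=bool)
        labels = categories >= boundary
    elif scheme == "adjacent":
        mask = (categories == boundary - 1) | (categories == boundary)
        labels = categories[mask] == boundary
    else:
        raise ValueError(f"unknown dichotomization scheme: {scheme!r}")
    return mask, labels


def build_cutpoint_table(
    table: pd.DataFrame,
    placement: str,
    axis: str = "vm",
    epoch_length_s: int = 15,
    filter_mode: str = "default",
    scheme: str = "cumulative",
) -> tuple[CutPointTable, dict[int, RocCurve]]:
    """Calibrate the three count boundaries for one stratum of an epoch table.

    Each boundary b in {1, 2, 3} is a binary ROC problem (by default the
    cumulative split: categories below b vs at-or-above b); its optimal
    corner threshold t is floored to the integer boundary T_b. If noise makes
    a boundary not exceed the previous one, that boundary is recomputed with
    the threshold search restricted above the previous boundary (logged as a
    warning). Returns the cut-point table and the per-boundary ROC curves.
    """
    col = {"vm": "count_vm", "v": "count_v", "vertical": "count_v"}.get(axis)
    if col is None:
        raise ValueError(f"axis must be 'vm' or 'v', got {axis!r}")
    stratum = table[
        (table["placement"] == placement)
        & (table["epoch_length_s"] == epoch_length_s)
        & (table["filter_mode"] == filter_mode)
    ]
    cats = stratum["category"].astype(int).to_numpy()
    present = set(np.unique(cats))
    if present != {0, 1, 2, 3}:
        missing = [SpeedCategory(c).name for c in sorted({0, 1, 2, 3} - present)]
        raise InsufficientClassesError(
            f"stratum {placement}/{axis}/{epoch_length_s}s lacks categories: "
            f"{missing}"
        )
    scores = stratum[col].to_numpy(dtype=float)

    curves: dict[int, RocCurve] = {}
    boundaries: list[int] = []
    for b in (1, 2, 3):
        mask, labels = _boundary_labels(cats, b, scheme)
        curve = roc_curve(scores[mask], labels)
        curves[b] = curve
        t, _, _ = optimal_cutpoint(curve)
        T = int(math.floor(t))
        prev = boundaries[-1] if boundaries else -1
        if T <= prev:
            warnings.warn(
                f"boundary {b} ({T}) did not exceed boundary {b-1} ({prev}); "
                "recomputing restricted to higher thresholds",
                stacklevel=2,
            )
            t, _, _ = optimal_cutpoint(curve, min_threshold=float(prev + 1))
            T = max(int(math.floor(t)), prev + 1)
        boundaries.append(T)

    cuts = CutPointTable(
        placement=placement,
        axis="v" if axis == "vertical" else axis,
        epoch_length_s=epoch_length_s,
        filter_mode=filter_mode,
        t1=boundaries[0],
        t2=boundaries[1],
        t3=boundaries[2],
    )
    return cuts, curves


def category_performance(
    table: pd.DataFrame,
    cuts: CutPointTable,
) -> dict[SpeedCategory, tuple[float, float]]:
    """Per-category sensitivity and specificity of interval classification.

    Sensitivity of category c: fraction of c's epochs classified into c's
    interval. Specificity of c: fraction of all other epochs classified
    outside c's interval.
    """
    stratum = table[
        (table["placement"] == cuts.placement)
        & (table["epoch_length_s"] == cuts.epoch_length_s)
    ]
    if len(stratum) < len(table):
        mismatched = table.drop(stratum.index)
        raise ValueError(
            "table contains rows outside the cut-point stratum "
            f"(e.g. placement={mismatched['placement'].iloc[0]!r}, "
            f"epoch_length_s={mismatched['epoch_length_s'].iloc[0]!r})"
        )
    col = "count_vm" if cuts.axis == "vm" else "count_v"
    true = stratum["category"].astype(int).to_numpy()
    pred = cuts.classify_array(stratum[col].to_numpy())

    out: dict[SpeedCategory, tuple[float, float]] = {}
    for cat in SpeedCategory:
        c = int(cat)
        in_c = true == c
        sens = float(np.mean(pred[in_c] == c)) if in_c.any() else float("nan")
        spec = float(np.mean(pred[~in_c] != c)) if (~in_c).any() else float("nan")
        out[cat] = (sens, spec)
    return out


def calibration_report(
    cuts: CutPointTable,
    curves: dict[int, RocCurve],
    performance: dict[SpeedCategory, tuple[float, float]],
) -> pd.DataFrame:
    """Tabular calibration summary: one row per category with its interval,
    sensitivity/specificity, and the AUC (with grade) of the boundary below
    the category (walking categories) or above it (non-ambulation)."""
    intervals = cuts.intervals()
    # boundary b separates categories < b from >= b; attribute boundary b's
    # AUC to category b (its lower edge), and boundary 1's to NONAMB as well.
    cat_to_boundary = {
        SpeedCategory.NONAMB: 1,
        SpeedCategory.SLOW: 1,
        SpeedCategory.MED: 2,
        SpeedCategory.FAST: 3,
    }
    rows = []
    for cat in SpeedCategory:
        b = cat_to_boundary[cat]
        sens, spec = performance[cat]
        rows.append(
            {
                "placement": cuts.placement,
                "axis": cuts.axis,
                "epoch_length_s": cuts.epoch_length_s,
                "filter_mode": cuts.filter_mode,
                "category": cat.name,
                "band": CATEGORY_BANDS[cat],
                "interval": intervals[cat],
                "sensitivity": round(sens, 2),
                "specificity": round(spec, 2),
                "auc": round(curves[b].auc, 2),
                "auc_grade": grade_auc(curves[b].auc),
            }
        )
    return pd.DataFrame(rows)
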
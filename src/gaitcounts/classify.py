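"""Applying cut-point tables to epoch counts.

Ships the published vector-magnitude cut-points for 15 s epochs as built-in
constants (the recommended configuration); the remaining published strata
(vertical axis, 1 min epochs) are loadable from the packaged fixtures file.
Counts must be integers — real-valued inputs are rejected rather than
rounded, to prevent silent drift across interval boundaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import SpeedCategory
from .errors import GaitCountsError
from .roc import CutPointTable

#: Published VM/15 s cut-point boundaries per placement:
#: waist: <=140 / 141-572 / 573-990 / >=991
#: ankle: <=401 / 402-1862 / 1863-3265 / >=3266
PUBLISHED_CUTPOINTS = {
    "waist": CutPointTable(placement="waist", axis="vm", epoch_length_s=15,
                           t1=140, t2=572, t3=990),
    "ankle": CutPointTable(placement="ankle", axis="vm", epoch_length_s=15,
                           t1=401, t2=1862, t3=3265),
}


def published_cutpoints(placement: str) -> CutPointTable:
    """The built-in published VM/15 s cut-point table for a placement."""
    try:
        return PUBLISHED_CUTPOINTS[placement]
    except KeyError:
        raise ValueError(f"no published cut-points for placement "
                         f"{placement!r}") from None


def load_cutpoint_fixtures(path=None) -> pd.DataFrame:
    """Load the full published cut-point strata (axis x epoch length).

    Reads the packaged fixtures CSV by default. Columns: placement, axis,
    epoch_length_s, t1, t2, t3.
    """
    if path is None:
        ref = importlib.resources.files("gaitcounts.data") / "published_cutpoints.csv"
        with importlib.resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def cutpoints_from_fixtures(placement: str, axis: str = "vm",
                            epoch_length_s: int = 15,
                            path=None) -> CutPointTable:
    """Build a :class:`CutPointTable` from the fixtures file."""
    df = load_cutpoint_fixtures(path)
    row = df[(df["placement"] == placement) & (df["axis"] == axis)
             & (df["epoch_length_s"] == epoch_length_s)]
    if len(row) != 1:
        raise ValueError(
            f"no fixture for {placement}/{axis}/{epoch_length_s}s")
    r = row.iloc[0]
    return CutPointTable(placement=placement, axis=axis,
                         epoch_length_s=int(epoch_length_s),
                         t1=int(r.t1), t2=int(r.t2), t3=int(r.t3))


def classify_epoch(count_vm: int, cuts: CutPointTable) -> SpeedCategory:
    """Classify one epoch's count into its speed category."""
    return cuts.classify(count_vm)


def classify_table(table: pd.DataFrame, cuts: CutPointTable) -> pd.DataFrame:
    """Add a ``predicted_category`` column to a matching epoch table.

    The table's placement and epoch length must match the cut-point table's
    stratum; mixed strata are rejected.
    """
    out = table.copy()
    if len(out) == 0:
        out["predicted_category"] = pd.Series(dtype=object)
        return out
    for colname, expect in (("placement", cuts.placement),
                            ("epoch_length_s", cuts.epoch_length_s)):
        if colname in out.columns:
            vals = set(out[colname].unique())
            if vals != {expect}:
                raise ValueError(
                    f"table {colname} {sorted(map(str, vals))} does not match "
                    f"cut-point stratum {expect!r}")
    col = "count_vm" if cuts.axis == "vm" else "count_v"
    codes = cuts.classify_array(out[col].to_numpy())
    out["predicted_category"] = [SpeedCategory(int(c)) for c in codes]
    return out


@dataclass
class ClassificationReport:
    """Confusion matrix plus per-category performance of a classified table."""

    confusion_matrix: pd.DataFrame  # true category rows x predicted columns
    per_category: dict[SpeedCategory, tuple[float, float]]
    overall_accuracy: float

    @property
    def total(self) -> int:
        return int(self.confusion_matrix.to_numpy().sum())


def evaluate(table: pd.DataFrame) -> ClassificationReport:
    """Summarize a table carrying true ``category`` and ``predicted_category``.

    Sensitivity of a category is the fraction of its epochs predicted into
    it; specificity the fraction of all other epochs predicted elsewhere.
    """
    if len(table) == 0:
        raise GaitCountsError("cannot evaluate an empty table")
    if "predicted_category" not in table.columns:
        raise GaitCountsError("table has no predictions; run classify_table")
    names = [c.name for c in SpeedCategory]
    true = table["category"].map(lambda c: SpeedCategory(int(c)).name)
    pred = table["predicted_category"].map(lambda c: SpeedCategory(int(c)).name)
    cm = pd.crosstab(true, pred).reindex(index=names, columns=names,
                                         fill_value=0)
    cm.index.name = "true"
    cm.columns.name = "predicted"
    m = cm.to_numpy()
    total = m.sum()
    accuracy = float(np.trace(m) / total)

    per_cat: dict[SpeedCategory, tuple[float, float]] = {}
    for i, cat in enumerate(SpeedCategory):
        tp = m[i, i]
        fn = m[i, :].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        per_cat[cat] = (float(sens), float(spec))
    return ClassificationReport(confusion_matrix=cm, per_category=per_cat,
                                overall_accuracy=accuracy)
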
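"""Study-style summary tables from pipeline outputs.

Three renderings mirror the calibration workflow: per-category count
summaries (n, median, bootstrap percentile interval), the per-category
calibration report (interval, sensitivity, specificity, AUC with grade) and
the final cut-point intervals per placement. The published study tables do
not document their interval construction, so the count summary reports a
clearly labeled percentile bootstrap interval of the median instead.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import CATEGORY_BANDS, SpeedCategory
from .roc import CutPointTable

SUMMARY_COLUMNS = [
    "placement", "axis", "epoch_length_s", "filter_mode", "category", "n",
    "median", "boot_low", "boot_high",
]


def _bootstrap_median_interval(values: np.ndarray, n_boot: int,
                               rng: np.random.Generator,
                               level: float = 0.95) -> tuple[float, float]:
    if len(values) == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(medians, alpha)),
            float(np.quantile(medians, 1.0 - alpha)))


def summarize_counts(
    table: pd.DataFrame,
    axes: tuple[str, ...] = ("v", "vm"),
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """One summary row per stratum x axis x category.

    Medians are exact sample medians; intervals are seeded percentile
    bootstrap (default 2,000 resamples) intervals of the median. Empty
    strata are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    strata = table.groupby(["placement", "epoch_length_s", "filter_mode"],
                           sort=True)
    for (placement, epoch_len, fmode), grp in strata:
        for axis in axes:
            col = f"count_{axis}"
            for cat in SpeedCategory:
                vals = grp.loc[grp["category"].astype(int) == int(cat),
                               col].to_numpy()
                if len(vals) == 0:
                    warnings.warn(
                        f"empty category {cat.name} in stratum "
                        f"{placement}/{axis}/{epoch_len}s; omitted",
                        stacklevel=2,
                    )
                    continue
                lo, hi = _bootstrap_median_interval(vals, n_boot, rng)
                rows.append({
                    "placement": placement, "axis": axis,
                    "epoch_length_s": epoch_len, "filter_mode": fmode,
                    "category": cat.name, "n": len(vals),
                    "median": float(np.median(vals)),
                    "boot_low": lo, "boot_high": hi,
                })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def cutpoint_intervals_table(cuts_by_placement: dict[str, CutPointTable]) -> pd.DataFrame:
    """Final cut-point intervals, one row per category, placements as columns."""
    data = {"category": [c.name for c in SpeedCategory],
            "band": [CATEGORY_BANDS[c] for c in SpeedCategory]}
    for placement in sorted(cuts_by_placement):
        cuts = cuts_by_placement[placement]
        intervals = cuts.intervals()
        label = f"{placement}_{cuts.axis}_counts_per_{cuts.epoch_length_s}s"
        data[label] = [intervals[c] for c in SpeedCategory]
    return pd.DataFrame(data)


def _fixed_width(df: pd.DataFrame) -> str:
    if len(df) == 0:
        return "  ".join(map(str, df.columns)) + "\n"
    return df.to_string(index=False) + "\n"


def render_tables(
    outdir,
    summary: pd.DataFrame | None = None,
    calibration: pd.DataFrame | None = None,
    evaluation: pd.DataFrame | None = None,
    cutpoints: pd.DataFrame | None = None,
    fixed_width: bool = False,
) -> list[Path]:
    """Write the provided tables as CSV (and optionally fixed-width text).

    Pure function of its inputs: identical inputs produce byte-identical
    files. Floats are rendered with two decimals, counts as integers.
    Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    named = {"count_summary": summary, "calibration": calibration,
             "evaluation": evaluation, "cutpoints": cutpoints}
    for name, df in named.items():
        if df is None:
            continue
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(lambda x: f"{x:.2f}")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        if fixed_width:
            txt = outdir / f"{name}.txt"
            txt.write_text(_fixed_width(df))
            written.append(txt)
    return written
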
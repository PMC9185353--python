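"""Open emulation of the accelerometer count digitization chain.

ActiGraph-style activity counts are produced by a proprietary pipeline; this
module re-creates its published structure with documented, inspectable
defaults: a zero-phase Butterworth band-pass (0.25-2.5 Hz by default, or a
low-frequency extension mode that opens the low cut to 0.05 Hz), 12-bit
analog-to-digital quantization centred at mid-scale, rectification, a
dead-band below which motion contributes nothing, clipping at a ceiling,
amplitude quantization, and per-second summation. Bit-exact equivalence with
the vendor chain is explicitly not a contract; monotonicity (more in-band
acceleration never yields fewer counts) and zero-input -> zero-count are.

Counts for the three axes (vertical, anterior-posterior, medio-lateral) are
kept at a 1 s base epoch together with a per-second vector-magnitude (VM)
series, so that aggregation to 15 s or 60 s epochs is a plain integer sum for
every series, VM included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

AXES = ("v", "ap", "ml")

#: Defaults of the count emulation (g units).
DEFAULT_DEADBAND_G = 0.05
DEFAULT_CEILING_G = 2.13
DEFAULT_QUANTUM_G = 1.0 / 128.0

ADC_BITS = 12
ADC_LEVELS = 2 ** ADC_BITS          # 4096
ADC_MID = ADC_LEVELS // 2           # 2048, the zero-acceleration level
ADC_RANGE_G = 6.0                   # device dynamic range is +/- 6 g


@dataclass
class AccelSignal:
    """Tri-axial acceleration time series in g at a fixed sampling rate."""

    sampling_rate_hz: float
    v: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n = len(self.v)
        if n < 1 or len(self.ap) != n or len(self.ml) != n:
            raise ValueError("all three axes must have equal, non-zero length")
        for name, arr in zip(AXES, (self.v, self.ap, self.ml)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"axis {name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.v)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    def axes(self) -> dict[str, np.ndarray]:
        return {"v": self.v, "ap": self.ap, "ml": self.ml}


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; ``lfe`` opens the low cut for slow movement."""

    mode: str = "default"
    low_cut_hz: float = 0.25
    high_cut_hz: float = 2.5
    order: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("default", "lfe"):
            raise ValueError(f"unknown filter mode: {self.mode!r}")
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 1:
            raise ValueError("order must be a positive integer")

    @classmethod
    def for_mode(cls, mode: str) -> "FilterSpec":
        if mode == "default":
            return cls()
        if mode == "lfe":
            return cls(mode="lfe", low_cut_hz=0.05)
        raise ValueError(f"unknown filter mode: {mode!r}")


@dataclass
class CountSeries:
    """Per-second integer counts for the three axes plus vector magnitude."""

    placement: str
    filter_mode: str
    counts_v: np.ndarray
    counts_ap: np.ndarray
    counts_ml: np.ndarray
    counts_vm: np.ndarray
    base_epoch_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("counts_v", "counts_ap", "counts_ml", "counts_vm"):
            arr = np.asarray(getattr(self, name))
            if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer)):
                raise ValueError(f"{name} must be non-negative integers")
            setattr(self, name, arr.astype(np.int64))
        n = len(self.counts_v)
        if any(len(getattr(self, f"counts_{a}")) != n for a in AXES) or len(self.counts_vm) != n:
            raise ValueError("all count series must have equal length")

    def __len__(self) -> int:
        return len(self.counts_v)


def bandpass(sig: AccelSignal, spec: FilterSpec | None = None) -> AccelSignal:
    """Zero-phase band-pass filter applied independently to each axis.

    Raises ``ValueError`` when the sampling rate violates the Nyquist
    precondition (fs must exceed twice the upper cut-off).
    """
    spec = spec or FilterSpec()
    if sig.sampling_rate_hz <= 2 * spec.high_cut_hz:
        raise ValueError(
            f"sampling rate {sig.sampling_rate_hz} Hz must exceed twice the "
            f"upper cut-off {spec.high_cut_hz} Hz"
        )
    sos = sps.butter(
        spec.order,
        [spec.low_cut_hz, spec.high_cut_hz],
        btype="bandpass",
        fs=sig.sampling_rate_hz,
        output="sos",
    )
    out = {name: sps.sosfiltfilt(sos, arr) for name, arr in sig.axes().items()}
    return AccelSignal(
        sampling_rate_hz=sig.sampling_rate_hz,
        v=out["v"], ap=out["ap"], ml=out["ml"],
        t0_s=sig.t0_s,
    )


def adc_digitize(accel_g: np.ndarray | float) -> np.ndarray:
    """Map acceleration in g to 12-bit converter levels.

    Zero acceleration sits at the centre of the scale (level 2048 of 4096);
    the full +/- 6 g range spans the 4096 levels.
    """
    lsb = 2 * ADC_RANGE_G / ADC_LEVELS
    levels = np.rint(np.asarray(accel_g, dtype=float) / lsb) + ADC_MID
    return np.clip(levels, 0, ADC_LEVELS - 1).astype(np.int64)


def adc_to_g(levels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`adc_digitize` (up to quantization)."""
    lsb = 2 * ADC_RANGE_G / ADC_LEVELS
    return (np.asarray(levels, dtype=float) - ADC_MID) * lsb


def vector_magnitude(count_v, count_ap, count_ml, method: str = "euclidean"):
    """Combine the three axis counts into a single vector-magnitude count.

    The conventional combination is the Euclidean norm rounded to the nearest
    integer; ``method='sum'`` gives the plain arithmetic sum instead. Accepts
    scalars or equal-length arrays of non-negative integers.
    """
    v = np.asarray(count_v)
    ap = np.asarray(count_ap)
    ml = np.asarray(count_ml)
    for arr in (v, ap, ml):
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
    if method == "euclidean":
        vm = np.rint(np.sqrt(v.astype(float) ** 2 + ap.astype(float) ** 2
                             + ml.astype(float) ** 2)).astype(np.int64)
    elif method == "sum":
        vm = (v + ap + ml).astype(np.int64)
    else:
        raise ValueError(f"unknown vector-magnitude method: {method!r}")
    if vm.ndim == 0:
        return int(vm)
    return vm


def accel_to_counts(
    filtered: AccelSignal,
    deadband_g: float = DEFAULT_DEADBAND_G,
    ceiling_g: float = DEFAULT_CEILING_G,
    quantum_g: float = DEFAULT_QUANTUM_G,
    placement: str = "waist",
    filter_mode: str = "default",
    vm_method: str = "euclidean",
) -> CountSeries:
    """Convert band-pass-filtered acceleration to per-second counts.

    Chain per axis: 12-bit digitization about mid-scale, rectification,
    dead-band suppression, clipping at the ceiling, quantization in steps of
    ``quantum_g`` and integer summation over each whole second. The trailing
    partial second is discarded. Counts are monotone in signal amplitude:
    scaling the in-band signal up never decreases any second's count.
    """
    if quantum_g <= 0:
        raise ValueError("quantum_g must be positive")
    if deadband_g < 0:
        raise ValueError("deadband_g must be non-negative")
    if not deadband_g < ceiling_g:
        raise ValueError("deadband_g must be below ceiling_g")
    fs = filtered.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("sampling rate must be a whole number of Hz")
    fs = int(round(fs))
    n_sec = len(filtered) // fs

    per_axis: dict[str, np.ndarray] = {}
    for name, arr in filtered.axes().items():
        x = np.abs(adc_to_g(adc_digitize(arr)))
        x = np.where(x < deadband_g, 0.0, np.minimum(x, ceiling_g))
        q = np.floor(x / quantum_g).astype(np.int64)
        per_axis[name] = q[: n_sec * fs].reshape(n_sec, fs).sum(axis=1)

    vm = vector_magnitude(per_axis["v"], per_axis["ap"], per_axis["ml"],
                          method=vm_method)
    return CountSeries(
        placement=placement,
        filter_mode=filter_mode,
        counts_v=per_axis["v"],
        counts_ap=per_axis["ap"],
        counts_ml=per_axis["ml"],
        counts_vm=np.asarray(vm),
    )


def aggregate_epochs(
    series: CountSeries,
    epoch_length_s: int,
    allow_any_length: bool = False,
) -> pd.DataFrame:
    """Sum 1 s base counts into fixed-length epochs.

    Returns a frame with one row per whole epoch (columns ``epoch_index``,
    ``epoch_length_s``, ``count_v``, ``count_ap``, ``count_ml``,
    ``count_vm``); a trailing partial epoch is discarded. Epoch lengths other
    than 15 s and 60 s are rejected unless ``allow_any_length`` is set.
    """
    if epoch_length_s not in (15, 60) and not allow_any_length:
        raise ValueError(
            f"epoch_length_s must be 15 or 60 (got {epoch_length_s}); "
            "pass allow_any_length=True to override"
        )
    if epoch_length_s < 1 or int(epoch_length_s) != epoch_length_s:
        raise ValueError("epoch_length_s must be a positive whole number")
    L = int(epoch_length_s)
    if series.base_epoch_s != 1.0:
        raise ValueError("aggregation expects a 1 s base epoch")
    n_ep = len(series) // L
    data = {"epoch_index": np.arange(n_ep), "epoch_length_s": L}
    for col, name in (("count_v", "counts_v"), ("count_ap", "counts_ap"),
                      ("count_ml", "counts_ml"), ("count_vm", "counts_vm")):
        arr = getattr(series, name)[: n_ep * L]
        data[col] = arr.reshape(n_ep, L).sum(axis=1)
    return pd.DataFrame(data)
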
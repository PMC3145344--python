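"""Baseline-wander removal and high-frequency artifact suppression.

Each lead is cleaned in two stages before feature extraction:

1. the baseline is estimated by two cascaded running-median filters
   (default windows 0.2 s and 0.6 s) and subtracted — this tracks slow
   respiratory drift while leaving QRS complexes untouched;
2. a zero-phase low-pass (4th-order Butterworth applied forward-backward,
   default cutoff 35 Hz) removes powerline and muscle noise.

Medians are computed on centered, edge-truncated windows so the output
length equals the input length.  The default window lengths and cutoff
follow the filtering lineage commonly used for MIT-BIH interpatient
classification; they are configurable through :class:`FilterSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ECGRecord

__all__ = ["FilterSpec", "filter_record", "remove_baseline", "lowpass"]


@dataclass(frozen=True)
class FilterSpec:
    baseline_window_1: float = 0.2  # seconds, first median stage
    baseline_window_2: float = 0.6  # seconds, second median stage
    lowpass_cutoff: float = 35.0    # Hz

    def validate(self, fs: float) -> None:
        if self.baseline_window_1 <= 0 or self.baseline_window_2 <= 0:
            raise ValueError("baseline windows must be positive")
        if not 0 < self.lowpass_cutoff < fs / 2:
            raise ValueError(
                f"lowpass cutoff must lie in (0, fs/2) = (0, {fs / 2:g})"
            )


def _odd_window(seconds: float, fs: float) -> int:
    w = max(1, round(seconds * fs))
    return w if w % 2 else w + 1


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def remove_baseline(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Subtract the two-stage running-median baseline estimate."""
    w1 = _odd_window(spec.baseline_window_1, fs)
    w2 = _odd_window(spec.baseline_window_2, fs)
    baseline = _running_median(_running_median(x, w1), w2)
    return x - baseline


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (linear in its input)."""
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def filter_record(rec: ECGRecord, spec: FilterSpec | None = None) -> ECGRecord:
    """Return a new record with baseline and high-frequency noise removed."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    min_len = _odd_window(max(spec.baseline_window_1, spec.baseline_window_2), rec.fs) + 1
    if rec.n_samples < min_len:
        raise ValueError(
            f"record {rec.record_id!r} has {rec.n_samples} samples; at least "
            f"{min_len} are required for the {spec.baseline_window_2:g} s "
            "baseline window"
        )
    out = np.stack(
        [
            lowpass(remove_baseline(lead, rec.fs, spec), rec.fs, spec.lowpass_cutoff)
            for lead in rec.lead_signals
        ]
    )
    return replace_signals(rec, out)


def replace_signals(rec: ECGRecord, signals: np.ndarray) -> ECGRecord:
    return ECGRecord(rec.record_id, rec.fs, signals, rec.lead_names)
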
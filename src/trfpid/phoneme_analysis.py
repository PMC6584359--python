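"""Event-locked epoching and decoding of manner-of-articulation classes.

A continuous response is cut into epochs around phoneme onsets, averaged per
manner class (phoneme-related fields), scanned for class information with
equipopulated-bin MI per time point, and — to test whether observed
class information exceeds what a forward model predicts — decomposed per
time point into contributions redundant and unique to observed vs predicted
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .core import EventTable
from .features import onset_to_sample
from .infotheory import binned_mi, pid_ccs, PIDResult

__all__ = ["EpochSet", "epoch_events", "class_average", "mi_timecourse",
           "mi_objective", "pid_timecourse"]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Event x time matrix with per-event class labels."""

    epochs: np.ndarray                  # events x time samples
    window: tuple[float, float]
    rate: float
    classes: np.ndarray                 # per-event labels (object or int)
    times: np.ndarray                   # per-sample latency in seconds

    @property
    def n_events(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def class_codes(self) -> np.ndarray:
        _, codes = np.unique(self.classes, return_inverse=True)
        return codes


def epoch_events(signal: np.ndarray, events: EventTable,
                 window: tuple[float, float] = (-0.1, 0.6),
                 rate: float = 40.0) -> EpochSet:
    """Extract per-event windows around onsets (nearest-sample alignment).

    Events whose window would run outside the recording are dropped with a
    logged count.  Overlapping epochs are allowed.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    lo = int(round(window[0] * rate))
    hi = int(round(window[1] * rate))
    centers = onset_to_sample(events.onsets, rate)
    valid = (centers + lo >= 0) & (centers + hi < len(signal))
    n_dropped = int(np.count_nonzero(~valid))
    if n_dropped:
        logger.info("dropped %d events with out-of-range windows", n_dropped)
    centers = centers[valid]
    if centers.size == 0:
        raise ValueError("no events with complete windows")
    offsets = np.arange(lo, hi + 1)
    epochs = signal[centers[:, None] + offsets[None, :]]
    return EpochSet(epochs=epochs, window=window, rate=rate,
                    classes=events.manner_classes[valid],
                    times=offsets / rate)


def class_average(epochs: EpochSet) -> dict[str, np.ndarray]:
    """Mean time course per class (phoneme-related fields)."""
    out = {}
    for cls in np.unique(epochs.classes):
        sel = epochs.classes == cls
        if not np.any(sel):
            raise ValueError(f"class {cls!r} has no events")
        out[str(cls)] = epochs.epochs[sel].mean(axis=0)
    return out


def mi_timecourse(epochs: EpochSet, n_bins: int = 4,
                  miller_madow: bool = False) -> np.ndarray:
    """Binned MI between epoch values and class labels at every time point."""
    codes = epochs.class_codes
    _, counts = np.unique(codes, return_counts=True)
    if counts.min() < 20:
        raise ValueError("need at least 20 events per class")
    return np.array([binned_mi(epochs.epochs[:, t], codes, n_bins,
                               miller_madow)
                     for t in range(epochs.n_times)])


def mi_objective(epochs: EpochSet, n_bins: int = 4) -> float:
    """Class-MI time course summed over time points.

    The scalar objective maximized when selecting response channels for the
    event-locked decoding analysis.
    """
    return float(mi_timecourse(epochs, n_bins).sum())


def pid_timecourse(observed: EpochSet, predicted: EpochSet,
                   n_mc: int = 50_000, seed: int = 0) -> list[PIDResult]:
    """Per-time-point decomposition of class information carried by observed
    vs predicted epochs (sources) about the manner classes (target)."""
    if observed.epochs.shape != predicted.epochs.shape:
        raise ValueError("observed and predicted epochs must match")
    if not np.array_equal(observed.classes, predicted.classes):
        raise ValueError("event class labels must match")
    codes = observed.class_codes
    return [pid_ccs(observed.epochs[:, t], predicted.epochs[:, t], codes,
                    n_mc=n_mc, seed=seed + t)
            for t in range(observed.n_times)]
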
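"""Shared container types used across the pipeline.

Two data structures travel through almost every stage: :class:`FeatureSpace`
(a time x channel matrix at a stated sampling rate, with a named partition of
the channel axis into subspaces) and :class:`EventTable` (discrete event
onsets with phoneme labels, articulatory feature sets and manner classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["FeatureSpace", "EventTable", "child_rng"]

#: The four manner-of-articulation classes used as decoding targets.
MANNER_CLASSES = ("vowel", "nasal", "plosive", "fricative")


def child_rng(seed: int, *path: object) -> np.random.Generator:
    """Derive an independent substream from a global seed.

    Every stochastic operation in the package draws from its own substream
    keyed by ``(seed, path...)`` so that stages can be regenerated
    independently of call order.  Path elements are hashed with a stable
    digest (not the process-randomized builtin ``hash``) so results are
    bit-reproducible across processes.
    """
    import zlib
    ss = np.random.SeedSequence(
        [int(seed) & 0xFFFFFFFFFFFFFFFF] +
        [zlib.crc32(repr(p).encode()) for p in path])
    return np.random.default_rng(ss)


@dataclass
class FeatureSpace:
    """Time x channel matrix at a fixed sampling rate with subspace labels.

    Parameters
    ----------
    data : ndarray, shape (n_times, n_channels)
    rate : float
        Sampling rate in Hz.
    name : str
        Identifier, e.g. ``"Sg"``, ``"Sg & Deriv"``.
    subspaces : list of (str, (start, stop))
        Ordered channel-index ranges (half-open) that partition the channel
        axis.  Defaults to a single subspace covering everything.
    """

    data: np.ndarray
    rate: float
    name: str = ""
    subspaces: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("FeatureSpace data must be 2-D (time x channel)")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not self.subspaces:
            self.subspaces = [(self.name or "all", (0, self.n_channels))]
        self._check_partition()

    def _check_partition(self) -> None:
        pos = 0
        for sub_name, (start, stop) in self.subspaces:
            if start != pos or stop <= start:
                raise ValueError(
                    f"subspace ranges must partition the channel axis without "
                    f"overlap; got {sub_name}: ({start}, {stop}) at position {pos}")
            pos = stop
        if pos != self.n_channels:
            raise ValueError(
                f"subspaces cover {pos} channels but data has {self.n_channels}")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.rate

    def subspace_names(self) -> list[str]:
        return [name for name, _ in self.subspaces]

    def subspace_slice(self, name: str) -> slice:
        for sub_name, (start, stop) in self.subspaces:
            if sub_name == name:
                return slice(start, stop)
        raise KeyError(f"no subspace named {name!r}; have {self.subspace_names()}")

    def with_data(self, data: np.ndarray, **kwargs) -> "FeatureSpace":
        return replace(self, data=data, **kwargs)


@dataclass
class EventTable:
    """Event onsets (seconds) with phoneme labels and derived groupings."""

    onsets: np.ndarray
    phonemes: np.ndarray
    articulatory_sets: list[frozenset]
    manner_classes: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.phonemes = np.asarray(self.phonemes, dtype=object)
        self.manner_classes = np.asarray(self.manner_classes, dtype=object)
        n = len(self.onsets)
        if not (len(self.phonemes) == len(self.articulatory_sets)
                == len(self.manner_classes) == n):
            raise ValueError("EventTable columns must have equal length")
        if n > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def class_indices(self) -> np.ndarray:
        """Manner classes as integer codes in the canonical order."""
        lookup = {c: i for i, c in enumerate(MANNER_CLASSES)}
        return np.array([lookup[c] for c in self.manner_classes], dtype=int)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "onset_s": self.onsets,
            "phoneme": self.phonemes,
            "class": self.manner_classes,
        })


def as_2d(x: np.ndarray) -> np.ndarray:
    """View samples as (n, d); 1-D input becomes a single column."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[:, None]
    if x.ndim != 2:
        raise ValueError("expected 1-D or 2-D sample array")
    return x


def check_finite(x: np.ndarray, name: str = "input") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
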
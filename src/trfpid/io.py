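"""File interfaces: WAV audio, TSV/TextGrid annotations, HDF5 containers."""

from __future__ import annotations

import re
import warnings

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .artic import articulatory_set, load_mapping, manner_class
from .core import EventTable, FeatureSpace

__all__ = ["read_audio", "read_events_tsv", "read_events_textgrid",
           "write_events_tsv", "save_feature_space", "load_feature_space",
           "save_response", "load_response"]


def read_audio(path: str) -> tuple[np.ndarray, float]:
    """Mono waveform as float in [-1, 1] plus its sampling rate."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    data = data.astype(float)
    if data.ndim == 2:
        warnings.warn("stereo audio averaged to mono")
        data = data.mean(axis=1)
    return data, float(sr)


def _events_from_frame(frame: pd.DataFrame, mapping_path: str | None
                       ) -> EventTable:
    table = load_mapping(mapping_path)
    phonemes = frame["phoneme"].astype(str).str.upper().str.replace(
        r"\d+$", "", regex=True)
    known = phonemes.isin(table.index)
    if not known.all():
        warnings.warn(f"dropping {int((~known).sum())} events with unmapped "
                      f"phonemes: {sorted(set(phonemes[~known]))[:10]}")
    frame = frame[known.values]
    phonemes = phonemes[known.values]
    return EventTable(
        onsets=frame["onset_s"].to_numpy(dtype=float),
        phonemes=phonemes.to_numpy(dtype=object),
        articulatory_sets=[articulatory_set(p, table) for p in phonemes],
        manner_classes=np.array([manner_class(p, table) for p in phonemes],
                                dtype=object))


def read_events_tsv(path: str, mapping_path: str | None = None) -> EventTable:
    frame = pd.read_csv(path, sep="\t")
    if "onset_s" not in frame.columns or "phoneme" not in frame.columns:
        raise ValueError("event TSV needs columns onset_s and phoneme")
    return _events_from_frame(frame.sort_values("onset_s"), mapping_path)


_TG_INTERVAL = re.compile(
    r"intervals\s*\[\d+\]\s*:\s*xmin\s*=\s*([\d.eE+-]+)\s*"
    r"xmax\s*=\s*([\d.eE+-]+)\s*text\s*=\s*\"([^\"]*)\"", re.S)


def read_events_textgrid(path: str, tier: str = "phones",
                         mapping_path: str | None = None) -> EventTable:
    """Minimal Praat TextGrid reader (long text format, interval tiers)."""
    with open(path) as fh:
        text = fh.read()
    tiers = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    rows = []
    for block in tiers:
        name_match = re.search(r"name\s*=\s*\"([^\"]*)\"", block)
        if name_match is None or name_match.group(1) != tier:
            continue
        for xmin, _xmax, label in _TG_INTERVAL.findall(block):
            label = label.strip()
            if label and label.lower() not in ("sil", "sp", ""):
                rows.append((float(xmin), label))
    if not rows:
        raise ValueError(f"no labelled intervals in tier {tier!r}")
    frame = pd.DataFrame(rows, columns=["onset_s", "phoneme"])
    return _events_from_frame(frame.sort_values("onset_s"), mapping_path)


def write_events_tsv(events: EventTable, path: str) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def save_feature_space(fs: FeatureSpace, path: str, key: str = "features"
                       ) -> None:
    with h5py.File(path, "a") as fh:
        if key in fh:
            del fh[key]
        grp = fh.create_group(key)
        grp.create_dataset("data", data=fs.data)
        grp.attrs["rate_hz"] = fs.rate
        grp.attrs["name"] = fs.name
        grp.attrs["subspace_names"] = [n for n, _ in fs.subspaces]
        grp.attrs["subspace_ranges"] = [list(r) for _, r in fs.subspaces]


def load_feature_space(path: str, key: str = "features") -> FeatureSpace:
    with h5py.File(path, "r") as fh:
        grp = fh[key]
        names = [n if isinstance(n, str) else n.decode()
                 for n in grp.attrs["subspace_names"]]
        ranges = [tuple(int(v) for v in r)
                  for r in grp.attrs["subspace_ranges"]]
        return FeatureSpace(grp["data"][()], rate=float(grp.attrs["rate_hz"]),
                            name=str(grp.attrs["name"]),
                            subspaces=list(zip(names, ranges)))


def save_response(data: np.ndarray, rate: float, path: str,
                  key: str = "response") -> None:
    with h5py.File(path, "a") as fh:
        if key in fh:
            del fh[key]
        ds = fh.create_dataset(key, data=np.asarray(data, dtype=float))
        ds.attrs["rate_hz"] = rate


def load_response(path: str, key: str = "response"
                  ) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as fh:
        ds = fh[key]
        return ds[()], float(ds.attrs["rate_hz"])
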
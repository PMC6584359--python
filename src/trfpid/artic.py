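"""Phoneme-to-articulatory-feature and phoneme-to-manner-class mappings.

A default ARPAbet mapping (23 binary articulatory features, 4 manner
classes) ships as package data and can be overridden with a user TSV of the
same layout: one row per phoneme, a ``manner_class`` column and 23 binary
feature columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import MANNER_CLASSES

__all__ = ["load_mapping", "ARTICULATORY_FEATURES", "articulatory_set",
           "manner_class"]

_DEFAULT = None


def load_mapping(path: str | None = None) -> pd.DataFrame:
    """Load a phoneme mapping table (default: the packaged ARPAbet table)."""
    if path is None:
        global _DEFAULT
        if _DEFAULT is None:
            with resources.files("trfpid.data").joinpath(
                    "articulatory_features.tsv").open() as fh:
                _DEFAULT = _validate(pd.read_csv(fh, sep="\t"))
        return _DEFAULT
    return _validate(pd.read_csv(path, sep="\t"))


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"phoneme", "manner_class"}
    if not required <= set(table.columns):
        raise ValueError(f"mapping table needs columns {sorted(required)}")
    bad = set(table["manner_class"]) - set(MANNER_CLASSES)
    if bad:
        raise ValueError(f"unknown manner classes {sorted(bad)}; "
                         f"expected one of {MANNER_CLASSES}")
    return table.set_index("phoneme")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "manner_class"]


ARTICULATORY_FEATURES = tuple(_feature_columns(load_mapping()))


def articulatory_set(phoneme: str, table: pd.DataFrame | None = None
                     ) -> frozenset:
    table = load_mapping() if table is None else table
    row = table.loc[phoneme]
    return frozenset(c for c in _feature_columns(table) if row[c] == 1)


def manner_class(phoneme: str, table: pd.DataFrame | None = None) -> str:
    table = load_mapping() if table is None else table
    return str(table.loc[phoneme, "manner_class"])
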
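"""Responsivity maps from repeated presentations and iterative unique-
information mapping over leakage-correlated grids.

Neighboring grid points of a source reconstruction are strongly correlated
by leakage, so a map of repeat reliability is redundant.  The iterative
procedure starts from seed points, decomposes every other grid point's
repeat-predictive information into parts shared with the selected set and
parts unique to the point, and greedily adds the point with peak unique
information — revealing how many effective sources the grid contains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infotheory import mi_gaussian_copula, pid_ccs

__all__ = ["GridRecording", "responsivity_map", "iterative_unique_mapping"]


@dataclass
class GridRecording:
    """Two repeated presentations of identical material over a channel grid."""

    repetition_1: np.ndarray        # time x grid points
    repetition_2: np.ndarray
    grid_ids: list | None = None

    def __post_init__(self) -> None:
        self.repetition_1 = np.atleast_2d(np.asarray(self.repetition_1, float))
        self.repetition_2 = np.atleast_2d(np.asarray(self.repetition_2, float))
        if self.repetition_1.shape != self.repetition_2.shape:
            raise ValueError("repetitions must have equal shapes")
        if not (np.all(np.isfinite(self.repetition_1))
                and np.all(np.isfinite(self.repetition_2))):
            raise ValueError("grid recordings contain non-finite values")
        if self.grid_ids is None:
            self.grid_ids = list(range(self.repetition_1.shape[1]))

    @property
    def n_points(self) -> int:
        return self.repetition_1.shape[1]


def responsivity_map(grid: GridRecording, metric: str = "r2") -> np.ndarray:
    """Per-grid-point repeat reliability: squared correlation or copula MI.

    Constant channels get NaN (flagged, not fatal).
    """
    if grid.repetition_1.shape[0] < 100:
        raise ValueError("need at least 100 samples")
    if metric not in ("r2", "mi"):
        raise ValueError(f"metric must be 'r2' or 'mi', got {metric!r}")
    out = np.full(grid.n_points, np.nan)
    for g in range(grid.n_points):
        a = grid.repetition_1[:, g]
        b = grid.repetition_2[:, g]
        if a.std() == 0 or b.std() == 0:
            continue
        if metric == "r2":
            out[g] = np.corrcoef(a, b)[0, 1] ** 2
        else:
            out[g] = mi_gaussian_copula(a, b)
    return out


@dataclass
class MappingIteration:
    redundancy_map: np.ndarray
    unique_map: np.ndarray
    chosen_point: int
    selected_before: list[int]


def iterative_unique_mapping(grid: GridRecording, seed_points: list[int],
                             n_iterations: int = 10, n_mc: int = 20_000,
                             seed: int = 0) -> list[MappingIteration]:
    """Greedy unique-information source search.

    Iteration k uses the first-repetition activity at the currently selected
    set as one (multivariate) source; for every other grid point g, the
    first-repetition activity at g is the second source and the
    second-repetition activity at g the target.  The argmax of the unique
    map joins the selected set.
    """
    selected = list(dict.fromkeys(int(p) for p in seed_points))
    if len(selected) != len(seed_points):
        raise ValueError("seed points must be distinct")
    results = []
    for it in range(n_iterations):
        source1 = grid.repetition_1[:, selected]
        red_map = np.full(grid.n_points, np.nan)
        unq_map = np.full(grid.n_points, np.nan)
        for g in range(grid.n_points):
            if g in selected:
                continue
            try:
                pid = pid_ccs(source1, grid.repetition_1[:, g],
                              grid.repetition_2[:, g], n_mc=n_mc,
                              seed=seed * 101 + it)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"selected-set covariance singular at iteration {it}; "
                    "try fewer iterations") from exc
            red_map[g] = pid.redundancy
            unq_map[g] = pid.unique_y
        chosen = int(np.nanargmax(unq_map))
        results.append(MappingIteration(redundancy_map=red_map,
                                        unique_map=unq_map,
                                        chosen_point=chosen,
                                        selected_before=list(selected)))
        selected.append(chosen)
    return results
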
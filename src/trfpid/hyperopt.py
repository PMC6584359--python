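"""Black-box hyperparameter optimization and autocorrelation-based lag allocation.

:func:`optimize` is a derivative-free maximizer fulfilling a simple contract:
all proposals stay inside the box, runs are deterministic given the seed, and
the best evaluated point plus the full evaluation trace are returned.  The
default implementation is a surrogate-assisted direct search: a radial-basis
surrogate fitted to all evaluated points proposes promising candidates, and
shrinking poll steps around the incumbent provide local refinement.  It is a
stand-in for more elaborate Bayesian direct-search algorithms, not a port of
any of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.stats import qmc

__all__ = ["HyperBox", "optimize", "autocorrelation_time",
           "allocate_gabor_lags"]


@dataclass
class HyperBox:
    """Per-parameter (name, lower, upper, init, scale) box constraints."""

    params: list[tuple[str, float, float, float, str]]

    def __post_init__(self) -> None:
        for name, lo, hi, init, scale in self.params:
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper")
            if not lo <= init <= hi:
                raise ValueError(f"{name}: init {init} outside [{lo}, {hi}]")
            if scale not in ("linear", "log"):
                raise ValueError(f"{name}: unknown scale {scale!r}")

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.params]

    @property
    def lower(self) -> np.ndarray:
        return np.array([p[1] for p in self.params])

    @property
    def upper(self) -> np.ndarray:
        return np.array([p[2] for p in self.params])

    @property
    def init(self) -> np.ndarray:
        return np.array([p[3] for p in self.params])

    def __len__(self) -> int:
        return len(self.params)


def _to_unit(x: np.ndarray, box: HyperBox) -> np.ndarray:
    return (x - box.lower) / (box.upper - box.lower)


def _from_unit(u: np.ndarray, box: HyperBox) -> np.ndarray:
    return box.lower + np.clip(u, 0.0, 1.0) * (box.upper - box.lower)


def optimize(objective, box: HyperBox, n_iter: int = 200, seed: int = 0
             ) -> tuple[np.ndarray, list[tuple[np.ndarray, float]]]:
    """Maximize ``objective`` over ``box`` with a fixed evaluation budget.

    Returns ``(best_params, trace)`` where trace is the list of
    ``(params, value)`` pairs in evaluation order.
    """
    d = len(box)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, d]))
    n_init = min(max(2 * d + 2, 6), max(n_iter // 3, 1))
    sob = qmc.Sobol(d, scramble=True, seed=rng.integers(2**31))
    n_pow2 = int(2 ** np.ceil(np.log2(max(n_init - 1, 1))))
    inits = sob.random(n_pow2)[:n_init - 1]
    points = np.vstack([_to_unit(box.init, box)[None, :], inits])

    trace: list[tuple[np.ndarray, float]] = []
    evaluated: list[np.ndarray] = []
    values: list[float] = []

    def evaluate(u: np.ndarray) -> float:
        x = _from_unit(u, box)
        try:
            val = float(objective(x))
        except Exception as exc:
            raise RuntimeError(
                f"objective failed at {dict(zip(box.names, x))}") from exc
        evaluated.append(u)
        values.append(val)
        trace.append((x, val))
        return val

    for u in points[:n_iter]:
        evaluate(u)

    radius = 0.25
    while len(values) < n_iter:
        best_i = int(np.argmax(values))
        incumbent = evaluated[best_i]
        U = np.array(evaluated)
        y = np.array(values)
        # candidate pool: global exploration + polls around the incumbent
        n_global = 64
        n_local = 64
        cands = np.vstack([
            rng.random((n_global, d)),
            np.clip(incumbent + radius * rng.standard_normal((n_local, d)),
                    0.0, 1.0),
        ])
        try:
            # deduplicate for the interpolator
            _, keep = np.unique(np.round(U, 10), axis=0, return_index=True)
            surrogate = RBFInterpolator(U[np.sort(keep)], y[np.sort(keep)],
                                        kernel="thin_plate_spline")
            pred = surrogate(cands)
        except Exception:
            pred = -np.linalg.norm(cands - incumbent, axis=1)
        u_next = cands[int(np.argmax(pred))]
        prev_best = max(values)
        val = evaluate(u_next)
        if val > prev_best:
            radius = min(0.5, radius * 1.6)     # successful step: expand
        else:
            radius = max(0.02, radius * 0.8)    # poll failed: contract
    best_i = int(np.argmax(values))
    return _from_unit(evaluated[best_i], box), trace


def incumbent_trace(trace) -> np.ndarray:
    """Running maximum of the objective along an evaluation trace."""
    return np.maximum.accumulate([v for _, v in trace])


def autocorrelation_time(x: np.ndarray, threshold: float = 0.05) -> int:
    """Shortest lag where the normalized absolute autocorrelation drops
    below ``threshold``."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("autocorrelation time undefined for constant series")
    n = len(x)
    # FFT-based autocorrelation, unbiased normalization per lag
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(spec * np.conj(spec))[:n]
    acf = raw / (n - np.arange(n)) / (denom / n)
    below = np.flatnonzero(np.abs(acf[1:]) < threshold)
    if below.size == 0:
        raise ValueError(
            f"autocorrelation never drops below {threshold} within the series")
    return int(below[0] + 1)


def allocate_gabor_lags(window_slow: tuple[float, float],
                        window_fast: tuple[float, float],
                        group_acts) -> list[tuple[float, float]]:
    """Spread lag windows across modulation groups proportionally to their
    mean autocorrelation times.

    The slowest group (largest ACT) receives ``window_slow``, the fastest
    receives ``window_fast``; intermediate groups are interpolated linearly
    in ACT between the two anchors.
    """
    acts = np.asarray(group_acts, dtype=float)
    if len(acts) < 2:
        raise ValueError("need at least 2 modulation groups")
    slow, fast = acts[0], acts[-1]
    if slow == fast:
        mid = tuple((a + b) / 2 for a, b in zip(window_slow, window_fast))
        return [mid for _ in acts]
    frac = (acts - fast) / (slow - fast)        # 1 at slow anchor, 0 at fast
    out = []
    for f in frac:
        t_min = window_fast[0] + f * (window_slow[0] - window_fast[0])
        t_max = window_fast[1] + f * (window_slow[1] - window_fast[1])
        out.append((float(t_min), float(t_max)))
    return out
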
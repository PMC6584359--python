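"""Lagged ridge regression (temporal response functions) and cross-validation.

The linear forward model is ``r_hat(t) = sum_ch sum_tau w(ch, tau) *
s(ch, t - tau)`` with integer lags ``tau`` from ``round(tMin*rate)`` to
``round(tMax*rate)``; positive lags read stimulus samples in the past,
negative lags in the future.  Weights come from the closed-form penalized
normal equations ``w = (S'S + Lambda)^-1 S'r`` where ``Lambda`` is block
diagonal: each feature subspace carries its own regularization value and its
own lag window.

Two cross-validation drivers are provided: :func:`nested_cv` (six equal
portions, inner tuning folds, black-box optimization of per-subspace
``(tMin, tMax, log10 lambda)``, hyperparameter and weight averaging) and
:func:`grid_search_cv` (block rotation with one shared lambda selected by
exhaustive grid search under a fixed lag window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import FeatureSpace

__all__ = [
    "LaggedDesign", "TRFModel", "CVScheme", "CVResult",
    "build_lagged_design", "fit_ridge", "predict", "pearson_score",
    "make_cv_scheme", "nested_cv", "grid_search_cv", "default_lambda_grid",
]


def lag_range(window_s: tuple[float, float], rate: float) -> np.ndarray:
    """Integer lags covering a window in seconds (inclusive both ends)."""
    t_min, t_max = window_s
    if t_min > t_max:
        raise ValueError(f"invalid lag window {window_s}")
    return np.arange(int(round(t_min * rate)), int(round(t_max * rate)) + 1)


def shift_column(x: np.ndarray, lag: int) -> np.ndarray:
    """x delayed by ``lag`` samples with zero padding (lag<0 advances)."""
    n = len(x)
    out = np.zeros_like(x)
    if lag >= 0:
        if lag < n:
            out[lag:] = x[:n - lag]
    else:
        if -lag < n:
            out[:n + lag] = x[-lag:]
    return out


@dataclass
class LaggedDesign:
    """Lagged stimulus matrix with per-subspace lag windows.

    Columns are grouped by subspace; within a subspace, by lag (ascending);
    within a lag group, feature channels are contiguous.
    """

    matrix: np.ndarray
    rate: float
    subspace_names: list[str]
    channel_slices: dict[str, slice]       # channels in the source FeatureSpace
    lags: dict[str, np.ndarray]            # integer lags per subspace
    column_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_lagged_design(features: FeatureSpace,
                        windows: dict[str, tuple[float, float]]
                        ) -> LaggedDesign:
    """Construct the lagged design matrix for given per-subspace windows."""
    for name in features.subspace_names():
        if name not in windows:
            raise ValueError(f"no lag window for subspace {name!r}")
    n = features.n_times
    blocks, lags, col_slices, ch_slices = [], {}, {}, {}
    pos = 0
    for name, (start, stop) in features.subspaces:
        sub_lags = lag_range(windows[name], features.rate)
        n_sec = len(sub_lags) / features.rate
        if n_sec > features.duration:
            raise ValueError(
                f"lag window {windows[name]} exceeds signal duration")
        sub = features.data[:, start:stop]
        cols = np.empty((n, len(sub_lags) * (stop - start)))
        for j, lag in enumerate(sub_lags):
            width = stop - start
            for c in range(width):
                cols[:, j * width + c] = shift_column(sub[:, c], int(lag))
        blocks.append(cols)
        lags[name] = sub_lags
        ch_slices[name] = slice(start, stop)
        col_slices[name] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    return LaggedDesign(matrix=np.hstack(blocks), rate=features.rate,
                        subspace_names=features.subspace_names(),
                        channel_slices=ch_slices, lags=lags,
                        column_slices=col_slices)


@dataclass
class TRFModel:
    """Fitted weights per subspace (channels x lags) with their lag windows."""

    weights: dict[str, np.ndarray]
    lags: dict[str, np.ndarray]
    lambdas: dict[str, float]
    rate: float

    def weight_vector(self, design: LaggedDesign) -> np.ndarray:
        parts = []
        for name in design.subspace_names:
            w = self.weights[name]
            parts.append(w.T.reshape(-1))       # lag-major, channels contiguous
        return np.concatenate(parts)


def penalty_diagonal(design: LaggedDesign,
                     lambdas: dict[str, float]) -> np.ndarray:
    diag = np.empty(design.n_columns)
    for name in design.subspace_names:
        lam = lambdas[name]
        if lam < 0 or not np.isfinite(lam):
            raise ValueError(f"lambda for {name!r} must be finite and >= 0")
        diag[design.column_slices[name]] = lam
    return diag


def fit_ridge(design: LaggedDesign, response: np.ndarray,
              lambdas: dict[str, float] | float) -> TRFModel:
    """Closed-form ridge solution with a block-diagonal penalty.

    ``lambdas`` may be a scalar (applied to every subspace) or a dict keyed
    by subspace name.  No intercept is fitted; inputs are assumed z-scored.
    """
    response = np.asarray(response, dtype=float).ravel()
    if len(response) != design.matrix.shape[0]:
        raise ValueError("design rows must match response length")
    if np.isscalar(lambdas):
        lambdas = {name: float(lambdas) for name in design.subspace_names}
    diag = penalty_diagonal(design, lambdas)
    gram = design.matrix.T @ design.matrix
    gram[np.diag_indices_from(gram)] += diag
    rhs = design.matrix.T @ response
    if np.all(diag == 0):
        rank = np.linalg.matrix_rank(gram)
        if rank < design.n_columns:
            raise np.linalg.LinAlgError(
                f"S'S is rank deficient (rank {rank} < {design.n_columns}) "
                "and no regularization was applied")
    w = linalg.solve(gram, rhs, assume_a="pos")
    weights = {}
    for name in design.subspace_names:
        block = w[design.column_slices[name]]
        n_ch = design.channel_slices[name].stop - design.channel_slices[name].start
        weights[name] = block.reshape(len(design.lags[name]), n_ch).T
    return TRFModel(weights=weights, lags=dict(design.lags),
                    lambdas=dict(lambdas), rate=design.rate)


def predict(model: TRFModel, features: FeatureSpace) -> np.ndarray:
    """Apply a fitted TRF to a feature space (zero-padded edges)."""
    out = np.zeros(features.n_times)
    for name, (start, stop) in features.subspaces:
        if name not in model.weights:
            raise ValueError(f"model has no weights for subspace {name!r}")
        w = model.weights[name]
        if w.shape[0] != stop - start:
            raise ValueError(
                f"subspace {name!r}: model expects {w.shape[0]} channels, "
                f"features have {stop - start}")
        sub = features.data[:, start:stop]
        for j, lag in enumerate(model.lags[name]):
            for c in range(sub.shape[1]):
                out += w[c, j] * shift_column(sub[:, c], int(lag))
    return out


def pearson_score(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sample Pearson correlation between prediction and observation."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("need equal-length series of at least 3 samples")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(pred, obs)[0, 1])


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

@dataclass
class CVScheme:
    """All ordered (test, tune) assignments over equal-duration portions."""

    assignments: list[tuple[tuple[int, ...], int, int]]  # (train, tune, test)
    n_portions: int


def make_cv_scheme(n_portions: int = 6) -> CVScheme:
    """Enumerate every assignment of portions to train/tune/test roles.

    Each portion serves as the outer test set; each remaining portion serves
    as the tuning set once, with the rest training — ``n*(n-1)`` assignments.
    """
    if n_portions < 3:
        raise ValueError("need at least 3 portions")
    assignments = []
    for test in range(n_portions):
        for tune in range(n_portions):
            if tune == test:
                continue
            train = tuple(p for p in range(n_portions)
                          if p not in (test, tune))
            assignments.append((train, tune, test))
    return CVScheme(assignments=assignments, n_portions=n_portions)


@dataclass
class FoldResult:
    test_portion: int
    prediction: np.ndarray
    observed: np.ndarray
    score: float
    hyperparams: dict
    model: TRFModel
    traces: list


@dataclass
class CVResult:
    folds: list[FoldResult]
    rate: float
    config: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.folds])

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean())

    def mean_weights(self, subspace: str) -> tuple[np.ndarray, np.ndarray]:
        """Fold-average weight tensor on the union lag axis.

        Returns ``(lags, weights)`` where weights is channels x lags; folds
        whose window does not cover a lag contribute zero there.
        """
        all_lags = sorted({int(l) for f in self.folds
                           for l in f.model.lags[subspace]})
        lag_index = {l: i for i, l in enumerate(all_lags)}
        n_ch = self.folds[0].model.weights[subspace].shape[0]
        acc = np.zeros((n_ch, len(all_lags)))
        for f in self.folds:
            w = f.model.weights[subspace]
            for j, lag in enumerate(f.model.lags[subspace]):
                acc[:, lag_index[int(lag)]] += w[:, j]
        return np.array(all_lags), acc / len(self.folds)


def _portion_bounds(n: int, n_portions: int) -> list[tuple[int, int]]:
    size = n // n_portions
    return [(p * size, (p + 1) * size) for p in range(n_portions)]


class _PortionCache:
    """Per-portion lagged designs at the maximal window plus their Grams.

    Hyperparameter search only ever selects contiguous lag sub-ranges, so the
    Gram matrix and cross-covariance of any candidate model are sub-blocks of
    the maximal-window quantities.  Each portion is lagged independently
    (zero padding at portion edges), which makes Grams additive over
    portions.
    """

    def __init__(self, features: FeatureSpace, response: np.ndarray,
                 n_portions: int, max_windows: dict[str, tuple[float, float]]):
        self.rate = features.rate
        self.subspaces = features.subspaces
        self.bounds = _portion_bounds(features.n_times, n_portions)
        self.designs, self.responses, self.grams, self.crosses = [], [], [], []
        response = np.asarray(response, dtype=float)
        if response.ndim == 1:
            response = response[:, None]
        for (a, b) in self.bounds:
            part = FeatureSpace(features.data[a:b], rate=features.rate,
                                name=features.name,
                                subspaces=[(n, r) for n, r in features.subspaces])
            design = build_lagged_design(part, max_windows)
            r = response[a:b]
            r = (r - r.mean(axis=0)) / r.std(axis=0)   # z-score per portion
            self.designs.append(design)
            self.responses.append(r)
            self.grams.append(design.matrix.T @ design.matrix)
            self.crosses.append(design.matrix.T @ r)
        self.template = self.designs[0]
        self.max_lags = {name: self.template.lags[name]
                         for name in self.template.subspace_names}

    def columns_for(self, windows: dict[str, tuple[int, int]]) -> np.ndarray:
        """Column indices for integer per-subspace lag sub-windows."""
        idx = []
        for name, (start, stop) in self.subspaces:
            width = stop - start
            full = self.max_lags[name]
            lo, hi = windows[name]
            base = self.template.column_slices[name].start
            j0 = int(np.searchsorted(full, lo))
            j1 = int(np.searchsorted(full, hi, side="right"))
            for j in range(j0, j1):
                idx.extend(range(base + j * width, base + (j + 1) * width))
        return np.array(idx, dtype=int)

    def lambda_diag(self, idx: np.ndarray,
                    lambdas: dict[str, float]) -> np.ndarray:
        full_diag = np.empty(self.template.n_columns)
        for name in self.template.subspace_names:
            full_diag[self.template.column_slices[name]] = lambdas[name]
        return full_diag[idx]

    def solve(self, train: tuple[int, ...], idx: np.ndarray,
              lam_diag: np.ndarray) -> np.ndarray:
        gram = sum(self.grams[p][np.ix_(idx, idx)] for p in train)
        gram[np.diag_indices_from(gram)] += lam_diag
        rhs = sum(self.crosses[p][idx] for p in train)
        w = linalg.solve(gram, rhs, assume_a="pos")
        return w[:, 0] if w.ndim == 2 and w.shape[1] == 1 else w

    def score(self, w: np.ndarray, idx: np.ndarray, portion: int) -> float:
        """Mean Pearson r over response channels on one portion."""
        pred = np.atleast_2d((self.designs[portion].matrix[:, idx] @ w).T).T
        obs = self.responses[portion]
        rs = []
        for c in range(obs.shape[1]):
            p = pred[:, c] if pred.shape[1] > 1 else pred[:, 0]
            if p.std() == 0:
                rs.append(-1.0)
            else:
                rs.append(float(np.corrcoef(p, obs[:, c])[0, 1]))
        return float(np.mean(rs))


def _unpack_params(vec: np.ndarray, names: list[str]) -> dict[str, dict]:
    out = {}
    for i, name in enumerate(names):
        t_min, t_max, log_lam = vec[3 * i: 3 * i + 3]
        out[name] = {"t_min": float(t_min), "t_max": float(t_max),
                     "log10_lambda": float(log_lam)}
    return out


def nested_cv(features: FeatureSpace, response: np.ndarray,
              scheme: CVScheme | None = None,
              optimizer=None,
              bounds: dict[str, dict[str, tuple[float, float]]] | None = None,
              n_iter: int = 200, seed: int = 0) -> CVResult:
    """Nested cross-validation with black-box hyperparameter optimization.

    Per outer fold, each inner assignment optimizes per-subspace
    ``(tMin, tMax, log10 lambda)`` against the tuning-set Pearson
    correlation; hyperparameters are averaged across inner folds (lag edges
    rounded toward wider windows), weights are retrained on every train
    assignment with the averaged hyperparameters and averaged, and the
    resulting model predicts the held-out test portion once.
    """
    from .hyperopt import HyperBox, optimize as default_optimize
    if scheme is None:
        scheme = make_cv_scheme(6)
    if optimizer is None:
        optimizer = default_optimize
    names = features.subspace_names()
    if bounds is None:
        bounds = {name: {"t_min": (-0.3, 0.0), "t_max": (0.05, 1.0),
                         "log10_lambda": (-3.0, 8.0)} for name in names}
    max_windows = {name: (bounds[name]["t_min"][0], bounds[name]["t_max"][1])
                   for name in names}
    cache = _PortionCache(features, response, scheme.n_portions, max_windows)
    rate = features.rate

    box_params = []
    for name in names:
        for key in ("t_min", "t_max", "log10_lambda"):
            lo, hi = bounds[name][key]
            # log10_lambda is already a log-scale coordinate
            box_params.append((f"{name}:{key}", lo, hi, (lo + hi) / 2,
                               "linear"))
    box = HyperBox(box_params)

    def make_objective(train, tune):
        def objective(vec):
            params = _unpack_params(np.asarray(vec), names)
            for name in names:
                lo, hi = bounds[name]["t_min"]
                lo2, hi2 = bounds[name]["t_max"]
                p = params[name]
                if not (lo - 1e-9 <= p["t_min"] <= hi + 1e-9
                        and lo2 - 1e-9 <= p["t_max"] <= hi2 + 1e-9):
                    raise RuntimeError(
                        f"optimizer proposed out-of-bounds parameters: {p}")
            windows = {name: (int(round(params[name]["t_min"] * rate)),
                              int(round(params[name]["t_max"] * rate)))
                       for name in names}
            lambdas = {name: 10.0 ** params[name]["log10_lambda"]
                       for name in names}
            idx = cache.columns_for(windows)
            lam_diag = cache.lambda_diag(idx, lambdas)
            w = cache.solve(train, idx, lam_diag)
            return cache.score(w, idx, tune)
        return objective

    folds = []
    for test in range(scheme.n_portions):
        inner = [(train, tune) for (train, tune, tst) in scheme.assignments
                 if tst == test]
        chosen, traces = [], []
        for k, (train, tune) in enumerate(inner):
            best, trace = optimizer(make_objective(train, tune), box,
                                    n_iter=n_iter, seed=seed * 1000 + test * 10 + k)
            chosen.append(_unpack_params(np.asarray(best), names))
            traces.append(trace)
        # average hyperparameters; round lag edges toward wider windows
        avg = {}
        for name in names:
            t_min = float(np.mean([c[name]["t_min"] for c in chosen]))
            t_max = float(np.mean([c[name]["t_max"] for c in chosen]))
            log_lam = float(np.mean([c[name]["log10_lambda"] for c in chosen]))
            avg[name] = {"t_min": t_min, "t_max": t_max,
                         "log10_lambda": log_lam,
                         "lag_lo": int(np.floor(t_min * rate)),
                         "lag_hi": int(np.ceil(t_max * rate))}
        windows = {name: (avg[name]["lag_lo"], avg[name]["lag_hi"])
                   for name in names}
        lambdas = {name: 10.0 ** avg[name]["log10_lambda"] for name in names}
        idx = cache.columns_for(windows)
        lam_diag = cache.lambda_diag(idx, lambdas)
        w_acc = np.zeros(len(idx))
        for train, tune in inner:
            w_acc += cache.solve(train, idx, lam_diag)
        w_mean = w_acc / len(inner)
        score = cache.score(w_mean, idx, test)
        pred = cache.designs[test].matrix[:, idx] @ w_mean

        weights, lag_map = {}, {}
        offset = 0
        for name, (start, stop) in cache.subspaces:
            width = stop - start
            full = cache.max_lags[name]
            lo, hi = windows[name]
            sub_lags = full[(full >= lo) & (full <= hi)]
            block = w_mean[offset: offset + len(sub_lags) * width]
            weights[name] = block.reshape(len(sub_lags), width).T
            lag_map[name] = sub_lags
            offset += len(sub_lags) * width
        model = TRFModel(weights=weights, lags=lag_map, lambdas=lambdas,
                         rate=rate)
        folds.append(FoldResult(test_portion=test, prediction=pred,
                                observed=cache.responses[test][:, 0],
                                score=score, hyperparams=avg, model=model,
                                traces=traces))
    return CVResult(folds=folds, rate=rate,
                    config={"n_iter": n_iter, "seed": seed, "bounds": bounds})


def default_lambda_grid() -> np.ndarray:
    """The exhaustive grid {0.1^k | k in [-25 .. 60]} (86 values)."""
    return 0.1 ** np.arange(-25, 61, dtype=float)


def grid_search_cv(features: FeatureSpace, response: np.ndarray,
                   n_blocks: int = 20,
                   lag_window: tuple[float, float] = (-0.1, 0.4),
                   lambda_grid: np.ndarray | None = None) -> CVResult:
    """Block rotation with a single shared lambda from an exhaustive grid.

    Each block serves as the test set once; the following block (cyclically)
    is the validation block used to pick lambda; the rest train.  A warning
    is issued when an extreme grid value is selected.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must not be empty")
    if n_blocks < 3:
        raise ValueError("need at least 3 blocks")
    names = features.subspace_names()
    windows = {name: lag_window for name in names}
    cache = _PortionCache(features, response, n_blocks, windows)
    idx = np.arange(cache.template.n_columns)
    folds = []
    for test in range(n_blocks):
        val = (test + 1) % n_blocks
        train = tuple(p for p in range(n_blocks) if p not in (test, val))
        gram = sum(cache.grams[p] for p in train)
        rhs = sum(cache.crosses[p] for p in train)
        evals, evecs = linalg.eigh(gram)
        evals = np.maximum(evals, 0.0)
        proj = evecs.T @ rhs                     # (p, k) response channels
        best_lam, best_r, best_w = None, -np.inf, None
        for lam in lambda_grid:
            w = evecs @ (proj / (evals[:, None] + lam))
            r = cache.score(w, idx, val)
            if r > best_r:
                best_lam, best_r, best_w = lam, r, w
        if best_lam in (lambda_grid[0], lambda_grid[-1]):
            warnings.warn(f"extreme grid value lambda={best_lam:g} selected")
        score = cache.score(best_w, idx, test)
        pred = cache.designs[test].matrix @ best_w
        w_first = best_w[:, 0] if best_w.ndim == 2 else best_w
        weights, lag_map = {}, {}
        offset = 0
        for name, (start, stop) in cache.subspaces:
            width = stop - start
            sub_lags = cache.max_lags[name]
            block = w_first[offset: offset + len(sub_lags) * width]
            weights[name] = block.reshape(len(sub_lags), width).T
            lag_map[name] = sub_lags
            offset += len(sub_lags) * width
        model = TRFModel(weights=weights, lags=lag_map,
                         lambdas={name: float(best_lam) for name in names},
                         rate=features.rate)
        folds.append(FoldResult(
            test_portion=test, prediction=pred,
            observed=cache.responses[test], score=score,
            hyperparams={"lambda": float(best_lam), "val_score": best_r},
            model=model, traces=[]))
    return CVResult(folds=folds, rate=features.rate,
                    config={"lag_window": lag_window,
                            "n_lambda": int(lambda_grid.size)})
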
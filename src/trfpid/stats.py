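"""Hierarchical Bayesian comparison of per-fold performances.

The model has a zero intercept, one fixed effect per feature space with a
weakly informative normal prior (mean 0, variance 10), and zero-mean random
effects for participant x feature-space, participant x fold, participant x
hemisphere and hemisphere x feature-space cells sharing a single scale.
Residual and random-effect scales carry half-Student-t priors with 3 degrees
of freedom and scale 10.

Sampling uses a conjugate Gibbs scheme: the half-t scale priors are
represented as inverse-gamma scale mixtures (Huang & Wand parameter
expansion), which makes every conditional a standard draw.  This is the
reference backend; the surrounding contract (posterior draws per effect,
split-R-hat diagnostics, directed-hypothesis fractions) is backend-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PerformanceTable", "PosteriorSamples", "fit_hierarchical",
           "hypothesis_fraction", "silhouette_index"]

_REQUIRED = ("participant", "hemisphere", "fold", "feature_space", "value")


def _validate_table(perf: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in perf.columns]
    if missing:
        raise ValueError(f"performance table missing columns {missing}")
    keys = perf[["participant", "hemisphere", "fold", "feature_space"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (participant, hemisphere, fold, "
                         "feature_space) keys")
    if not np.all(np.isfinite(perf["value"].to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    return perf


#: Alias kept for symmetry with the other modules' domain types.
PerformanceTable = pd.DataFrame


@dataclass
class PosteriorSamples:
    """Post-warmup draws, shaped (chains, draws) per named effect."""

    effects: dict[str, np.ndarray]
    sigma: np.ndarray
    sigma_int: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    family: str = "gaussian"

    def pooled(self, name: str) -> np.ndarray:
        if name not in self.effects:
            raise KeyError(
                f"unknown effect {name!r}; have {sorted(self.effects)}")
        return self.effects[name].reshape(-1)

    @property
    def n_chains(self) -> int:
        return self.sigma.shape[0]


def _build_design(perf: pd.DataFrame):
    f_codes, f_levels = pd.factorize(perf["feature_space"], sort=True)
    groups = []
    for cols in (("participant", "feature_space"), ("participant", "fold"),
                 ("participant", "hemisphere"), ("hemisphere", "feature_space")):
        key = perf[list(cols)].astype(str).agg("|".join, axis=1)
        codes, levels = pd.factorize(key, sort=True)
        groups.append((codes, len(levels)))
    n = len(perf)
    m = len(f_levels)
    p = m + sum(k for _, k in groups)
    X = np.zeros((n, p))
    X[np.arange(n), f_codes] = 1.0
    offset = m
    for codes, k in groups:
        X[np.arange(n), offset + codes] = 1.0
        offset += k
    return X, list(f_levels), m, p


def fit_hierarchical(perf: pd.DataFrame, family: str = "gaussian",
                     chains: int = 4, iters: int = 4000, warmup: int = 1000,
                     seed: int = 0, prior_is_variance: bool = True,
                     prior_scale: float = 10.0) -> PosteriorSamples:
    """Sample the hierarchical comparison model by Gibbs sampling.

    ``family="lognormal"`` models the log of (strictly positive) responses,
    appropriate for skewed normalized-information ratios.  ``prior_is_
    variance`` reads the fixed-effect prior "10" as a variance (default);
    set False to read it as a squared scale of 10**2.
    """
    perf = _validate_table(perf)
    if perf["feature_space"].nunique() < 2:
        raise ValueError("need at least 2 feature spaces")
    y = perf["value"].to_numpy(dtype=float)
    if family == "lognormal":
        if np.any(y <= 0):
            raise ValueError("lognormal family requires positive values")
        y = np.log(y)
    elif family != "gaussian":
        raise ValueError(f"unknown family {family!r}")
    X, f_levels, m, p = _build_design(perf)
    n = len(y)
    xtx = X.T @ X
    xty = X.T @ y
    v_fix = prior_scale if prior_is_variance else prior_scale ** 2
    nu, A = 3.0, 10.0            # half-t(3, 0, 10) hyperpriors

    n_keep = iters - warmup
    betas = np.empty((chains, n_keep, m))
    sigmas = np.empty((chains, n_keep))
    sigma_ints = np.empty((chains, n_keep))
    for ch in range(chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0xFFFFFFFF, ch]))
        sigma2, sigma2_int = 1.0, 1.0
        a_sig = a_int = 1.0
        theta = np.zeros(p)
        for it in range(iters):
            prior_prec = np.empty(p)
            prior_prec[:m] = 1.0 / v_fix
            prior_prec[m:] = 1.0 / sigma2_int
            Q = xtx / sigma2
            Q[np.diag_indices_from(Q)] += prior_prec
            chol = np.linalg.cholesky(Q)
            mean = np.linalg.solve(
                chol.T, np.linalg.solve(chol, xty / sigma2))
            theta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            resid = y - X @ theta
            # residual scale (half-t via inverse-gamma mixture)
            a_sig = 1.0 / rng.gamma((nu + 1) / 2,
                                    1.0 / (nu / sigma2 + 1.0 / A ** 2))
            sigma2 = 1.0 / rng.gamma((nu + n) / 2,
                                     1.0 / (nu / a_sig + 0.5 * resid @ resid))
            sigma2 = max(sigma2, 1e-12)     # guard degenerate zero-residual data
            # shared random-effect scale
            u = theta[m:]
            a_int = 1.0 / rng.gamma((nu + 1) / 2,
                                    1.0 / (nu / sigma2_int + 1.0 / A ** 2))
            sigma2_int = 1.0 / rng.gamma(
                (nu + len(u)) / 2, 1.0 / (nu / a_int + 0.5 * u @ u))
            sigma2_int = max(sigma2_int, 1e-12)
            if it >= warmup:
                k = it - warmup
                betas[ch, k] = theta[:m]
                sigmas[ch, k] = np.sqrt(sigma2)
                sigma_ints[ch, k] = np.sqrt(sigma2_int)

    effects = {str(lvl): betas[:, :, j] for j, lvl in enumerate(f_levels)}
    rhat = _split_rhat(effects | {"sigma": sigmas})
    bad = {k: v for k, v in rhat.items() if v > 1.01}
    if bad:
        warnings.warn(f"convergence diagnostics above 1.01: {bad}")
    return PosteriorSamples(effects=effects, sigma=sigmas,
                            sigma_int=sigma_ints, rhat=rhat, family=family)


def _split_rhat(named: dict[str, np.ndarray]) -> dict[str, float]:
    try:
        import arviz as az
        return {name: float(az.rhat(draws[None] if draws.ndim == 1
                                    else az.convert_to_dataset(draws))
                            .to_array().values)
                for name, draws in named.items()}
    except Exception:
        # fallback: split each chain in half and compare means/variances
        out = {}
        for name, draws in named.items():
            half = draws.shape[1] // 2
            parts = np.concatenate([draws[:, :half], draws[:, half:2 * half]])
            w = parts.var(axis=1, ddof=1).mean()
            b = parts.mean(axis=1).var(ddof=1) * half
            out[name] = float(np.sqrt((w * (half - 1) / half + b / half) / w))
        return out


def hypothesis_fraction(post: PosteriorSamples, effect_a: str,
                        effect_b: str) -> float:
    """Fraction of posterior draws with effect_a - effect_b > 0."""
    diff = post.pooled(effect_a) - post.pooled(effect_b)
    return float(np.mean(diff > 0))


def silhouette_index(positions: np.ndarray, labels) -> np.ndarray:
    """Per-point silhouette values s = (b - a) / max(a, b).

    ``a`` is the mean distance to other points of the same label; ``b`` the
    minimum over other labels of the mean distance to that label's points.
    Points in singleton labels get NaN.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    diffs = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diffs ** 2).sum(axis=-1))
    s = np.full(len(positions), np.nan)
    for i in range(len(positions)):
        same = (labels == labels[i])
        same[i] = False
        if not np.any(same):
            warnings.warn(f"label {labels[i]!r} is a singleton; s undefined")
            continue
        a = dist[i, same].mean()
        b = min(dist[i, labels == other].mean()
                for other in uniq if other != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s
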
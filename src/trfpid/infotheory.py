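"""Gaussian-copula mutual information and pointwise partial information
decomposition.

Continuous variables are rank-transformed to standard-normal marginals
(empirical CDF followed by the inverse normal CDF), after which Gaussian
formulas with analytic small-sample bias correction give a robust,
monotone-transform-invariant MI estimate.  The decomposition of the joint MI
two sources carry about a target into redundancy, unique and synergistic
parts uses pointwise co-information restricted to samples where (I) both
sources carry pointwise MI about the target with the same sign and (II) the
pointwise co-information shares that sign; the expectation of those terms is
the redundancy, and the remaining lattice terms follow by subtraction, so
the decomposition identities hold exactly.  Unique terms may be negative
(pointwise misinformation carried by only one source).

All quantities are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, ndtri
from scipy.stats import rankdata

from .core import as_2d

__all__ = [
    "PIDResult", "copula_normalize", "mi_gaussian_copula", "binned_mi",
    "pid_ccs", "coinformation", "permutation_threshold", "normalize_pid",
]

_LN2 = np.log(2.0)


@dataclass
class PIDResult:
    """Decomposition of joint MI into redundancy, unique and synergy terms.

    Satisfies ``mi_x = redundancy + unique_x``, ``mi_y = redundancy +
    unique_y`` and ``mi_joint = redundancy + unique_x + unique_y + synergy``
    by construction.
    """

    redundancy: float
    unique_x: float
    unique_y: float
    synergy: float
    mi_x: float
    mi_y: float
    mi_joint: float

    def __post_init__(self) -> None:
        assert abs(self.mi_x - (self.redundancy + self.unique_x)) < 1e-9
        assert abs(self.mi_y - (self.redundancy + self.unique_y)) < 1e-9
        assert abs(self.mi_joint - (self.redundancy + self.unique_x
                                    + self.unique_y + self.synergy)) < 1e-9

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in
                ("redundancy", "unique_x", "unique_y", "synergy",
                 "mi_x", "mi_y", "mi_joint")}


def copula_normalize(x: np.ndarray) -> np.ndarray:
    """Transform each channel to standard-normal marginals, preserving ranks.

    Ranks (average method for ties) are scaled by ``1/(n+1)`` to avoid the
    infinities of the inverse normal CDF at 0 and 1.
    """
    x2 = as_2d(x)
    n = x2.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    out = np.empty_like(x2, dtype=float)
    for c in range(x2.shape[1]):
        col = x2[:, c]
        if np.all(col == col[0]):
            raise ValueError(f"channel {c} is constant; copula undefined")
        n_ties = n - len(np.unique(col))
        if n_ties > 0.1 * n:
            warnings.warn(f"channel {c}: {n_ties}/{n} tied samples")
        out[:, c] = ndtri(rankdata(col, method="average") / (n + 1))
    return out if np.asarray(x).ndim == 2 else out[:, 0]


def _entropy_bits(z: np.ndarray, bias_correct: bool = True,
                  shrink: float = 0.0) -> float:
    """Differential entropy of a Gaussian fit, analytic bias correction.

    The correction removes the expected bias of the log-determinant of the
    sample covariance (Wishart expectation), so the estimate is unbiased for
    truly Gaussian data.  ``shrink`` adds diagonal shrinkage so degenerate
    (perfectly collinear) inputs stay finite; with the default 0 such inputs
    raise instead.
    """
    z = as_2d(z)
    n, d = z.shape
    c = np.cov(z, rowvar=False, ddof=1).reshape(d, d)
    if shrink > 0:
        c = c + shrink * np.trace(c) / d * np.eye(d)
    sign, logdet = np.linalg.slogdet(c)
    if sign <= 0:
        corr = np.corrcoef(z, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"singular covariance; channels {i} and {j} are collinear "
            f"(|r| = {abs(corr[i, j]):.6f})")
    h = 0.5 * (logdet + d * np.log(2 * np.pi * np.e))
    if bias_correct:
        psiterms = digamma((n - np.arange(1, d + 1)) / 2.0) / 2.0
        dterm = 0.5 * np.log(2.0 / (n - 1))
        h -= d * dterm + psiterms.sum()
    return h / _LN2


def _mi_continuous(cx: np.ndarray, cy: np.ndarray,
                   bias_correct: bool = True, shrink: float = 0.0) -> float:
    cx, cy = as_2d(cx), as_2d(cy)
    joint = np.hstack([cx, cy])
    return (_entropy_bits(cx, bias_correct, shrink)
            + _entropy_bits(cy, bias_correct, shrink)
            - _entropy_bits(joint, bias_correct, shrink))


def _mi_discrete(cx: np.ndarray, labels: np.ndarray,
                 bias_correct: bool = True) -> float:
    """Class-conditional Gaussian MI: H(X) - sum_c p_c H(X | c)."""
    cx = as_2d(cx)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = cx.shape[1]
    if np.any(counts < d + 2):
        raise ValueError(
            f"every class needs at least dim(x)+2 = {d + 2} samples; "
            f"smallest has {counts.min()}")
    h_total = _entropy_bits(cx, bias_correct)
    h_cond = 0.0
    for cls, cnt in zip(classes, counts):
        h_cond += (cnt / len(labels)) * _entropy_bits(cx[labels == cls],
                                                      bias_correct)
    return h_total - h_cond


def mi_gaussian_copula(x: np.ndarray, y: np.ndarray,
                       bias_correct: bool = True) -> float:
    """Mutual information (bits) between continuous x and continuous or
    discrete y, via the Gaussian copula.

    Discrete y is detected by integer/object dtype; pass explicit integer
    class labels for the discrete route.
    """
    x2 = as_2d(x)
    y_arr = np.asarray(y)
    if len(x2) != len(y_arr):
        raise ValueError("x and y need equal sample counts")
    cx = copula_normalize(x2)
    if y_arr.ndim == 1 and not np.issubdtype(y_arr.dtype, np.floating):
        return _mi_discrete(cx, y_arr, bias_correct)
    cy = copula_normalize(as_2d(y_arr))
    # collinearity *within* either argument is an error (checked strictly);
    # perfect cross-dependence instead saturates at the estimator ceiling
    hx = _entropy_bits(cx, bias_correct)
    hy = _entropy_bits(cy, bias_correct)
    hxy = _entropy_bits(np.hstack([cx, cy]), bias_correct, shrink=1e-12)
    return hx + hy - hxy


def equipopulated_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into equipopulated bins; ties broken by stable rank."""
    x = np.asarray(x, dtype=float).ravel()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(np.unique(x)) < n_bins:
        raise ValueError(
            f"only {len(np.unique(x))} distinct values for {n_bins} bins")
    order = rankdata(x, method="ordinal") - 1       # stable ranks 0..n-1
    return (order * n_bins // len(x)).astype(int)


def binned_mi(x: np.ndarray, classes: np.ndarray, n_bins: int = 4,
              miller_madow: bool = False) -> float:
    """Plugin discrete MI between equipopulated bins of x and class labels."""
    classes = np.asarray(classes)
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != len(classes):
        raise ValueError("x and classes need equal length")
    uniq = np.unique(classes)
    if len(x) < n_bins * len(uniq) * 5:
        raise ValueError("too few samples for reliable binned MI")
    if n_bins == 1:
        return 0.0
    bins = equipopulated_bins(x, n_bins)
    table = np.zeros((n_bins, len(uniq)))
    for j, cls in enumerate(uniq):
        table[:, j] = np.bincount(bins[classes == cls], minlength=n_bins)
    p = table / table.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz]))) / _LN2
    if miller_madow:
        k = int(np.count_nonzero(p))
        kx = int(np.count_nonzero(px))
        ky = int(np.count_nonzero(py))
        mi -= (k - kx - ky + 1) / (2 * len(x) * _LN2)
    return mi


# ---------------------------------------------------------------------------
# Pointwise partial information decomposition
# ---------------------------------------------------------------------------

def _regularize(cov: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    cov = np.atleast_2d(cov)
    return cov + eps * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])


def _sample_gaussian(cov: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.0)
    return rng.standard_normal((n, cov.shape[0])) @ (
        evecs * np.sqrt(evals)).T


def _cond_pmi(z: np.ndarray, cov: np.ndarray, src: np.ndarray,
              tgt: np.ndarray) -> np.ndarray:
    """Pointwise MI (nats) between source block and target block.

    Computed as ``log p(t | s) - log p(t)`` from the conditional Gaussian,
    which stays finite even when the source block is (near-)singular.
    """
    s = z[:, src]
    t = z[:, tgt]
    c_ss = _regularize(cov[np.ix_(src, src)])
    c_tt = cov[np.ix_(tgt, tgt)]
    c_ts = cov[np.ix_(tgt, src)]
    gain = np.linalg.solve(c_ss, c_ts.T).T        # dt x ds
    cond_cov = _regularize(c_tt - gain @ c_ts.T, 1e-12)
    resid = t - s @ gain.T
    return (_gauss_logpdf(resid, cond_cov) - _gauss_logpdf(t, c_tt))


def _gauss_logpdf(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    chol = np.linalg.cholesky(_regularize(cov, 1e-12))
    w = np.linalg.solve(chol, x.T)
    quad = np.sum(w ** 2, axis=0)
    logdet = 2 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (quad + logdet + d * np.log(2 * np.pi))


def _redundancy_mc(delta_x: np.ndarray, delta_y: np.ndarray,
                   delta_xy: np.ndarray) -> float:
    """Expectation (bits) of pointwise co-information restricted to samples
    with sign-consistent pointwise MI terms."""
    coi = delta_x + delta_y - delta_xy
    keep = (delta_x * delta_y > 0) & (coi * delta_x > 0)
    return float(np.sum(coi[keep]) / len(coi)) / _LN2


def pid_ccs(x: np.ndarray, y: np.ndarray, t: np.ndarray,
            n_mc: int = 100_000, seed: int = 0) -> PIDResult:
    """Pointwise partial information decomposition of two sources about a
    target.

    Continuous targets: a joint Gaussian is fitted to the copula-normalized
    variables and the pointwise terms are integrated by Monte Carlo.
    Discrete targets (integer labels): class-conditional Gaussians with
    empirical class weights.  Deterministic given ``seed``.
    """
    x2, y2 = as_2d(x), as_2d(y)
    t_arr = np.asarray(t)
    if not (len(x2) == len(y2) == len(t_arr)):
        raise ValueError("x, y, t need equal sample counts")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 77]))
    cx = copula_normalize(x2)
    cy = copula_normalize(y2)
    dx, dy = cx.shape[1], cy.shape[1]
    if t_arr.ndim == 1 and not np.issubdtype(t_arr.dtype, np.floating):
        return _pid_discrete(cx, cy, t_arr, n_mc, rng)
    ct = copula_normalize(as_2d(t_arr))
    dt = ct.shape[1]
    z = np.hstack([cx, cy, ct])
    cov = np.cov(z, rowvar=False, ddof=1)
    ix = np.arange(dx)
    iy = np.arange(dx, dx + dy)
    it = np.arange(dx + dy, dx + dy + dt)
    ixy = np.concatenate([ix, iy])

    samples = _sample_gaussian(_regularize(cov), n_mc, rng)
    delta_x = _cond_pmi(samples, cov, ix, it)
    delta_y = _cond_pmi(samples, cov, iy, it)
    delta_xy = _cond_pmi(samples, cov, ixy, it)
    red = _redundancy_mc(delta_x, delta_y, delta_xy)

    # shrinkage keeps degenerate cases (e.g. identical sources) finite
    mi_x = _mi_continuous(cx, ct, shrink=1e-8)
    mi_y = _mi_continuous(cy, ct, shrink=1e-8)
    mi_joint = _mi_continuous(np.hstack([cx, cy]), ct, shrink=1e-8)
    return _assemble(red, mi_x, mi_y, mi_joint)


def _pid_discrete(cx: np.ndarray, cy: np.ndarray, labels: np.ndarray,
                  n_mc: int, rng: np.random.Generator) -> PIDResult:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 target classes")
    probs = counts / counts.sum()
    dx, dy = cx.shape[1], cy.shape[1]
    z = np.hstack([cx, cy])
    ix = np.arange(dx)
    iy = np.arange(dx, dx + dy)
    ixy = np.arange(dx + dy)
    means, covs = [], []
    for cls in classes:
        sel = z[labels == cls]
        means.append(sel.mean(axis=0))
        covs.append(_regularize(np.cov(sel, rowvar=False, ddof=1)
                                .reshape(dx + dy, dx + dy)))

    def mixture_logpdf(pts: np.ndarray, idx: np.ndarray) -> np.ndarray:
        terms = np.stack([
            np.log(p) + _gauss_logpdf(pts - m[idx], c[np.ix_(idx, idx)])
            for p, m, c in zip(probs, means, covs)])
        mx = terms.max(axis=0)
        return mx + np.log(np.exp(terms - mx).sum(axis=0))

    dxs, dys, dxys = [], [], []
    for k, cls in enumerate(classes):
        n_k = max(int(round(n_mc * probs[k])), 2)
        pts = means[k] + _sample_gaussian(covs[k], n_k, rng)
        for idx, store in ((ix, dxs), (iy, dys), (ixy, dxys)):
            cond = _gauss_logpdf(pts[:, idx] - means[k][idx],
                                 covs[k][np.ix_(idx, idx)])
            marg = mixture_logpdf(pts[:, idx], idx)
            store.append(cond - marg)
    delta_x = np.concatenate(dxs)
    delta_y = np.concatenate(dys)
    delta_xy = np.concatenate(dxys)
    # pooled samples are already class-weighted by allocation
    red = _redundancy_mc(delta_x, delta_y, delta_xy)
    mi_x = float(np.mean(delta_x)) / _LN2
    mi_y = float(np.mean(delta_y)) / _LN2
    mi_joint = float(np.mean(delta_xy)) / _LN2
    return _assemble(red, mi_x, mi_y, mi_joint)


def _assemble(red: float, mi_x: float, mi_y: float, mi_joint: float
              ) -> PIDResult:
    unique_x = mi_x - red
    unique_y = mi_y - red
    synergy = mi_joint - mi_x - mi_y + red
    return PIDResult(redundancy=red, unique_x=unique_x, unique_y=unique_y,
                     synergy=synergy, mi_x=mi_x, mi_y=mi_y, mi_joint=mi_joint)


def coinformation(x: np.ndarray, y: np.ndarray, t: np.ndarray) -> float:
    """MI(x;t) + MI(y;t) - MI([x,y];t), in bits."""
    x2, y2 = as_2d(x), as_2d(y)
    cx = copula_normalize(x2)
    cy = copula_normalize(y2)
    ct = copula_normalize(as_2d(np.asarray(t)))
    # same shrinkage as pid_ccs so CoI == redundancy - synergy exactly
    return (_mi_continuous(cx, ct, shrink=1e-8)
            + _mi_continuous(cy, ct, shrink=1e-8)
            - _mi_continuous(np.hstack([cx, cy]), ct, shrink=1e-8))


def permutation_threshold(fixed: np.ndarray, permutable: np.ndarray, stat,
                          n_perm: int = 1000, min_shift: int = 200,
                          percentile: float = 95.0, seed: int = 0) -> float:
    """Maximum-statistics noise threshold from circular-shift permutations.

    Each permutation circularly shifts ``permutable`` by a uniform draw in
    ``[min_shift, n - min_shift]``, recomputes ``stat(fixed, shifted)``
    (scalar or vector) and records its maximum; the threshold is the stated
    percentile of the ``n_perm`` maxima.
    """
    permutable = np.asarray(permutable)
    n = permutable.shape[0]
    if n <= 2 * min_shift:
        raise ValueError(
            f"series length {n} too short for min_shift={min_shift}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 13]))
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        shift = int(rng.integers(min_shift, n - min_shift + 1))
        maxima[i] = np.max(stat(fixed, np.roll(permutable, shift, axis=0)))
    return float(np.percentile(maxima, percentile))


def normalize_pid(pid: PIDResult, reference_mi: float) -> PIDResult:
    """Divide every component by a reference marginal MI.

    Ratios may exceed 1 when the reference carries negative unique
    information.
    """
    if not reference_mi > 0:
        raise ValueError("reference MI must be positive")
    return PIDResult(**{k: v / reference_mi for k, v in pid.as_dict().items()})
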
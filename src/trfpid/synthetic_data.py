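"""Synthetic inputs with known ground truth for every pipeline stage.

Generates slowly varying spectrogram-like feature time series, renewal-process
event tables with four class labels, gamma-shaped ground-truth kernels,
responses obtained by convolving features with those kernels plus Gaussian
noise (shared signal across repeats), leakage-mixed multi-grid-point
recordings, and designed source/target triplets with known redundant, unique
or synergistic structure.

All generators are bit-reproducible given their seed; substreams are derived
per operation so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import FeatureSpace, EventTable, MANNER_CLASSES, child_rng

__all__ = [
    "SyntheticGroundTruth", "simulate_features", "simulate_events",
    "make_ground_truth_trf", "simulate_response", "simulate_source_grid",
    "simulate_pid_triplet",
]


@dataclass
class SyntheticGroundTruth:
    """Parameters that fully determine a simulated dataset."""

    trf_true: np.ndarray          # channels x lags
    snr: float                    # linear signal-to-noise power ratio
    event_rate: float             # events / s
    class_probs: np.ndarray       # probability over the 4 manner classes
    leakage: np.ndarray           # grid points x latent sources
    seed: int

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if abs(self.class_probs.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must sum to 1")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        self.leakage = np.atleast_2d(np.asarray(self.leakage, dtype=float))
        if not np.all(np.isfinite(np.linalg.norm(self.leakage, axis=1))):
            raise ValueError("leakage rows must have finite norm")


def simulate_features(duration_s: float, rate: float, n_channels: int,
                      smoothness: float, seed: int) -> FeatureSpace:
    """Temporally smoothed Gaussian noise, z-scored per channel.

    ``smoothness`` is the standard deviation (seconds) of a Gaussian smoothing
    kernel; 0 gives white noise.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate))
    if n < 10:
        raise ValueError("need at least 10 samples")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = child_rng(seed, "features")
    data = rng.standard_normal((n, n_channels))
    if smoothness > 0:
        sigma = smoothness * rate
        half = int(np.ceil(4 * sigma))
        taps = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        taps /= taps.sum()
        data = sps.convolve(data, taps[:, None], mode="same")
    data -= data.mean(axis=0)
    data /= data.std(axis=0)
    return FeatureSpace(data, rate=rate, name="SynthFeatures",
                        subspaces=[("SynthFeatures", (0, n_channels))])


def simulate_events(duration_s: float, rate: float, refractory_s: float,
                    class_probs, seed: int) -> EventTable:
    """Renewal-process event table with four manner classes.

    Inter-event intervals are exponential with the rate adjusted so the
    *effective* rate (including the refractory dead time) matches ``rate``,
    truncated below at ``refractory_s``.
    """
    class_probs = np.asarray(class_probs, dtype=float)
    if abs(class_probs.sum() - 1.0) > 1e-9 or len(class_probs) != 4:
        raise ValueError("class_probs must be 4 probabilities summing to 1")
    if rate * refractory_s >= 1:
        raise ValueError(
            f"infeasible: rate*refractory = {rate * refractory_s} >= 1")
    rng = child_rng(seed, "events")
    # mean interval = refractory + 1/eff_rate must equal 1/rate
    eff_rate = rate / (1.0 - rate * refractory_s)
    n_guess = int(duration_s * rate * 1.5) + 20
    gaps = refractory_s + rng.exponential(1.0 / eff_rate, size=n_guess)
    onsets = np.cumsum(gaps)
    while onsets[-1] < duration_s:
        extra = refractory_s + rng.exponential(1.0 / eff_rate, size=n_guess)
        onsets = np.concatenate([onsets, onsets[-1] + np.cumsum(extra)])
    onsets = onsets[onsets < duration_s]
    classes = rng.choice(4, size=len(onsets), p=class_probs)
    # representative phoneme per manner class
    phoneme_for = {"vowel": "AA", "nasal": "N", "plosive": "T",
                   "fricative": "S"}
    manner = np.array([MANNER_CLASSES[c] for c in classes], dtype=object)
    phonemes = np.array([phoneme_for[m] for m in manner], dtype=object)
    from .artic import articulatory_set
    artic = [articulatory_set(p) for p in phonemes]
    return EventTable(onsets=onsets, phonemes=phonemes,
                      articulatory_sets=artic, manner_classes=manner)


def make_ground_truth_trf(lag_window: tuple[float, float], rate: float,
                          n_channels: int,
                          shape: dict | None = None,
                          seed: int = 0) -> np.ndarray:
    """Smooth gamma-shaped kernels with random per-channel gains.

    Returns a (n_channels, n_lags) weight tensor covering integer lags from
    ``round(tMin*rate)`` to ``round(tMax*rate)`` inclusive; taps before lag 0
    are zero (causal kernels inside a possibly acausal window).
    """
    t_min, t_max = lag_window
    if not t_min < t_max:
        raise ValueError("empty lag window")
    shape = dict(shape or {})
    k = shape.get("k", 3.0)
    theta = shape.get("theta", 0.04)
    lag0 = int(round(t_min * rate))
    lag1 = int(round(t_max * rate))
    lags = np.arange(lag0, lag1 + 1)
    t = lags / rate
    kernel = np.where(t > 0, np.power(np.maximum(t, 0), k - 1)
                      * np.exp(-np.maximum(t, 0) / theta), 0.0)
    if kernel.max() > 0:
        kernel = kernel / kernel.max()
    rng = child_rng(seed, "trf")
    if "gains" in shape:
        gains = np.asarray(shape["gains"], dtype=float)
        if len(gains) != n_channels:
            raise ValueError("gains must have one entry per channel")
    else:
        gains = rng.normal(1.0, 0.5, size=n_channels)
    phase_jitter = rng.uniform(0.8, 1.2, size=n_channels)
    trf = np.empty((n_channels, len(lags)))
    for c in range(n_channels):
        tc = t * phase_jitter[c]
        ker = np.where(tc > 0, np.power(np.maximum(tc, 0), k - 1)
                       * np.exp(-np.maximum(tc, 0) / theta), 0.0)
        if ker.max() > 0:
            ker = ker / ker.max()
        trf[c] = gains[c] * ker
    return trf


def convolve_trf(features: FeatureSpace, trf: np.ndarray,
                 t_min_s: float) -> np.ndarray:
    """Forward model: r(t) = sum_ch sum_tau w(ch, tau) s(ch, t - tau).

    Lag tau > 0 reads stimulus samples in the past; out-of-range samples are
    zero-padded, matching the lagged-design convention of the encoding stage.
    """
    n, c = features.data.shape
    if trf.shape[0] != c:
        raise ValueError(f"trf has {trf.shape[0]} channels, features {c}")
    lag0 = int(round(t_min_s * features.rate))
    out = np.zeros(n)
    for j, lag in enumerate(range(lag0, lag0 + trf.shape[1])):
        shifted = np.zeros((n, c))
        if lag >= 0:
            if lag < n:
                shifted[lag:] = features.data[:n - lag]
        else:
            if -lag < n:
                shifted[:n + lag] = features.data[-lag:]
        out += shifted @ trf[:, j]
    return out


def simulate_response(features: FeatureSpace, trf_true: np.ndarray,
                      snr: float, n_repeats: int, seed: int,
                      t_min_s: float = 0.0) -> np.ndarray:
    """Repeats sharing a clean convolution signal plus independent noise.

    Noise variance is scaled so var(clean)/var(noise) equals ``snr``.
    Returns an (n_times, n_repeats) array.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (use np.inf for noiseless)")
    clean = convolve_trf(features, trf_true, t_min_s)
    rng = child_rng(seed, "response")
    var_clean = clean.var()
    if np.isinf(snr):
        noise_sd = 0.0
    elif var_clean == 0:
        noise_sd = 1.0          # zero kernel: repeats are pure unit noise
    else:
        noise_sd = np.sqrt(var_clean / snr)
    reps = clean[:, None] + noise_sd * rng.standard_normal(
        (len(clean), n_repeats))
    return reps


def simulate_source_grid(latent_sources: np.ndarray, leakage: np.ndarray,
                         noise_sd: float, seed: int) -> np.ndarray:
    """Grid recordings as leakage mixtures of latent sources plus noise.

    ``latent_sources``: (n_times, n_sources); ``leakage``: (n_grid,
    n_sources).  Returns (n_times, n_grid).
    """
    latent_sources = np.atleast_2d(np.asarray(latent_sources, dtype=float))
    if latent_sources.ndim != 2:
        raise ValueError("latent_sources must be 2-D")
    leakage = np.atleast_2d(np.asarray(leakage, dtype=float))
    if leakage.shape[1] != latent_sources.shape[1]:
        raise ValueError(
            f"leakage has {leakage.shape[1]} source columns, "
            f"sources have {latent_sources.shape[1]}")
    rng = child_rng(seed, "grid")
    clean = latent_sources @ leakage.T
    return clean + noise_sd * rng.standard_normal(clean.shape)


def simulate_pid_triplet(n: int, structure: str, strength: float,
                         seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source/source/target triplets with known information structure.

    ``redundant``: y = x and t = strength*x + noise.  ``unique_x``: t depends
    on x only, y independent.  ``synergistic``: t = (x + y)/sqrt(2) plus
    noise scaled by (1 - strength); only the sum is informative.
    """
    if not 0 < strength < 1:
        raise ValueError("strength must be in (0, 1)")
    rng = child_rng(seed, "pid", structure)
    x = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    if structure == "redundant":
        y = x.copy()
        t = strength * x + np.sqrt(1 - strength ** 2) * noise
    elif structure == "unique_x":
        y = rng.standard_normal(n)
        t = strength * x + np.sqrt(1 - strength ** 2) * noise
    elif structure == "synergistic":
        y = rng.standard_normal(n)
        t = (x + y) / np.sqrt(2) + (1 - strength) * noise
    else:
        raise ValueError(f"unknown structure {structure!r}; expected "
                         "'redundant', 'unique_x' or 'synergistic'")
    return x, y, t
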
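"""Acoustic and event-based feature spaces.

Audio-side transforms: a 31-band log-mel spectrogram (``Sg``), the summed
amplitude envelope (``Env``), half-wave rectified spectrogram derivatives
(``Deriv``), a spectro-temporal 2-D Gabor modulation filterbank (``Gabor``)
and a 16-band Hilbert-envelope spectrogram (``Sg16``/``Sg16c``).  Annotation
side: binary impulse trains at phoneme onsets (``PhOn``) and per articulatory
feature (``Art``).  All spaces are resampled to a common modelling rate and
z-scored by :func:`preprocess` before entering the encoding stage.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import FeatureSpace, EventTable

__all__ = [
    "log_mel_spectrogram", "envelope", "halfwave_derivative",
    "gabor_filterbank", "hilbert_spectrogram16", "event_features",
    "preprocess", "concat_subspaces",
    "SPECTRAL_MODS", "TEMPORAL_MODS", "SG16_CENTERS",
]

# Default modulation frequency sets of the Gabor bank.  Units: the temporal
# values are Hz at the native 100 Hz frame rate; the spectral values use the
# same scale, i.e. 25 corresponds to pi/2 rad per channel.
SPECTRAL_MODS = (0.0, 2.9, 6.0, 12.2, 25.0)
TEMPORAL_MODS = (0.0, 6.2, 9.9, 15.7, 25.0)

#: Center frequencies (Hz) of the 16-band Butterworth/Hilbert spectrogram.
SG16_CENTERS = (250.0, 402.0, 577.0, 780.0, 1015.0, 1288.0, 1605.0, 1971.0,
                2396.0, 2888.0, 3459.0, 4121.0, 4888.0, 5777.0, 6807.0, 8001.0)

_MOD_MAX = 25.0       # modulation value mapped onto pi/2 rad/sample
_GABOR_NU = 3.5       # carrier periods under the Hann envelope
_GABOR_TSIZE_MAX = 39  # max temporal filter extent in frames (odd)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, fmin: float, fmax: float, sr: float,
                   n_fft: int) -> np.ndarray:
    """Triangular mel filterbank, rows = bands, columns = FFT bins."""
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax),
                                   n_bands + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    bank = np.zeros((n_bands, len(fft_freqs)))
    for b in range(n_bands):
        lo, ctr, hi = edges[b], edges[b + 1], edges[b + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        bank[b] = np.maximum(0.0, np.minimum(up, down))
    return bank


def mel_center_frequencies(n_bands: int = 31, fmin: float = 124.1,
                           fmax: float = 7284.1) -> np.ndarray:
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax),
                                   n_bands + 2))
    return edges[1:-1]


def log_mel_spectrogram(audio: np.ndarray, sr: float, n_bands: int = 31,
                        fmin: float = 124.1, fmax: float = 7284.1,
                        win_s: float = 0.025, hop_s: float = 0.010,
                        floor_ratio: float = 1e-10) -> FeatureSpace:
    """31-band log-mel spectrogram of a mono waveform.

    Frames of ``win_s`` seconds with ``hop_s`` hop (native frame rate 100 Hz
    by default), Hann window, mel filterbank energies between ``fmin`` and
    ``fmax``, log-compressed with a floor at ``floor_ratio`` of the peak
    energy so that silence maps to a finite constant.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        warnings.warn("stereo audio averaged to mono")
        audio = audio.mean(axis=1)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if sr < 2 * fmax:
        raise ValueError(f"sampling rate {sr} Hz too low for fmax={fmax} Hz")
    n_win = int(round(win_s * sr))
    n_hop = int(round(hop_s * sr))
    n_fft = int(2 ** np.ceil(np.log2(n_win)))
    _, _, spec = signal.stft(audio, fs=sr, window="hann", nperseg=n_win,
                             noverlap=n_win - n_hop, nfft=n_fft,
                             boundary="zeros", padded=True)
    power = np.abs(spec) ** 2
    bank = mel_filterbank(n_bands, fmin, fmax, sr, n_fft)
    energy = bank @ power                     # bands x frames
    peak = energy.max()
    floor = floor_ratio * peak if peak > 0 else floor_ratio
    data = np.log(np.maximum(energy, floor)).T
    return FeatureSpace(data, rate=1.0 / hop_s, name="Sg",
                        subspaces=[("Sg", (0, n_bands))])


def envelope(sg: FeatureSpace) -> FeatureSpace:
    """Amplitude envelope: channel-sum of a spectrogram-type space."""
    data = sg.data.sum(axis=1, keepdims=True)
    return FeatureSpace(data, rate=sg.rate, name="Env",
                        subspaces=[("Env", (0, 1))])


def halfwave_derivative(sg: FeatureSpace) -> FeatureSpace:
    """Positive temporal rate of change of each channel.

    First difference per channel with negatives clipped to zero; one zero row
    is prepended so the output aligns sample-for-sample with the input.
    """
    if sg.n_times < 2:
        raise ValueError("need at least 2 time samples for a derivative")
    diff = np.diff(sg.data, axis=0)
    rect = np.maximum(diff, 0.0)
    data = np.vstack([np.zeros((1, sg.n_channels)), rect])
    name = f"{sg.name}-Deriv" if sg.name not in ("", "Sg") else "Deriv"
    return FeatureSpace(data, rate=sg.rate, name=name,
                        subspaces=[(name, (0, sg.n_channels))])


# ---------------------------------------------------------------------------
# 2-D Gabor modulation filterbank
# ---------------------------------------------------------------------------

def _gabor_axis(omega: float, size_max: int) -> tuple[np.ndarray, int]:
    """Hann envelope axis for one dimension of a Gabor kernel.

    The envelope spans ``nu`` carrier periods, clipped to ``size_max`` and
    forced odd so the kernel has a center tap.  ``omega == 0`` yields the
    maximal extent (a pure low-pass in that dimension).
    """
    if omega == 0.0:
        size = size_max if size_max % 2 == 1 else size_max - 1
    else:
        half = int(np.floor(_GABOR_NU * np.pi / abs(omega)))
        size = min(2 * half + 1, size_max if size_max % 2 == 1 else size_max - 1)
    n = np.arange(size) - size // 2
    env = 0.5 + 0.5 * np.cos(2 * np.pi * n / (size + 1))
    return env, size


def gabor_kernel(omega_k: float, omega_n: float, n_channels: int
                 ) -> np.ndarray:
    """Real 2-D Gabor kernel (spectral axis first) with zero DC response."""
    env_k, _ = _gabor_axis(omega_k, 3 * n_channels)
    env_n, _ = _gabor_axis(omega_n, _GABOR_TSIZE_MAX)
    env = np.outer(env_k, env_n)
    kk = np.arange(len(env_k)) - len(env_k) // 2
    nn = np.arange(len(env_n)) - len(env_n) // 2
    carrier = np.exp(1j * (omega_k * kk[:, None] + omega_n * nn[None, :]))
    filt = env * carrier
    if omega_k != 0.0 or omega_n != 0.0:
        # remove the DC component so modulated filters ignore constant input
        filt = filt - env * (filt.sum() / env.sum())
    return np.real(filt)


def _gabor_channel_selection(omega_k: float, size_k: int, n_channels: int
                             ) -> np.ndarray:
    """Representative output channels for one filter shape.

    Spectrally unmodulated filters produce (near-)identical output in every
    channel, so only the center channel is kept.  Modulated filters are
    subsampled with a spacing of one eighth of the filter's spectral extent,
    centered on the channel axis.
    """
    if omega_k == 0.0:
        return np.array([n_channels // 2])
    step = max(1, size_k // 8)
    offset = ((n_channels - 1) % step) // 2
    return np.arange(offset, n_channels, step)


def gabor_filterbank(sg: FeatureSpace,
                     spectral_mods: tuple[float, ...] = SPECTRAL_MODS,
                     temporal_mods: tuple[float, ...] = TEMPORAL_MODS
                     ) -> FeatureSpace:
    """Filter a log-mel spectrogram with the 2-D Gabor modulation bank.

    Every combination of spectral modulation ``+-Omega`` and temporal
    modulation ``omega`` is represented once (down-sweeps duplicate up-sweeps
    when ``omega == 0`` and are skipped), and each filter's output is
    subsampled along the channel axis to avoid redundant features.  With the
    default parameters on a 31-channel spectrogram the bank has exactly 455
    output channels.
    """
    if any(m < 0 for m in spectral_mods + temporal_mods):
        raise ValueError("modulation frequencies must be non-negative")
    if 0.0 not in spectral_mods or 0.0 not in temporal_mods:
        raise ValueError("modulation sets must include 0")
    n_ch = sg.n_channels
    scale = (np.pi / 2) / _MOD_MAX
    columns = []
    for mod_k in sorted(set(spectral_mods)):
        signs = (1.0,) if mod_k == 0.0 else (1.0, -1.0)
        for sign in signs:
            omega_k = sign * mod_k * scale
            for mod_n in sorted(set(temporal_mods)):
                if sign < 0 and mod_n == 0.0:
                    continue  # down-sweep at omega=0 duplicates the up-sweep
                omega_n = mod_n * scale
                kern = gabor_kernel(omega_k, omega_n, n_ch)
                filtered = signal.convolve2d(sg.data.T, kern, mode="same",
                                             boundary="fill")
                keep = _gabor_channel_selection(omega_k, kern.shape[0], n_ch)
                columns.append(filtered[keep].T)
    data = np.hstack(columns)
    return FeatureSpace(data, rate=sg.rate, name="Gabor",
                        subspaces=[("Gabor", (0, data.shape[1]))])


def gabor_filter_count(n_channels: int = 31,
                       spectral_mods: tuple[float, ...] = SPECTRAL_MODS,
                       temporal_mods: tuple[float, ...] = TEMPORAL_MODS
                       ) -> int:
    """Number of output channels of the Gabor bank without filtering data."""
    scale = (np.pi / 2) / _MOD_MAX
    total = 0
    for mod_k in sorted(set(spectral_mods)):
        signs = (1.0,) if mod_k == 0.0 else (1.0, -1.0)
        for sign in signs:
            omega_k = sign * mod_k * scale
            _, size_k = _gabor_axis(omega_k, 3 * n_channels)
            n_keep = len(_gabor_channel_selection(omega_k, size_k, n_channels))
            for mod_n in sorted(set(temporal_mods)):
                if sign < 0 and mod_n == 0.0:
                    continue
                total += n_keep
    return total


def gabor_channel_labels(n_channels: int = 31,
                         spectral_mods: tuple[float, ...] = SPECTRAL_MODS,
                         temporal_mods: tuple[float, ...] = TEMPORAL_MODS
                         ) -> list[tuple[float, float, int]]:
    """(spectral_mod, temporal_mod, center_channel) for every output channel.

    The spectral modulation carries its sweep sign.  Iteration order matches
    :func:`gabor_filterbank` exactly.
    """
    scale = (np.pi / 2) / _MOD_MAX
    labels = []
    for mod_k in sorted(set(spectral_mods)):
        signs = (1.0,) if mod_k == 0.0 else (1.0, -1.0)
        for sign in signs:
            omega_k = sign * mod_k * scale
            _, size_k = _gabor_axis(omega_k, 3 * n_channels)
            keep = _gabor_channel_selection(omega_k, size_k, n_channels)
            for mod_n in sorted(set(temporal_mods)):
                if sign < 0 and mod_n == 0.0:
                    continue
                labels.extend((sign * mod_k, mod_n, int(c)) for c in keep)
    return labels


def gabor_temporal_groups(n_channels: int = 31,
                          spectral_mods: tuple[float, ...] = SPECTRAL_MODS,
                          temporal_mods: tuple[float, ...] = TEMPORAL_MODS
                          ) -> np.ndarray:
    """Temporal-modulation group index of every Gabor output channel.

    Used by the lag-allocation step that assigns longer lag windows to
    slower modulation groups.
    """
    t_sorted = sorted(set(temporal_mods))
    return np.array([t_sorted.index(mod_n) for _, mod_n, _ in
                     gabor_channel_labels(n_channels, spectral_mods,
                                          temporal_mods)], dtype=int)


# ---------------------------------------------------------------------------
# Hilbert-envelope spectrogram (EEG variant)
# ---------------------------------------------------------------------------

def hilbert_spectrogram16(audio: np.ndarray, sr: float,
                          compress: bool = False) -> FeatureSpace:
    """16-band Hilbert-envelope spectrogram.

    Fourth-order zero-phase (forward-reverse) Butterworth bandpass filters at
    mel-spaced center frequencies, band edges at half the distance to the
    neighboring centers; the magnitude of the analytic signal of each band is
    the channel value.  With ``compress`` the magnitudes are raised to the
    power 0.3 (name ``Sg16c``).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        warnings.warn("stereo audio averaged to mono")
        audio = audio.mean(axis=1)
    centers = np.asarray(SG16_CENTERS)
    upper_last = centers[-1] + (centers[-1] - centers[-2]) / 2
    if sr <= 2 * upper_last:
        raise ValueError(f"sampling rate {sr} Hz too low for the "
                         f"{centers[-1]} Hz band")
    gaps = np.diff(centers) / 2
    lows = centers - np.concatenate([[gaps[0]], gaps])
    highs = centers + np.concatenate([gaps, [gaps[-1]]])
    bands = np.empty((len(audio), len(centers)))
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
        filtered = signal.sosfiltfilt(sos, audio)
        bands[:, i] = np.abs(signal.hilbert(filtered))
    name = "Sg16c" if compress else "Sg16"
    if compress:
        bands = bands ** 0.3
    return FeatureSpace(bands, rate=sr, name=name,
                        subspaces=[(name, (0, len(centers)))])


# ---------------------------------------------------------------------------
# Event-based feature spaces
# ---------------------------------------------------------------------------

def onset_to_sample(onset_s, rate: float):
    """Nearest-sample index for an onset time, ties rounded earlier."""
    return np.ceil(np.asarray(onset_s) * rate - 0.5).astype(int)


def event_features(events: EventTable, mode: str, rate: float,
                   n_samples: int,
                   feature_names: list[str] | None = None) -> FeatureSpace:
    """Binary impulse feature spaces from a phoneme event table.

    ``mode="PhOn"``: one channel with a unit impulse at the sample nearest
    each onset.  ``mode="Art"``: 23 channels, one per articulatory feature,
    with impulses in every channel named in the event's articulatory set.
    """
    if mode not in ("PhOn", "Art"):
        raise ValueError(f"mode must be 'PhOn' or 'Art', got {mode!r}")
    idx = onset_to_sample(events.onsets, rate) if len(events) else np.array([], int)
    bad = np.flatnonzero((idx < 0) | (idx >= n_samples))
    if bad.size:
        raise ValueError(
            f"onsets beyond duration at rows {bad.tolist()}: "
            f"{events.onsets[bad].tolist()}")
    if mode == "PhOn":
        data = np.zeros((n_samples, 1))
        data[idx, 0] = 1.0
        return FeatureSpace(data, rate=rate, name="PhOn",
                            subspaces=[("PhOn", (0, 1))])
    if feature_names is None:
        from .artic import ARTICULATORY_FEATURES
        feature_names = list(ARTICULATORY_FEATURES)
    col = {name: j for j, name in enumerate(feature_names)}
    data = np.zeros((n_samples, len(feature_names)))
    for i, t in enumerate(idx):
        for feat in events.articulatory_sets[i]:
            if feat in col:
                data[t, col[feat]] = 1.0
    return FeatureSpace(data, rate=rate, name="Art",
                        subspaces=[("Art", (0, len(feature_names)))])


# ---------------------------------------------------------------------------
# Preprocessing and assembly
# ---------------------------------------------------------------------------

def zscore_columns(data: np.ndarray) -> np.ndarray:
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    out = data - mean
    constant = sd == 0
    if np.any(constant):
        warnings.warn(f"{int(constant.sum())} constant channel(s) left at 0")
        sd = np.where(constant, 1.0, sd)
    return out / sd


def preprocess(fs: FeatureSpace, target_rate: float = 40.0) -> FeatureSpace:
    """Anti-aliased resampling to the modelling rate plus per-channel z-scoring."""
    if fs.rate < target_rate:
        raise ValueError(f"cannot upsample from {fs.rate} to {target_rate} Hz")
    if fs.rate == target_rate:
        data = fs.data
    else:
        frac = Fraction(target_rate / fs.rate).limit_denominator(10000)
        data = signal.resample_poly(fs.data, frac.numerator, frac.denominator,
                                    axis=0)
        n_out = int(round(fs.n_times * target_rate / fs.rate))
        data = data[:n_out]
    return FeatureSpace(zscore_columns(data), rate=target_rate, name=fs.name,
                        subspaces=[(n, r) for n, r in fs.subspaces])


def concat_subspaces(spaces: list[FeatureSpace]) -> FeatureSpace:
    """Column-wise concatenation with subspace bookkeeping."""
    if not spaces:
        raise ValueError("need at least one feature space")
    rate = spaces[0].rate
    n = spaces[0].n_times
    for fs in spaces[1:]:
        if fs.rate != rate:
            raise ValueError(f"rate mismatch: {fs.rate} vs {rate}")
        if fs.n_times != n:
            raise ValueError(f"length mismatch: {fs.n_times} vs {n}")
    subspaces = []
    pos = 0
    for fs in spaces:
        for sub_name, (start, stop) in fs.subspaces:
            width = stop - start
            subspaces.append((sub_name, (pos, pos + width)))
            pos += width
    data = np.hstack([fs.data for fs in spaces])
    name = " & ".join(fs.name for fs in spaces)
    return FeatureSpace(data, rate=rate, name=name, subspaces=subspaces)
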
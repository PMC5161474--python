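"""Time-frequency feature extraction: multitaper PSD, STFT and Morlet
wavelet features, and baseline-z-scored time-frequency maps.

All extractors operate on an :class:`~mimeg.preprocessing.EpochSet` whose
"channels" may equally be spatially filtered components, and return a
:class:`FeatureMatrix` (trials x named features) ready for classification.

Numerical choices: the multitaper estimate uses a 2-Hz spectral bandwidth
(time-bandwidth ~3 over a 3-s imagery window, i.e. ~1-Hz bins remain
resolvable); the STFT uses 0.5-s Hann windows with 50 % overlap whose
squared magnitudes are pooled into the 1-s analysis windows; Morlet
wavelets use 7 cycles per frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocessing import BandSpec, EpochSet, ParameterError, WindowError

__all__ = ["FeatureMatrix", "TFRZMap",
           "multitaper_psd_features", "stft_features", "morlet_features",
           "tfr_zscore_map", "multitaper_band_psd"]

#: default spectral bandwidth (Hz) of the multitaper estimate
MT_BANDWIDTH = 2.0
#: Morlet wavelet width, cycles per frequency
MORLET_CYCLES = 7.0


@dataclass
class FeatureMatrix:
    """Trials x features with one descriptor record per feature.

    Descriptors are ``(signal, detail)`` tuples: the channel/component name
    plus the frequency bin or (band, window) that produced the feature.
    """

    X: np.ndarray
    feature_desc: list[tuple]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials, features)")
        if len(self.feature_desc) != self.X.shape[1]:
            raise ValueError("descriptor count does not match feature count")
        if len(set(self.feature_desc)) != len(self.feature_desc):
            raise ValueError("feature descriptors must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain non-finite values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.X[:, idx],
                             [self.feature_desc[i] for i in idx],
                             self.labels)

    def to_frame(self):
        import pandas as pd
        cols = ["|".join(str(p) for p in d) for d in self.feature_desc]
        return pd.DataFrame(self.X, columns=cols)

    @staticmethod
    def hstack(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        X = np.hstack([p.X for p in parts])
        desc = [d for p in parts for d in p.feature_desc]
        return FeatureMatrix(X, desc, parts[0].labels)


# ---------------------------------------------------------------------------
# multitaper PSD
# ---------------------------------------------------------------------------

def multitaper_band_psd(data: np.ndarray, sfreq: float,
                        fmin: float, fmax: float,
                        bandwidth: float = MT_BANDWIDTH):
    """Multitaper PSD pooled into 1-Hz bins centred on integer frequencies.

    Returns ``(power, centers)`` where ``power`` has shape
    ``data.shape[:-1] + (n_bins,)`` and holds *integrated* bin power
    (PSD density x 1 Hz), so that summing bins over a band approximates the
    band-limited signal variance (Parseval).
    """
    from mne.time_frequency import psd_array_multitaper

    n_times = data.shape[-1]
    if n_times / sfreq < 1.0:
        raise ParameterError(
            "window too short for 1-Hz resolution (need >= 1 s)")
    psd, freqs = psd_array_multitaper(
        data, sfreq, fmin=max(fmin - 0.5, 0.1), fmax=fmax + 0.5,
        bandwidth=bandwidth, adaptive=False, normalization="full",
        verbose="error")
    centers = np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    power = np.empty(data.shape[:-1] + (len(centers),))
    for i, c in enumerate(centers):
        m = (freqs >= c - 0.5) & (freqs < c + 0.5)
        power[..., i] = psd[..., m].sum(axis=-1) * df
    return power, centers


def multitaper_psd_features(epochs: EpochSet, fmin: float = 8.0,
                            fmax: float = 30.0) -> FeatureMatrix:
    """One linear-power feature per channel per 1-Hz bin over the epoch.

    The epochs are expected to be cropped to the analysis window (e.g. the
    3-s imagery interval); power is linear, not log, so the features can
    feed chi-square relevance scoring directly.
    """
    power, centers = multitaper_band_psd(epochs.data, epochs.sfreq, fmin, fmax)
    n_trials, n_ch, n_bins = power.shape
    desc = [(name, f"{c:d}Hz") for name in epochs.channel_names
            for c in centers]
    return FeatureMatrix(power.reshape(n_trials, n_ch * n_bins), desc,
                         epochs.labels)


# ---------------------------------------------------------------------------
# windowed features (STFT / Morlet)
# ---------------------------------------------------------------------------

def _default_windows(epochs: EpochSet, n_max: int = 4):
    """1-s analysis windows from the cue onward, as many as fit (up to 4)."""
    start = max(0.0, epochs.t0)
    n = min(n_max, int(np.floor(epochs.t_stop - start + 1e-9)))
    if n < 1:
        raise WindowError("epoch span too short for any 1-s analysis window")
    return tuple((start + i, start + i + 1.0) for i in range(n))


def stft_features(epochs: EpochSet, band: BandSpec = BandSpec(8.0, 30.0),
                  windows: tuple | None = None) -> FeatureMatrix:
    """Short-time-Fourier band power averaged into 1-s windows.

    Callers band-pass filter beforehand (the estimate restricts to the band
    in any case); one feature per channel per window.
    """
    band.validate_for(epochs.sfreq)
    if windows is None:
        windows = _default_windows(epochs)
    nper = int(round(0.5 * epochs.sfreq))
    freqs, seg_t, sxx = sps.spectrogram(
        epochs.data, fs=epochs.sfreq, window="hann", nperseg=nper,
        noverlap=nper // 2, detrend=False, mode="psd")
    seg_t = seg_t + epochs.t0
    fmask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    half = nper / (2 * epochs.sfreq)
    eps_t = 0.5 / epochs.sfreq
    cols = []
    for w0, w1 in windows:
        # only segments lying fully inside the window contribute, so a
        # power step at a window edge does not smear across windows
        tmask = (seg_t - half >= w0 - eps_t) & (seg_t + half <= w1 + eps_t)
        if not tmask.any():
            raise WindowError(f"no STFT segments inside window [{w0}, {w1})")
        cols.append(sxx[:, :, fmask][:, :, :, tmask].mean(axis=(2, 3)))
    X = np.stack(cols, axis=-1)  # (trials, channels, windows)
    desc = [(name, band.name, f"{w0:g}-{w1:g}s")
            for name in epochs.channel_names for (w0, w1) in windows]
    return FeatureMatrix(X.reshape(epochs.n_trials, -1), desc, epochs.labels)


def _morlet_window_power(epochs: EpochSet, freqs: np.ndarray,
                         windows: tuple, n_cycles: float = MORLET_CYCLES,
                         decim: int = 2, batch: int = 10) -> np.ndarray:
    """Morlet power pooled over time windows.

    Returns ``(n_trials, n_channels, n_freqs, n_windows)``.  Trials are
    processed in batches to bound the memory of the dense TFR.
    """
    from mne.time_frequency import tfr_array_morlet

    times = epochs.times[::decim]
    masks = []
    for w0, w1 in windows:
        m = (times >= w0) & (times < w1)
        if not m.any():
            raise WindowError(f"window [{w0}, {w1}) outside epoch span")
        masks.append(m)
    out = np.empty((epochs.n_trials, epochs.n_channels, len(freqs),
                    len(windows)))
    for s in range(0, epochs.n_trials, batch):
        sl = slice(s, min(s + batch, epochs.n_trials))
        power = tfr_array_morlet(epochs.data[sl], epochs.sfreq, freqs,
                                 n_cycles=n_cycles, output="power",
                                 decim=decim, verbose="error")
        for wi, m in enumerate(masks):
            out[sl, :, :, wi] = power[..., m].mean(axis=-1)
    return out


def morlet_features(epochs: EpochSet, fmin: float = 8.0, fmax: float = 30.0,
                    windows: tuple | None = None) -> FeatureMatrix:
    """Morlet wavelet power per 1-Hz bin, averaged over frequencies and
    1-s windows — the continuous-wavelet analogue of :func:`stft_features`."""
    if windows is None:
        windows = _default_windows(epochs)
    freqs = np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1, dtype=float)
    power = _morlet_window_power(epochs, freqs, windows)
    band_avg = power.mean(axis=2)  # (trials, channels, windows)
    desc = [(name, f"{fmin:g}-{fmax:g}Hz", f"{w0:g}-{w1:g}s")
            for name in epochs.channel_names for (w0, w1) in windows]
    return FeatureMatrix(band_avg.reshape(epochs.n_trials, -1), desc,
                         epochs.labels)


# ---------------------------------------------------------------------------
# z-scored TFR maps
# ---------------------------------------------------------------------------

@dataclass
class TFRZMap:
    """Trial-averaged Morlet power z-scored against the pre-cue baseline.

    ``z[c, f, w] = (power[c, f, w] - mu[f]) / sigma[f]`` with ``mu`` and
    ``sigma`` estimated per 1-Hz band from the baseline's 0.5-s windows
    (pooled over channels and baseline windows).
    """

    z: np.ndarray                  # (channels, freqs, windows)
    power: np.ndarray              # raw trial-averaged power, same shape
    freqs: np.ndarray
    windows: list[tuple[float, float]]
    baseline_window: tuple[float, float]
    mu: np.ndarray                 # per-band baseline mean
    sigma: np.ndarray              # per-band baseline std
    channel_names: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        rows = []
        for ci, ch in enumerate(self.channel_names):
            for fi, f in enumerate(self.freqs):
                for wi, (w0, w1) in enumerate(self.windows):
                    rows.append((ch, f, w0, w1, self.z[ci, fi, wi]))
        return pd.DataFrame(rows, columns=["channel", "freq", "t_start",
                                           "t_stop", "z"])


def tfr_zscore_map(epochs: EpochSet, fmin: float = 5.0, fmax: float = 45.0,
                   baseline: tuple[float, float] = (-2.0, 0.0),
                   t_stop: float = 4.0) -> TFRZMap:
    """Baseline-z-scored time-frequency map in 1-Hz bands and 0.5-s windows.

    Raises a degenerate-baseline error if any band's baseline power has
    zero variance across the baseline cells.
    """
    if epochs.t0 > baseline[0] or epochs.t_stop < t_stop:
        raise WindowError("epoch span must cover the baseline and the "
                          f"analysis range up to {t_stop} s")
    freqs = np.arange(int(np.ceil(fmin)), int(np.floor(fmax)) + 1, dtype=float)
    if freqs[-1] >= epochs.sfreq / 2:
        raise ParameterError("fmax at or above Nyquist")
    edges = np.arange(baseline[0], t_stop - 0.25 + 1e-9, 0.5)
    windows = [(e, e + 0.5) for e in edges]
    power = _morlet_window_power(epochs, freqs, tuple(windows))
    power = power.mean(axis=0)  # average over trials -> (ch, freq, win)

    base_mask = np.array([w1 <= baseline[1] + 1e-9 for _, w1 in windows])
    base = power[:, :, base_mask]            # (ch, freq, base windows)
    mu = base.mean(axis=(0, 2))
    sigma = base.std(axis=(0, 2))
    if np.any(sigma == 0):
        raise ValueError("degenerate baseline: zero variance in some band")
    z = (power - mu[None, :, None]) / sigma[None, :, None]
    return TFRZMap(z=z, power=power, freqs=freqs, windows=windows,
                   baseline_window=baseline, mu=mu, sigma=sigma,
                   channel_names=list(epochs.channel_names))
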
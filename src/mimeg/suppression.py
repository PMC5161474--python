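"""Mu-rhythm suppression quantification and its relation to decoding
accuracy.

The suppression percentage compares multitaper band power during motor
imagery (1.0-3.0 s after the cue) with the pre-cue baseline
(-4.0 to -2.0 s):

    suppression = (power_MI - power_rest) / power_rest * 100 %

computed for the 10-Hz rhythm (8-12 Hz) and the 20-Hz rhythm (16-24 Hz),
over sensor channels or spatially filtered components.  Negative values are
event-related desynchronization (ERD).  Pearson correlations relate
per-session suppression to per-session classification accuracy, globally
and channel by channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .preprocessing import EpochSet, WindowError, crop_window
from .spatial import SpatialFilterModel, apply_filters
from .spectral import multitaper_band_psd

__all__ = ["BANDS", "SuppressionResult", "CorrelationResult", "band_power",
           "suppression_percent", "correlate_suppression_accuracy",
           "suppression_accuracy_map"]

#: named rhythm bands: the 10-Hz rhythm spans 8-12 Hz, the 20-Hz 16-24 Hz
BANDS = {"MU10": (8.0, 12.0), "BETA20": (16.0, 24.0)}

BASELINE_WINDOW = (-4.0, -2.0)
MI_WINDOW = (1.0, 3.0)


@dataclass
class SuppressionResult:
    """Baseline and imagery band powers and the suppression percentage."""

    power_rest: float
    power_mi: float
    suppression_pct: float
    band: str
    scope: str
    per_channel_pct: np.ndarray | None = None
    channel_names: list | None = None

    def __post_init__(self) -> None:
        if self.power_rest <= 0:
            raise ValueError("baseline power must be positive")
        expected = (self.power_mi - self.power_rest) / self.power_rest * 100
        if abs(self.suppression_pct - expected) > 1e-9:
            raise ValueError("suppression_pct inconsistent with powers")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_desc: str = ""
    y_desc: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _resolve_band(band) -> tuple[str, tuple[float, float]]:
    if isinstance(band, str):
        return band, BANDS[band]
    return f"{band[0]:g}-{band[1]:g}Hz", tuple(band)


def band_power(epochs: EpochSet, band, window) -> np.ndarray:
    """Per-channel band power (multitaper, integrated over the band's
    1-Hz bins) averaged over epochs within the window."""
    _, (f_lo, f_hi) = _resolve_band(band)
    cropped = crop_window(epochs, *window)
    power, _ = multitaper_band_psd(cropped.data, epochs.sfreq, f_lo, f_hi)
    # sum over bins (integrated band power), mean over epochs
    return power.sum(axis=-1).mean(axis=0)


def suppression_percent(epochs: EpochSet, band="MU10", scope: str = "pooled",
                        model: SpatialFilterModel | None = None,
                        baseline_window=BASELINE_WINDOW,
                        mi_window=MI_WINDOW) -> SuppressionResult:
    """Suppression percentage of one rhythm band.

    ``scope='pooled'`` averages power over epochs and channels before the
    ratio (the averaging order: per-(epoch, channel, bin) power, then bins,
    then epochs, then channels); ``scope='channel'`` keeps the per-channel
    ratios alongside; ``scope='component'`` first projects through a fitted
    spatial-filter ``model``.
    """
    band_name, _ = _resolve_band(band)
    if scope == "component":
        if model is None:
            raise ValueError("scope='component' requires a fitted model")
        epochs = apply_filters(model, epochs)
    elif scope not in ("pooled", "channel"):
        raise ValueError(f"unknown scope {scope!r}")

    p_rest = band_power(epochs, band, baseline_window)
    p_mi = band_power(epochs, band, mi_window)
    if np.any(p_rest <= 0):
        raise ValueError("baseline power must be positive in every channel")
    rest, mi = float(p_rest.mean()), float(p_mi.mean())
    per_channel = (p_mi - p_rest) / p_rest * 100.0
    return SuppressionResult(
        power_rest=rest, power_mi=mi,
        suppression_pct=(mi - rest) / rest * 100.0,
        band=band_name, scope=scope,
        per_channel_pct=per_channel,
        channel_names=list(epochs.channel_names))


def correlate_suppression_accuracy(suppressions, accuracies,
                                   x_desc: str = "suppression",
                                   y_desc: str = "accuracy"
                                   ) -> CorrelationResult:
    """Pearson correlation (two-sided t-distribution p) between matched
    per-session suppression and accuracy values."""
    x = np.asarray(suppressions, float)
    y = np.asarray(accuracies, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matched 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 sessions")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x),
                             x_desc=x_desc, y_desc=y_desc)


def suppression_accuracy_map(per_channel_suppressions: np.ndarray,
                             accuracies, channel_names=None,
                             channel_positions=None):
    """Channel-wise correlation between suppression and accuracy.

    ``per_channel_suppressions`` is ``(n_sessions, n_channels)``; returns a
    DataFrame with one row per channel (r, p, and layout coordinates when
    given) — the numeric export behind a correlation topography.
    """
    import pandas as pd

    S = np.asarray(per_channel_suppressions, float)
    acc = np.asarray(accuracies, float)
    if S.ndim != 2 or S.shape[0] != len(acc):
        raise ValueError("suppressions must be (n_sessions, n_channels) "
                         "matched to accuracies")
    rows = []
    for c in range(S.shape[1]):
        res = correlate_suppression_accuracy(S[:, c], acc)
        name = channel_names[c] if channel_names is not None else f"CH{c:02d}"
        row = {"channel": name, "r": res.r, "p": res.p, "n": res.n}
        if channel_positions is not None:
            row["x"], row["y"] = channel_positions[c]
        rows.append(row)
    return pd.DataFrame(rows)
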
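"""Epoch container and shared signal conditioning.

The :class:`EpochSet` is the currency passed between every stage of the
analysis: a ``trials x channels x samples`` array with its sampling rate,
the time of the first sample relative to the imagery cue (cue onset = 0 s),
per-trial class labels and channel metadata.  All downstream feature
extractors, spatial filters and evaluators consume and return this
container.

Conventions
-----------
* sample ``i`` of every trial sits at ``t0 + i / sfreq`` seconds;
* time windows are half-open ``[start, stop)`` — the sample at the cue
  onset belongs to the imagery side;
* band-pass filtering is zero phase (symmetric Hamming-window FIR applied
  with centred convolution) and is meant to be applied to whole epochs
  before any cropping, so that edge transients fall outside the analysis
  windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "LEFT", "RIGHT", "REST", "MI",
    "BandSpec", "EpochSet",
    "fir_bandpass", "select_channels", "crop_window", "rest_epochs",
    "concatenate",
    "ParameterError", "ChannelLookupError", "WindowError",
]

LEFT = "LEFT"
RIGHT = "RIGHT"
REST = "REST"
#: pooled motor-imagery label used by the imagery-vs-rest task
MI = "MI"


class ParameterError(ValueError):
    """A parameter is outside its valid range (e.g. band above Nyquist)."""


class ChannelLookupError(KeyError):
    """Requested channel names are not present in the epoch set."""


class WindowError(ValueError):
    """A requested time window falls outside the epoch span."""


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification: pass band ``[f_lo, f_hi]`` Hz with the
    given transition width (Hz) on both edges."""

    f_lo: float
    f_hi: float
    transition: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ParameterError(
                f"band requires 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.transition <= 0:
            raise ParameterError(f"transition must be > 0, got {self.transition}")

    def validate_for(self, sfreq: float) -> None:
        if self.f_hi >= sfreq / 2:
            raise ParameterError(
                f"band edge {self.f_hi} Hz is at or above Nyquist ({sfreq / 2} Hz)")

    @property
    def name(self) -> str:
        return f"{self.f_lo:g}-{self.f_hi:g}Hz"


@dataclass
class EpochSet:
    """Epoched multichannel sensor (or component) time series.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` real array.
    sfreq
        Sampling rate in Hz.
    t0
        Time of the first sample relative to cue onset, in seconds.
    labels
        Per-trial class label, one of ``LEFT``, ``RIGHT``, ``REST``, ``MI``.
    session_id
        Free-text session identifier, carried through all operations.
    channel_names
        One name per channel.
    channel_positions
        Optional ``(n_channels, 2)`` flattened sensor-layout coordinates;
        component-space epoch sets have none.
    """

    data: np.ndarray
    sfreq: float
    t0: float
    labels: np.ndarray
    session_id: str = ""
    channel_names: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), "
                             f"got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 0:
            raise ParameterError(f"sfreq must be positive, got {self.sfreq}")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.n_trials,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.n_trials} trials")
        if not self.channel_names:
            self.channel_names = [f"CH{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, float)
            if self.channel_positions.shape[0] != self.n_channels:
                raise ValueError("channel_positions length does not match "
                                 "channel count")

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    @property
    def t_stop(self) -> float:
        """End of the half-open epoch span ``[t0, t_stop)``."""
        return self.t0 + self.n_samples / self.sfreq

    def copy(self, **overrides) -> "EpochSet":
        fields = {f.name: getattr(self, f.name)
                  for f in dataclasses.fields(self)}
        fields["data"] = fields["data"].copy()
        fields["labels"] = fields["labels"].copy()
        fields.update(overrides)
        return EpochSet(**fields)

    def subset(self, trial_idx) -> "EpochSet":
        """Epoch subset by trial index (copy)."""
        idx = np.asarray(trial_idx)
        return self.copy(data=self.data[idx], labels=self.labels[idx])

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Write to a single-file ``.npz`` archive (bit-exact round trip)."""
        np.savez_compressed(
            path,
            data=self.data,
            sfreq=self.sfreq,
            t0=self.t0,
            labels=np.asarray([str(l) for l in self.labels]),
            session_id=np.asarray(self.session_id),
            channel_names=np.asarray(self.channel_names),
            channel_positions=(self.channel_positions
                               if self.channel_positions is not None
                               else np.zeros((0, 2))),
        )

    @classmethod
    def load(cls, path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as f:
            pos = f["channel_positions"]
            return cls(
                data=f["data"],
                sfreq=float(f["sfreq"]),
                t0=float(f["t0"]),
                labels=f["labels"].astype(object),
                session_id=str(f["session_id"]),
                channel_names=list(f["channel_names"]),
                channel_positions=None if pos.size == 0 else pos,
            )

    @classmethod
    def from_mne_epochs(cls, epochs, session_id: str = "") -> "EpochSet":
        """Adapter from an ``mne.Epochs``-like object (e.g. read from FIF).

        Labels are taken from the event-id names; channel positions from the
        first two sensor-location coordinates.
        """
        inv = {v: k for k, v in epochs.event_id.items()}
        labels = np.asarray([inv[e] for e in epochs.events[:, 2]], dtype=object)
        pos = np.asarray([ch["loc"][:2] for ch in epochs.info["chs"]])
        return cls(data=epochs.get_data(copy=True),
                   sfreq=float(epochs.info["sfreq"]),
                   t0=float(epochs.times[0]),
                   labels=labels,
                   session_id=session_id,
                   channel_names=list(epochs.ch_names),
                   channel_positions=pos)

    def _sample_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.sfreq))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def design_bandpass_fir(band: BandSpec, sfreq: float,
                        max_taps: int | None = None) -> np.ndarray:
    """Symmetric (linear-phase) Hamming-window band-pass FIR.

    The number of taps follows the Hamming-window design rule for the
    requested transition width (~3.3 / transition seconds of impulse
    response), capped at ``max_taps`` — callers cap at the epoch length,
    mirroring a filter as long as the epoch.
    """
    band.validate_for(sfreq)
    numtaps = int(np.ceil(3.3 * sfreq / band.transition))
    if max_taps is not None:
        numtaps = min(numtaps, int(max_taps))
    numtaps = max(numtaps, 33)
    if numtaps % 2 == 0:
        numtaps -= 1
    return signal.firwin(numtaps, [band.f_lo, band.f_hi],
                         pass_zero=False, window="hamming", fs=sfreq)


def fir_bandpass(epochs: EpochSet, band: BandSpec) -> EpochSet:
    """Zero-phase FIR band pass applied per trial and channel.

    The symmetric FIR kernel is applied with centred convolution, which for
    a linear-phase filter is equivalent to delay-compensated filtering: no
    net phase shift.  Output shape equals input shape.
    """
    taps = design_bandpass_fir(band, epochs.sfreq, max_taps=epochs.n_samples)
    out = signal.fftconvolve(epochs.data, taps[None, None, :], mode="same")
    return epochs.copy(data=out)


def select_channels(epochs: EpochSet, roi: list[str]) -> EpochSet:
    """Channel-subset copy in ``roi`` order; metadata kept consistent."""
    name_to_idx = {n: i for i, n in enumerate(epochs.channel_names)}
    missing = [n for n in roi if n not in name_to_idx]
    if missing:
        raise ChannelLookupError(f"unknown channel names: {missing}")
    idx = [name_to_idx[n] for n in roi]
    pos = (epochs.channel_positions[idx]
           if epochs.channel_positions is not None else None)
    return epochs.copy(data=epochs.data[:, idx, :],
                       channel_names=list(roi),
                       channel_positions=pos)


def crop_window(epochs: EpochSet, t_start: float, t_stop: float) -> EpochSet:
    """Crop each trial to the half-open window ``[t_start, t_stop)``."""
    eps = 0.5 / epochs.sfreq
    if t_start < epochs.t0 - eps or t_stop > epochs.t_stop + eps:
        raise WindowError(
            f"window [{t_start}, {t_stop}) outside epoch span "
            f"[{epochs.t0}, {epochs.t_stop})")
    i0 = epochs._sample_index(t_start)
    i1 = epochs._sample_index(t_stop)
    i0 = max(i0, 0)
    i1 = min(i1, epochs.n_samples)
    if i1 <= i0:
        raise WindowError(f"empty window [{t_start}, {t_stop})")
    return epochs.copy(data=epochs.data[:, :, i0:i1],
                       t0=epochs.t0 + i0 / epochs.sfreq)


def rest_epochs(epochs: EpochSet,
                window: tuple[float, float] = (-4.0, -1.0)) -> EpochSet:
    """Rest-class epochs cut from the pre-cue interval of the same trials.

    The cropped segment is re-referenced so its own time axis starts at
    0 s and every trial is relabelled ``REST``.
    """
    out = crop_window(epochs, *window)
    return out.copy(t0=0.0,
                    labels=np.asarray([REST] * out.n_trials, dtype=object))


def concatenate(epoch_sets: list[EpochSet]) -> EpochSet:
    """Stack trials of epoch sets sharing channels, sfreq and time axis."""
    first = epoch_sets[0]
    for e in epoch_sets[1:]:
        if e.n_channels != first.n_channels or e.sfreq != first.sfreq:
            raise ValueError("incompatible epoch sets")
        if abs(e.t0 - first.t0) > 0.5 / first.sfreq \
                or e.n_samples != first.n_samples:
            raise ValueError("incompatible time axes")
    return first.copy(
        data=np.concatenate([e.data for e in epoch_sets], axis=0),
        labels=np.concatenate([e.labels for e in epoch_sets]))
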
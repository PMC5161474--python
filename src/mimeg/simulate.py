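"""Synthetic motor-imagery MEG sessions with known planted structure.

Generates epoched 48-channel planar-gradiometer-like data emulating a cued
left/right-hand motor-imagery experiment: each 11-s trial spans a 5-s rest
period, 2 s of preparation and a 3-s imagery interval (cue onset at 0 s),
followed by feedback.  Two oscillatory rhythms (mu ~10 Hz and beta ~20 Hz)
are generated per hemisphere as amplitude-modulated narrowband sources,
mixed into the sensors through smooth lateralised spatial patterns, and
suppressed during imagery — more deeply on the hemisphere contralateral to
the imagined hand — with a rebound after imagery ends.  Background is 1/f
("pink") plus white sensor noise.

The ground truth (which suppression percentage each rhythm/hemisphere/class
should show) is available analytically via :func:`planted_truth`, so every
downstream estimator can be validated as a recovery problem.

The event-related desynchronisation (ERD) starts 0.5 s after the cue —
the behavioural reaction delay — and lasts until imagery offset at 3.0 s;
the rebound (ERS) follows.  ``erd_*`` depths are *relative power changes*:
``-0.4`` plants a 40 % power suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocessing import LEFT, RIGHT, EpochSet

__all__ = ["SimConfig", "SimConfigError", "generate_session",
           "planted_truth", "sensor_grid", "HEMISPHERES"]

HEMISPHERES = ("left", "right")


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def sensor_grid(n_channels: int = 48) -> tuple[list[str], np.ndarray]:
    """Rectangular sensor patch over the parietal scalp.

    Channels are laid out on a grid spanning x in [-1, 1] (left to right)
    and y in [-0.5, 0.5] (posterior to anterior), 8 columns wide by
    default.  Returns names and ``(n_channels, 2)`` coordinates; names are
    ``MEG<idx><L|R>`` with the hemisphere suffix from the x sign.
    """
    n_cols = 8
    n_rows = int(np.ceil(n_channels / n_cols))
    xs = np.linspace(-1.0, 1.0, n_cols)
    ys = np.linspace(-0.5, 0.5, n_rows)
    pos = np.array([(x, y) for y in ys for x in xs])[:n_channels]
    names = [f"MEG{i:02d}{'L' if p[0] < 0 else 'R'}"
             for i, p in enumerate(pos)]
    return names, pos


def _gaussian_pattern(pos: np.ndarray, center: tuple[float, float],
                      width: float = 0.35) -> np.ndarray:
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2 * width ** 2))


@dataclass
class SimConfig:
    """Study conditions for one simulated session.

    Depth mappings give the relative power change in [-1, 0] during
    imagery for each rhythm, separately for the hemisphere contralateral
    and ipsilateral to the imagined hand.
    """

    n_channels: int = 48
    sfreq: float = 250.0
    tmin: float = -5.0
    tmax: float = 6.0
    #: 40 + 40 trials per session (training + feedback blocks pooled)
    n_trials_per_class: int = 40
    rhythm_freqs: tuple[float, ...] = (10.0, 20.0)
    erd_contra: dict[float, float] = field(
        default_factory=lambda: {10.0: -0.5, 20.0: -0.5})
    erd_ipsi: dict[float, float] = field(
        default_factory=lambda: {10.0: -0.1, 20.0: -0.1})
    erd_onset: float = 0.5
    erd_offset: float = 3.0
    ers_gain: float = 0.3
    ers_duration: float = 1.5
    #: source RMS amplitude per rhythm (sensor units at the pattern peak)
    source_amp: dict[float, float] = field(
        default_factory=lambda: {10.0: 1.0, 20.0: 0.8})
    #: std of the per-trial log-normal source gain (inter-trial variability)
    amp_jitter: float = 0.1
    #: std of the slow (<~0.5 Hz) amplitude modulation of each source
    am_depth: float = 0.15
    #: Lorentzian linewidth (Hz) of each rhythm: oscillators carry a
    #: diffusing phase, so hemispheres decorrelate as real rhythms do
    linewidth: float = 1.2
    #: half-separation (Hz) of the two hemispheres' peak frequencies
    #: (individual peaks never coincide exactly; decorrelates hemispheres)
    hemi_freq_offset: float = 0.2
    noise_pink_level: float = 0.15
    noise_white_level: float = 0.20
    #: spatially structured background: class-independent 1/f sources mixed
    #: through random smooth field patterns (brain/environmental noise is
    #: strongly correlated across sensors, unlike per-channel sensor noise)
    n_noise_sources: int = 12
    noise_structured_level: float = 0.11
    noise_pattern_width: float = 0.5
    #: log-std of the per-(trial, source) background power bursts; heavy
    #: tails emulate artifact-like transients with unchanged mean power
    noise_burst_sigma: float = 0.6
    #: task-irrelevant ongoing rhythms (Hz) with session-random smooth
    #: patterns and bursty per-trial power; they sit inside the broad
    #: analysis band but away from the mu/beta scoring bands
    distractor_freqs: tuple[float, ...] = (14.0,)
    distractor_amp: float = 0.45
    distractor_burst_sigma: float = 0.6
    #: distractors get their own (narrower) linewidth so their tails stay
    #: out of the mu/beta scoring bands
    distractor_linewidth: float = 0.7
    distractor_pattern_width: float = 0.4
    #: per-(trial, channel) log-normal gain: head movement relative to the
    #: fixed sensor array rescales sensor amplitudes trial by trial; it
    #: multiplies a trial's baseline and imagery windows identically, so
    #: power ratios are unaffected while single-channel features blur
    channel_gain_jitter: float = 0.0
    #: raised-cosine transition length of the ERD/ERS envelope, seconds
    transition: float = 0.25
    pattern_width: float = 0.35

    def validate(self) -> None:
        if self.n_channels < 1:
            raise SimConfigError("n_channels must be >= 1")
        if self.sfreq <= 0:
            raise SimConfigError("sfreq must be positive")
        if self.tmin >= 0 or self.tmax <= 0:
            raise SimConfigError("epoch span (tmin, tmax) must bracket the cue")
        for f in self.rhythm_freqs:
            if f >= self.sfreq / 2:
                raise SimConfigError(
                    f"rhythm_freqs: {f} Hz not below Nyquist ({self.sfreq / 2})")
        for f in self.distractor_freqs:
            if f >= self.sfreq / 2:
                raise SimConfigError(
                    f"distractor_freqs: {f} Hz not below Nyquist")
        if self.distractor_amp < 0:
            raise SimConfigError("distractor_amp must be >= 0")
        for name, depths in (("erd_contra", self.erd_contra),
                             ("erd_ipsi", self.erd_ipsi)):
            for f in self.rhythm_freqs:
                if f not in depths:
                    raise SimConfigError(f"{name}: missing depth for {f} Hz")
                if not -1.0 <= depths[f] <= 0.0:
                    raise SimConfigError(
                        f"{name}: depth {depths[f]} for {f} Hz not in [-1, 0]")
        if not 0 < self.erd_onset < self.erd_offset <= self.tmax:
            raise SimConfigError(
                "erd_onset/erd_offset must satisfy 0 < onset < offset <= tmax")
        if self.ers_gain < 0:
            raise SimConfigError("ers_gain must be >= 0")
        if self.noise_pink_level < 0 or self.noise_white_level < 0 \
                or self.noise_structured_level < 0:
            raise SimConfigError("noise levels must be >= 0")
        if self.n_noise_sources < 0:
            raise SimConfigError("n_noise_sources must be >= 0")
        if self.linewidth < 0:
            raise SimConfigError("linewidth must be >= 0")
        if self.n_trials_per_class < 1:
            raise SimConfigError("n_trials_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round((self.tmax - self.tmin) * self.sfreq))

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def depth(self, freq: float, hemisphere: str, label: str) -> float:
        """Planted relative power change for (rhythm, hemisphere, class)."""
        contra = (RIGHT if hemisphere == "left" else LEFT)
        return (self.erd_contra[freq] if label == contra
                else self.erd_ipsi[freq])


def planted_truth(config: SimConfig) -> dict[tuple[float, str, str], float]:
    """Analytic expected suppression percentage per (rhythm, hemisphere,
    class), as implied directly by the configured depths."""
    config.validate()
    return {(f, h, lab): 100.0 * config.depth(f, h, lab)
            for f in config.rhythm_freqs
            for h in HEMISPHERES
            for lab in (LEFT, RIGHT)}


def _raised_cosine_step(t: np.ndarray, t_edge: float, width: float) -> np.ndarray:
    """Smooth 0 -> 1 transition centred on ``t_edge`` over ``width`` s."""
    x = np.clip((t - (t_edge - width / 2)) / width, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * x))


def _power_envelope(cfg: SimConfig, depth: float) -> np.ndarray:
    """Relative power profile over the trial: 1 at rest, ``1 + depth``
    during imagery, ``1 + ers_gain`` during the rebound, then back to 1."""
    t = cfg.times
    levels = [1.0, 1.0 + depth, 1.0 + cfg.ers_gain, 1.0]
    edges = [cfg.erd_onset, cfg.erd_offset,
             cfg.erd_offset + cfg.ers_duration]
    p = np.full_like(t, levels[0])
    for lo, hi, edge in zip(levels[:-1], levels[1:], edges):
        p = p + (hi - lo) * _raised_cosine_step(t, edge, cfg.transition)
    return p


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float,
                level: float) -> np.ndarray:
    """Spectrally shaped white noise with a 1/f power profile (flat below
    1 Hz), normalised to the requested standard deviation."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], 1.0 / sfreq)
    spec *= 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    pink = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = pink.std()
    if sd > 0:
        pink *= level / sd
    return pink


def generate_session(config: SimConfig, seed: int,
                     session_id: str | None = None) -> EpochSet:
    """Generate one session of epoched sensor data.

    Trials alternate LEFT/RIGHT in a seed-randomised order
    (``n_trials_per_class`` each).  Identical ``config`` and ``seed``
    produce bit-identical output.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(seed)

    names, pos = sensor_grid(cfg.n_channels)
    n_trials = 2 * cfg.n_trials_per_class
    n = cfg.n_samples
    t = cfg.times

    labels = np.asarray([LEFT] * cfg.n_trials_per_class
                        + [RIGHT] * cfg.n_trials_per_class, dtype=object)
    rng.shuffle(labels)

    # hemisphere mixing patterns; the beta source sits slightly anterior
    centers = {"left": -0.45, "right": 0.45}
    y_off = {cfg.rhythm_freqs[i]: 0.15 * i
             for i in range(len(cfg.rhythm_freqs))}
    patterns = {(h, f): _gaussian_pattern(pos, (centers[h], y_off[f]),
                                          cfg.pattern_width)
                for h in HEMISPHERES for f in cfg.rhythm_freqs}

    n_h, n_f = len(HEMISPHERES), len(cfg.rhythm_freqs)
    # slow amplitude modulation: low-passed white noise (~0.5 Hz), mean 1
    am = rng.standard_normal((n_trials, n_h, n_f, n))
    am = gaussian_filter1d(am, sigma=0.3 * cfg.sfreq, axis=-1, mode="reflect")
    sd = am.std(axis=-1, keepdims=True)
    am = 1.0 + cfg.am_depth * am / np.where(sd > 0, sd, 1.0)
    np.clip(am, 0.05, None, out=am)

    phases = rng.uniform(0, 2 * np.pi, size=(n_trials, n_h, n_f))
    gains = np.exp(cfg.amp_jitter * rng.standard_normal((n_trials, n_h, n_f)))
    # Brownian phase with per-sample std sigma gives a Lorentzian line of
    # full width sigma^2 * sfreq / (2 pi); independent walks per source
    sigma_phi = np.sqrt(2 * np.pi * cfg.linewidth / cfg.sfreq)
    dphi = np.cumsum(sigma_phi * rng.standard_normal((n_trials, n_h, n_f, n)),
                     axis=-1)

    data = np.zeros((n_trials, cfg.n_channels, n))
    for hi, h in enumerate(HEMISPHERES):
        for fi, f in enumerate(cfg.rhythm_freqs):
            f_hemi = f + (-1, 1)[hi] * cfg.hemi_freq_offset
            carrier = np.cos(2 * np.pi * f_hemi * t[None, :]
                             + phases[:, hi, fi][:, None]
                             + dphi[:, hi, fi])
            # sqrt(2): unit-RMS carrier, so source_amp is the source RMS
            src = (np.sqrt(2.0) * cfg.source_amp[f]
                   * gains[:, hi, fi][:, None] * am[:, hi, fi] * carrier)
            for lab in (LEFT, RIGHT):
                mask = labels == lab
                env = np.sqrt(_power_envelope(cfg, cfg.depth(f, h, lab)))
                src[mask] *= env[None, :]
            data += patterns[(h, f)][None, :, None] * src[:, None, :]

    if cfg.distractor_amp > 0 and cfg.distractor_freqs:
        sigma_phi_d = np.sqrt(2 * np.pi * cfg.distractor_linewidth
                              / cfg.sfreq)
        for f in cfg.distractor_freqs:
            pat = _gaussian_pattern(pos, rng.uniform([-1.0, -0.5], [1.0, 0.5]),
                                    cfg.distractor_pattern_width)
            phi0 = rng.uniform(0, 2 * np.pi, n_trials)
            walk = np.cumsum(sigma_phi_d * rng.standard_normal((n_trials, n)),
                             axis=-1)
            osc = np.cos(2 * np.pi * f * t[None, :] + phi0[:, None] + walk)
            z = rng.standard_normal(n_trials)
            amp = cfg.distractor_amp * np.sqrt(2.0) * np.exp(
                cfg.distractor_burst_sigma * z
                - cfg.distractor_burst_sigma ** 2)
            data += pat[None, :, None] * (amp[:, None] * osc)[:, None, :]

    if cfg.n_noise_sources > 0 and cfg.noise_structured_level > 0:
        centers = rng.uniform([-1.0, -0.5], [1.0, 0.5],
                              size=(cfg.n_noise_sources, 2))
        amps = rng.choice([-1.0, 1.0], cfg.n_noise_sources) \
            * rng.uniform(0.5, 1.5, cfg.n_noise_sources)
        bg_pat = np.stack([a * _gaussian_pattern(pos, c,
                                                 cfg.noise_pattern_width)
                           for c, a in zip(centers, amps)])
        bg = _pink_noise(rng, (n_trials, cfg.n_noise_sources, n),
                         cfg.sfreq, cfg.noise_structured_level)
        if cfg.noise_burst_sigma > 0:
            # mean-one power bursts: exp(2 s z - 2 s^2), E[exp(2 s z)] = e^{2 s^2}
            z = rng.standard_normal((n_trials, cfg.n_noise_sources))
            bg *= np.exp(cfg.noise_burst_sigma * z
                         - cfg.noise_burst_sigma ** 2)[:, :, None]
        data += np.einsum("kc,tks->tcs", bg_pat, bg)
    if cfg.noise_pink_level > 0:
        data += _pink_noise(rng, (n_trials, cfg.n_channels, n),
                            cfg.sfreq, cfg.noise_pink_level)
    if cfg.noise_white_level > 0:
        data += cfg.noise_white_level * rng.standard_normal(
            (n_trials, cfg.n_channels, n))
    if cfg.channel_gain_jitter > 0:
        gains_ch = np.exp(cfg.channel_gain_jitter
                          * rng.standard_normal((n_trials, cfg.n_channels)))
        data *= gains_ch[:, :, None]

    return EpochSet(data=data, sfreq=cfg.sfreq, t0=cfg.tmin, labels=labels,
                    session_id=session_id or f"sim-{seed}",
                    channel_names=names, channel_positions=pos)
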
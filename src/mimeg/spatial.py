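"""Spatial filtering: shrinkage covariances, CSP, FBCSP, SSD and SSD+CSP.

Common Spatial Patterns (CSP) finds filters ``w`` maximising the variance
ratio between two classes via the generalized eigenproblem
``C1 w = lambda (C1 + C2) w``; Spatio-Spectral Decomposition (SSD) finds
filters maximising power in a band of interest against its flanking bands
via ``C_signal w = lambda C_flank w``.  Both are solved here by whitening
the right-hand covariance and diagonalising the transformed left-hand one —
the numerically stable equivalent of the generalized problem — and both
covariances are regularized with analytic Ledoit-Wolf shrinkage so the
decompositions remain well-posed even for rank-deficient data.

Filters are always fitted on training trials only; applying a stored model
to held-out trials is a fixed linear projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import (BandSpec, EpochSet, ParameterError, crop_window,
                            fir_bandpass)
from .spectral import FeatureMatrix, multitaper_band_psd

__all__ = [
    "CovarianceEstimate", "SpatialFilterModel", "SSDModel", "FBCSPModel",
    "lws_covariance", "fit_csp", "apply_filters", "logvar_features",
    "fit_fbcsp", "find_suppression_peak", "fit_ssd", "fit_ssd_csp",
    "solve_gen_eig", "DataError",
]

#: the six FBCSP analysis bands (Hz), FIR transition 1.0 Hz
FBCSP_BANDS = tuple(BandSpec(lo, lo + 4, transition=1.0)
                    for lo in (8, 12, 16, 20, 24, 28))


class DataError(ValueError):
    """Input data cannot support the requested fit (too few trials, ...)."""


@dataclass
class CovarianceEstimate:
    """Class-average trial covariance after Ledoit-Wolf shrinkage."""

    C: np.ndarray
    shrinkage: float
    n_trials: int
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.C, float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.C = 0.5 * (C + C.T)


@dataclass
class SpatialFilterModel:
    """Fitted spatial filters.

    ``W`` rows are filters (components x channels); ``patterns`` columns
    are the corresponding forward topographies for display; eigenvalues are
    the generalized eigenvalues of the retained components (for CSP the
    class-1 variance fraction, in (0, 1))."""

    W: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    method: str
    band: BandSpec | None = None
    class_pair: tuple | None = None
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    def component_names(self) -> list[str]:
        return [f"{self.method}{i:02d}" for i in range(self.n_components)]


@dataclass
class SSDModel(SpatialFilterModel):
    """SSD filters plus the frequency geometry that produced them."""

    f_star: float = 0.0
    signal_band: BandSpec | None = None
    flank_lo: BandSpec | None = None
    flank_hi: BandSpec | None = None


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def _trial_slice(epochs: EpochSet, window) -> EpochSet:
    return crop_window(epochs, *window) if window is not None else epochs


def ledoit_wolf_lambda_trials(covs: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity at the trial level.

    The published estimator balances the dispersion of the observations
    around their mean against the distance of the mean from the scaled
    identity target: ``lambda = min(b2, d2) / d2`` with
    ``b2 = sum_i ||C_i - Cbar||_F^2 / n^2`` and
    ``d2 = ||Cbar - mu I||_F^2``.  Treating each *trial's* covariance as
    one independent observation keeps the estimate honest for band-limited
    epochs, whose samples are strongly autocorrelated (far fewer effective
    degrees of freedom than time points); the sample-level formula would
    under-regularize them.
    """
    covs = np.asarray(covs, float)
    n, p, _ = covs.shape
    C = covs.mean(axis=0)
    mu = np.trace(C) / p
    d2 = float(np.sum((C - mu * np.eye(p)) ** 2))
    if d2 <= 0:
        return 0.0
    b2 = float(np.sum((covs - C) ** 2)) / n ** 2
    return min(b2, d2) / d2


def lws_covariance(epochs: EpochSet, class_label: str | None = None,
                   window: tuple[float, float] | None = None,
                   band: BandSpec | None = None,
                   trace_normalize: bool = True) -> CovarianceEstimate:
    """Ledoit-Wolf-shrunk average covariance of one class's trials.

    Per-trial covariances are trace-normalized (equalizing trial power)
    before averaging; the analytic shrinkage intensity is estimated from
    the dispersion of the per-trial covariances
    (:func:`ledoit_wolf_lambda_trials`) and the average is shrunk toward
    the scaled identity ``trace(C)/p * I``.

    ``trace_normalize=False`` keeps absolute scale — required when total
    power *is* the class contrast (imagery versus rest), where
    normalization would cancel the signal the filters should find.
    """
    if class_label is not None:
        sel = epochs.labels == class_label
        if sel.sum() < 2:
            raise DataError(
                f"need >= 2 trials of class {class_label!r}, got {sel.sum()}")
        epochs = epochs.subset(np.flatnonzero(sel))
    elif epochs.n_trials < 2:
        raise DataError("need >= 2 trials")
    epochs = _trial_slice(epochs, window)

    X = epochs.data                       # (trials, ch, samples)
    n = X.shape[-1]
    covs = np.einsum("tcs,tds->tcd", X, X) / n
    if trace_normalize:
        traces = np.trace(covs, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise DataError("trial with zero power; cannot trace-normalize")
        covs /= traces[:, None, None]
    C = covs.mean(axis=0)
    lam = ledoit_wolf_lambda_trials(covs)
    p = C.shape[0]
    mu = np.trace(C) / p
    C_shrunk = (1 - lam) * C + lam * mu * np.eye(p)
    return CovarianceEstimate(C=C_shrunk, shrinkage=lam,
                              n_trials=X.shape[0], band=band)


# ---------------------------------------------------------------------------
# generalized eigenproblem via whitening
# ---------------------------------------------------------------------------

def _sym_inv_sqrt(B: np.ndarray) -> np.ndarray:
    d, V = np.linalg.eigh(0.5 * (B + B.T))
    if d.min() <= 0:
        raise np.linalg.LinAlgError(
            f"matrix not positive definite (min eigenvalue {d.min():.3e}); "
            "shrinkage should prevent this")
    return V @ np.diag(1.0 / np.sqrt(d)) @ V.T


def solve_gen_eig(A: np.ndarray, B: np.ndarray):
    """Solve ``A w = lambda B w`` for symmetric A and SPD B by whitening.

    Returns ``(eigenvalues, W)`` sorted by descending eigenvalue, with
    filters as the *rows* of ``W`` (so component signals are ``W @ x``),
    normalized to ``w' B w = 1``.
    """
    P = _sym_inv_sqrt(B)
    S = P @ (0.5 * (A + A.T)) @ P
    d, U = np.linalg.eigh(0.5 * (S + S.T))
    order = np.argsort(d)[::-1]
    W = (U[:, order].T @ P)
    return d[order], W


def _patterns_from_filters(W_full: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Forward topographies: columns of the inverse of the full filter
    matrix, for the selected components, with a sign convention that the
    largest-magnitude pattern entry is positive."""
    A_full = np.linalg.inv(W_full)          # columns are patterns
    patterns = A_full[:, sel]
    signs = np.sign(patterns[np.abs(patterns).argmax(axis=0),
                             np.arange(patterns.shape[1])])
    signs[signs == 0] = 1.0
    return patterns * signs, signs


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def fit_csp(epochs: EpochSet, classes: tuple[str, str],
            band: BandSpec | None = None, n_per_class: int = 3,
            cov_window: tuple[float, float] | None = None,
            trace_normalize: bool = True) -> SpatialFilterModel:
    """Common Spatial Patterns on band-filtered epochs.

    Solves ``C1 w = lambda (C1 + C2) w`` on the shrunk class covariances
    and retains the ``n_per_class`` eigenvectors with the largest and the
    smallest eigenvalues (most discriminative for each class).  The epochs
    are expected to be band-pass filtered already; ``band`` is metadata.
    """
    c1 = lws_covariance(epochs, classes[0], window=cov_window, band=band,
                        trace_normalize=trace_normalize)
    c2 = lws_covariance(epochs, classes[1], window=cov_window, band=band,
                        trace_normalize=trace_normalize)
    Cc = c1.C + c2.C
    d, W_full = solve_gen_eig(c1.C, Cc)
    n_ch = Cc.shape[0]
    if 2 * n_per_class > n_ch:
        raise ParameterError(
            f"cannot retain 2x{n_per_class} components from {n_ch} channels")
    sel = np.r_[np.arange(n_per_class), np.arange(n_ch - n_per_class, n_ch)]
    patterns, signs = _patterns_from_filters(W_full, sel)
    return SpatialFilterModel(W=W_full[sel] * signs[:, None],
                              patterns=patterns,
                              eigenvalues=d[sel], method="CSP", band=band,
                              class_pair=tuple(classes),
                              channel_names=list(epochs.channel_names))


def apply_filters(model: SpatialFilterModel, epochs: EpochSet) -> EpochSet:
    """Project epochs onto the model's components (components become the
    'channels' of the returned epoch set)."""
    if model.W.shape[1] != epochs.n_channels:
        raise ParameterError(
            f"model expects {model.W.shape[1]} channels, "
            f"epochs have {epochs.n_channels}")
    comp = np.einsum("kc,tcs->tks", model.W, epochs.data)
    return epochs.copy(data=comp, channel_names=model.component_names(),
                       channel_positions=None)


def logvar_features(component_epochs: EpochSet,
                    window: tuple[float, float] = (0.5, 3.0)
                    ) -> FeatureMatrix:
    """Log of the windowed mean-square of each component signal — the
    standard scalar feature after spatial filtering."""
    cropped = crop_window(component_epochs, *window)
    ms = np.mean(cropped.data ** 2, axis=2)
    if np.any(ms <= 0):
        raise DataError("all-zero component signal; log-variance undefined")
    desc = [(name, f"logvar[{window[0]:g},{window[1]:g})s")
            for name in component_epochs.channel_names]
    return FeatureMatrix(np.log(ms), desc, component_epochs.labels)


# ---------------------------------------------------------------------------
# FBCSP
# ---------------------------------------------------------------------------

@dataclass
class FBCSPModel:
    """Per-band CSP models plus the cross-band chi-square feature selection
    fitted on training data."""

    band_models: list[SpatialFilterModel]
    bands: tuple[BandSpec, ...]
    selected: np.ndarray
    scores: np.ndarray
    logvar_window: tuple[float, float]

    def features(self, band_epochs: list[EpochSet],
                 select: bool = True) -> FeatureMatrix:
        """Log-variance features from per-band filtered epochs; ``select``
        applies the fitted top-k choice."""
        parts = []
        for band, model in zip(self.bands, self.band_models):
            eps = band_epochs[self.bands.index(band)]
            comp = apply_filters(model, eps)
            fm = logvar_features(comp, self.logvar_window)
            fm.feature_desc = [(band.name,) + d for d in fm.feature_desc]
            parts.append(fm)
        full = FeatureMatrix.hstack(parts)
        return full.select(self.selected) if select else full


def fit_fbcsp(epochs: EpochSet, classes: tuple[str, str],
              bands: tuple[BandSpec, ...] = FBCSP_BANDS,
              n_per_class: int = 3, n_select: int = 18,
              cov_window: tuple[float, float] | None = (0.5, 3.0),
              logvar_window: tuple[float, float] = (0.5, 3.0),
              prefiltered: list[EpochSet] | None = None,
              trace_normalize: bool = True
              ) -> tuple[FBCSPModel, list[EpochSet]]:
    """Filter-bank CSP: per-band CSP fits plus chi-square feature selection.

    ``epochs`` are broadband; each band is FIR-filtered (or taken from
    ``prefiltered``, matching ``bands`` order), CSP fitted per band, the
    6 x n_bands log-variance features scored by chi-square against the
    labels on the training data and the top ``n_select`` retained.
    Returns the model and the per-band filtered training epochs (reusable
    by callers that apply the model to the same data).
    """
    from .decoding import chi2_scores, select_k_best

    if prefiltered is None:
        prefiltered = [fir_bandpass(epochs, b) for b in bands]
    models = []
    for band, beps in zip(bands, prefiltered):
        models.append(fit_csp(beps, classes, band=band,
                              n_per_class=n_per_class,
                              cov_window=cov_window,
                              trace_normalize=trace_normalize))
    model = FBCSPModel(band_models=models, bands=tuple(bands),
                       selected=np.arange(0), scores=np.zeros(0),
                       logvar_window=logvar_window)
    full = model.features(prefiltered, select=False)
    scores = chi2_scores(full.X, full.labels)
    model.selected = select_k_best(scores, min(n_select, full.n_features))
    model.scores = scores
    return model, prefiltered


# ---------------------------------------------------------------------------
# SSD
# ---------------------------------------------------------------------------

def find_suppression_peak(epochs: EpochSet,
                          search_band: tuple[float, float] = (8.0, 30.0),
                          baseline_window: tuple[float, float] = (-4.0, -2.0),
                          mi_window: tuple[float, float] = (1.0, 3.0),
                          prominence: float = 0.2) -> float:
    """Frequency (1-Hz bin) of maximum power suppression, imagery versus
    baseline, averaged over trials and channels — the subject's most
    reactive rhythm frequency, found in sensor space with multitaper PSD.

    Bins are ranked by the *absolute* power decrease ``base - imagery``:
    a rhythm can only be suppressed where it exists, and the absolute
    decrease localizes at the rhythm's spectral peak, whereas the relative
    change is near-flat (and sampling-noise-ranked) across a peak's tails
    and leakage bins.  ``prominence`` additionally restricts candidates to
    bins whose baseline power is a minimum fraction of the strongest bin;
    on a flat spectrum every bin qualifies.
    """
    p_base, centers = multitaper_band_psd(
        crop_window(epochs, *baseline_window).data, epochs.sfreq,
        *search_band)
    p_mi, _ = multitaper_band_psd(
        crop_window(epochs, *mi_window).data, epochs.sfreq, *search_band)
    base = p_base.mean(axis=(0, 1))
    drop = base - p_mi.mean(axis=(0, 1))
    candidates = base >= prominence * base.max()
    if drop[candidates].max() <= 0:
        warnings.warn("no frequency bin shows power suppression; "
                      "returning the least-increasing bin", RuntimeWarning)
    masked = np.where(candidates, drop, -np.inf)
    return float(centers[np.argmax(masked)])


def ssd_bands(f_star: float, sfreq: float,
              transition: float = 1.0) -> tuple[BandSpec, BandSpec, BandSpec]:
    """Signal band ``f* +- 2`` Hz and the adjacent 4-Hz-wide flanks."""
    sig = BandSpec(f_star - 2.0, f_star + 2.0, transition)
    lo = BandSpec(f_star - 6.0, f_star - 2.0, transition)
    hi = BandSpec(f_star + 2.0, f_star + 6.0, transition)
    for b in (sig, lo, hi):
        b.validate_for(sfreq)
    return sig, lo, hi


def fit_ssd(epochs: EpochSet, f_star: float, n_keep: int = 20,
            transition: float = 1.0,
            prefiltered: tuple[EpochSet, EpochSet, EpochSet] | None = None
            ) -> SSDModel:
    """Spatio-Spectral Decomposition around the peak-suppression frequency.

    Maximizes band power at ``f* +- 2`` Hz relative to the pooled adjacent
    4-Hz flanks via ``C_signal w = lambda C_flank w`` on shrunk
    covariances; the top ``n_keep`` components (descending eigenvalue,
    i.e. descending signal-to-flank power ratio) are retained.
    """
    sig, lo, hi = ssd_bands(f_star, epochs.sfreq, transition)
    if prefiltered is None:
        prefiltered = (fir_bandpass(epochs, sig), fir_bandpass(epochs, lo),
                       fir_bandpass(epochs, hi))
    eps_sig, eps_lo, eps_hi = prefiltered
    C_sig = lws_covariance(eps_sig, band=sig)
    C_flank = 0.5 * (lws_covariance(eps_lo, band=lo).C
                     + lws_covariance(eps_hi, band=hi).C)
    d, W_full = solve_gen_eig(C_sig.C, C_flank)
    n_keep = min(n_keep, W_full.shape[0])
    sel = np.arange(n_keep)
    patterns, signs = _patterns_from_filters(W_full, sel)
    return SSDModel(W=W_full[sel] * signs[:, None], patterns=patterns,
                    eigenvalues=d[sel], method="SSD", band=sig,
                    channel_names=list(epochs.channel_names),
                    f_star=f_star, signal_band=sig, flank_lo=lo, flank_hi=hi)


@dataclass
class ComposedModel:
    """SSD followed by CSP; the composite filter equals sequential
    application of the two stages and both remain inspectable."""

    ssd: SSDModel
    csp: SpatialFilterModel
    composite: SpatialFilterModel


def fit_ssd_csp(epochs: EpochSet, classes: tuple[str, str], f_star: float,
                n_keep: int = 20, n_per_class: int = 3,
                cov_window: tuple[float, float] | None = (0.5, 3.0),
                csp_epochs: EpochSet | None = None,
                prefiltered=None,
                trace_normalize: bool = True) -> ComposedModel:
    """SSD as narrowband preprocessing, CSP on the SSD component signals.

    ``n_keep`` is 20 for left-vs-right and 30 for imagery-vs-rest.  CSP is
    fitted on ``csp_epochs`` (defaults to ``epochs``) after SSD projection,
    so callers can fit SSD on whole trials but CSP on task-specific crops.
    """
    ssd = fit_ssd(epochs, f_star, n_keep=n_keep, prefiltered=prefiltered)
    source = csp_epochs if csp_epochs is not None else \
        (prefiltered[0] if prefiltered is not None
         else fir_bandpass(epochs, ssd.signal_band))
    comp = apply_filters(ssd, source)
    csp = fit_csp(comp, classes, band=ssd.signal_band,
                  n_per_class=n_per_class, cov_window=cov_window,
                  trace_normalize=trace_normalize)
    W = csp.W @ ssd.W
    # composite forward patterns via the two stages' patterns
    patterns = ssd.patterns @ csp.patterns
    composite = SpatialFilterModel(
        W=W, patterns=patterns, eigenvalues=csp.eigenvalues,
        method="SSD+CSP", band=ssd.signal_band, class_pair=tuple(classes),
        channel_names=list(epochs.channel_names))
    return ComposedModel(ssd=ssd, csp=csp, composite=composite)
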
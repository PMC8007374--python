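"""Band-averaged magnitude-squared coherence between all channel pairs.

The connectivity measure is the magnitude-squared coherence

    C^2(f) = |P_ab(f)|^2 / (P_aa(f) P_bb(f)),

bounded in [0, 1]: 0 for independent signals, 1 for perfectly synchronized
ones.  Auto and cross spectra are Welch estimates — tapered, overlapping
segments taken within each trial, with periodogram cross-products averaged
over *all segments of all trials* (pooled, the default) before the ratio is
formed.  Averaging per-trial coherences instead is a different, upward-biased
estimator; it is available behind ``per_trial=True`` for comparison.

The scalar edge weight for a band is the arithmetic mean of C^2 over the
Welch bins inside the band, and the full symmetric node x node matrix of
these values is the coherence matrix handed to the network stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CoherenceMatrix, EpochSet
from .design import BandDefinition, get_band

#: Welch defaults: 1 s Hann windows, 50% overlap.
DEFAULT_WELCH = (1.0, 0.5, "hann")


@dataclass
class SpectralEstimate:
    """Welch cross-spectral matrix over all channel pairs.

    ``csd`` has shape (n_channels, n_channels, n_freqs); its diagonal holds
    the (real, nonnegative) auto spectra.  ``degenerate`` flags channels
    whose total power is zero, for which coherence is undefined.
    """

    freqs: np.ndarray
    csd: np.ndarray
    n_segments: int
    n_trials: int
    welch_params: Tuple[float, float, str]

    def auto(self, i: int) -> np.ndarray:
        return self.csd[i, i].real

    @property
    def degenerate(self) -> np.ndarray:
        return np.array([self.auto(i).sum() == 0 for i in range(self.csd.shape[0])])


def cross_spectra(
    epochs: EpochSet,
    welch_params: Tuple[float, float, str] = DEFAULT_WELCH,
) -> SpectralEstimate:
    """Welch auto and cross spectra for every channel pair, pooled over trials.

    Segments of ``window_s`` seconds with the stated overlap are tapered and
    FFT'd inside each trial; cross products ``X_a X_b*`` are averaged over
    every segment of every trial.
    """
    window_s, overlap, shape = welch_params
    fs = epochs.sampling_rate
    nper = round(window_s * fs)
    if nper > epochs.n_samples:
        raise ValueError(
            f"Welch window of {nper} samples exceeds trial length of "
            f"{epochs.n_samples} samples"
        )
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap fraction {overlap} outside [0, 1)")
    step = max(1, round(nper * (1 - overlap)))
    win = signal.get_window(shape, nper)
    starts = np.arange(0, epochs.n_samples - nper + 1, step)
    # (channels, trials, segments, nper) -> rFFT -> pooled outer products
    segs = np.stack(
        [epochs.data[:, s : s + nper, :].transpose(0, 2, 1) for s in starts],
        axis=2,
    )
    segs = signal.detrend(segs, axis=-1, type="constant") * win
    X = np.fft.rfft(segs, axis=-1)
    scale = 1.0 / (fs * (win**2).sum())
    csd = np.einsum("aijf,bijf->abf", np.conj(X), X) * scale  # P_ab = E[X_a* X_b]
    n_seg_total = epochs.n_trials * len(starts)
    csd /= n_seg_total
    # one-sided scaling (all interior bins doubled), matching scipy.signal
    if nper % 2 == 0:
        csd[..., 1:-1] *= 2
    else:
        csd[..., 1:] *= 2
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    # enforce exactly-real nonnegative auto spectra
    di = np.arange(epochs.n_channels)
    csd[di, di] = csd[di, di].real.clip(min=0)
    return SpectralEstimate(
        freqs=freqs, csd=csd, n_segments=n_seg_total,
        n_trials=epochs.n_trials, welch_params=tuple(welch_params),
    )


def coherence_from_spectra(
    p_aa: np.ndarray, p_bb: np.ndarray, p_ab: np.ndarray
) -> np.ndarray:
    """C^2(f) = |P_ab|^2 / (P_aa P_bb) per bin; NaN where a spectrum is 0."""
    p_aa = np.asarray(p_aa, float)
    p_bb = np.asarray(p_bb, float)
    p_ab = np.asarray(p_ab)
    if not (p_aa.shape == p_bb.shape == p_ab.shape):
        raise ValueError(
            f"spectra grids differ: {p_aa.shape}, {p_bb.shape}, {p_ab.shape}"
        )
    denom = p_aa * p_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        c2 = np.abs(p_ab) ** 2 / denom
    c2 = np.where(denom > 0, c2, np.nan)
    return np.clip(c2, 0.0, 1.0)


def band_average(
    c2: np.ndarray, freqs: np.ndarray, band: "str | BandDefinition"
) -> float:
    """Arithmetic mean of C^2 over bins with f_low <= f <= f_high.

    Bins flagged NaN (zero-power) are skipped; if no usable bin falls inside
    the band the call fails, naming the grid resolution.
    """
    b = get_band(band)
    freqs = np.asarray(freqs, float)
    mask = (freqs >= b.f_low) & (freqs <= b.f_high)
    vals = np.asarray(c2, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        df = freqs[1] - freqs[0] if len(freqs) > 1 else float("nan")
        raise ValueError(
            f"no usable frequency bins inside band {b.name} "
            f"[{b.f_low}, {b.f_high}] Hz (grid resolution {df} Hz)"
        )
    return float(vals.mean())


def coherence_matrix(
    epochs: EpochSet,
    band: "str | BandDefinition",
    welch_params: Tuple[float, float, str] = DEFAULT_WELCH,
    per_trial: bool = False,
) -> CoherenceMatrix:
    """Symmetric matrix of band-averaged squared coherence over all pairs."""
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels for a coherence matrix")
    b = get_band(band)
    n = epochs.n_channels
    if per_trial:
        mats = []
        for t in range(epochs.n_trials):
            single = epochs.with_data(epochs.data[:, :, t : t + 1])
            mats.append(
                coherence_matrix(single, b, welch_params).values
            )
        values = np.mean(mats, axis=0)
        np.fill_diagonal(values, 1.0)
        return CoherenceMatrix(
            values=values, band=b, node_labels=list(epochs.channel_labels),
            n_trials_used=epochs.n_trials, welch_params=tuple(welch_params),
        )
    est = cross_spectra(epochs, welch_params)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c2 = coherence_from_spectra(est.auto(i), est.auto(j), est.csd[i, j])
            values[i, j] = values[j, i] = band_average(c2, est.freqs, b)
    return CoherenceMatrix(
        values=values, band=b, node_labels=list(epochs.channel_labels),
        n_trials_used=epochs.n_trials, welch_params=tuple(welch_params),
    )


class CoherenceEstimator(TransformerMixin, BaseEstimator):
    """Transformer: EpochSet -> CoherenceMatrix for one band.

    Parameters mirror :func:`coherence_matrix`; after ``fit`` the Welch
    frequency grid is available as ``freqs_``.
    """

    def __init__(
        self,
        band: str = "full",
        welch_window_s: float = 1.0,
        welch_overlap: float = 0.5,
        welch_shape: str = "hann",
        per_trial: bool = False,
    ):
        self.band = band
        self.welch_window_s = welch_window_s
        self.welch_overlap = welch_overlap
        self.welch_shape = welch_shape
        self.per_trial = per_trial

    @property
    def _welch(self) -> Tuple[float, float, str]:
        return (self.welch_window_s, self.welch_overlap, self.welch_shape)

    def fit(self, X: EpochSet, y=None):
        if not isinstance(X, EpochSet):
            raise TypeError(f"expected EpochSet, got {type(X).__name__}")
        get_band(self.band)
        nper = round(self.welch_window_s * X.sampling_rate)
        self.freqs_ = np.fft.rfftfreq(nper, 1.0 / X.sampling_rate)
        return self

    def transform(self, X: EpochSet) -> CoherenceMatrix:
        return coherence_matrix(X, self.band, self._welch, self.per_trial)
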
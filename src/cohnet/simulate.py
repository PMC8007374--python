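"""Synthetic two-session EEG-like study generator.

Signal model
------------
Each channel of each trial is independent broadband Gaussian noise.  A
:class:`~cohnet.design.CouplingSpec` adds a *shared* narrowband source (white
noise band-passed to the coupling's band, normalized to unit variance per trial)
to both endpoint channels:

    x_ch(t) = noise_sd * n_ch(t) + weight * source_amp_uv * s(t)

``source_amp_uv`` (default 10 uV, a typical scalp-rhythm amplitude, equal to
the default noise level) sets the physical scale of the shared rhythm; with
it fixed, coherence rises monotonically with the mixing weight and falls
with ``noise_sd``, reaching 1 in the noise-free limit.  Squared coherence on
a coupled edge is, per frequency bin,

    C^2(f) = ( r S(f) / (r S(f) + N) )^2,   r = (weight * source_amp_uv)^2

with S the unit-variance source power spectral density and N the flat
density of noise with variance ``noise_sd**2``;
:func:`expected_band_coherence` evaluates the band average of this
expression from the actual filter response and
:func:`weight_for_coherence` inverts it, which is how session weights are
chosen to hit a target coherence.

Seeding
-------
All randomness derives from ``design.seed`` through labeled
``np.random.SeedSequence`` spawn keys ``(stream, subject, session)``:
stream 0 = epoch noise/sources, stream 1 = behavior, stream 2 = per-subject
weight perturbations.  Adding subjects or trials therefore never changes the
data of earlier subjects, and the same seed reproduces the collection
bit-for-bit.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, stats

from .containers import EpochSet
from .design import BehaviorSpec, CouplingSpec, StudyDesign, get_band

_STREAM_EPOCHS = 0
_STREAM_BEHAVIOR = 1
_STREAM_SUBJECT = 2


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _band_sos(band, fs: float):
    b = get_band(band)
    high = min(b.f_high, 0.999 * fs / 2)
    return signal.butter(4, (b.f_low, high), btype="bandpass", output="sos", fs=fs)


def _narrowband_source(rng: np.random.Generator, band, fs: float,
                       n_samples: int, n_trials: int) -> np.ndarray:
    """Unit-variance (per trial) band-limited noise, (n_samples, n_trials)."""
    sos = _band_sos(band, fs)
    white = rng.standard_normal((n_trials, n_samples))
    src = signal.sosfiltfilt(sos, white, axis=1)
    sd = src.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (src / sd).T


def generate_epochs(
    design: StudyDesign,
    couplings: Sequence[CouplingSpec] = (),
    noise_sd: float = 10.0,
    source_amp_uv: float = 10.0,
) -> Dict[Tuple[int, int], EpochSet]:
    """Generate raw epochs for every subject and session.

    Returns a dict keyed by ``(subject, session)`` (1-based) of
    :class:`EpochSet` in microvolts, each epoch spanning
    ``[-baseline_duration, epoch_duration]`` around the memory-array onset.
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd}")
    # resolve labels up front so a bad spec fails before any simulation
    edges_idx = [
        (design.channel_index(a), design.channel_index(b))
        for a, b in (c.edge for c in couplings)
    ]
    fs = design.sampling_rate
    n_samp = design.n_retention_samples + design.n_baseline_samples
    window = (-design.baseline_duration, design.epoch_duration)
    out: Dict[Tuple[int, int], EpochSet] = {}
    for subject in range(1, design.n_subjects + 1):
        # per-subject weight offsets, shared by both sessions (a subject
        # random effect on synchronization strength)
        subj_rng = _rng(design.seed, _STREAM_SUBJECT, subject)
        offsets = [subj_rng.normal(0.0, c.subject_sd) for c in couplings]
        for session in range(1, design.n_sessions + 1):
            rng = _rng(design.seed, _STREAM_EPOCHS, subject, session)
            data = noise_sd * rng.standard_normal(
                (design.n_channels, n_samp, design.n_trials_per_session)
            )
            for c, (ia, ib), off in zip(couplings, edges_idx, offsets):
                w = float(np.clip(c.weight(session) + off, 0.0, 1.0))
                src = _narrowband_source(
                    rng, c.band, fs, n_samp, design.n_trials_per_session
                )
                data[ia] += w * source_amp_uv * src
                data[ib] += w * source_amp_uv * src
            out[(subject, session)] = EpochSet(
                data=data,
                channel_labels=list(design.channel_labels),
                sampling_rate=fs,
                epoch_window=window,
            )
    return out


def generate_behavior(design: StudyDesign, spec: BehaviorSpec):
    """Trial-level behavioral table for every subject and session.

    Returns a pandas DataFrame with columns
    ``subject, session, trial, racc, t_i, mt``: Bernoulli accuracy with the
    session's probability and truncated-normal latencies in (0, MT].
    """
    import pandas as pd

    rows = []
    for subject in range(1, design.n_subjects + 1):
        for session in range(1, design.n_sessions + 1):
            rng = _rng(design.seed, _STREAM_BEHAVIOR, subject, session)
            n = design.n_trials_per_session
            racc = (rng.random(n) < spec.accuracy(session)).astype(int)
            mu, sd, mt = spec.rt_mean(session), spec.rt_sd, spec.max_time
            if sd == 0:
                lat = np.full(n, mu)
            else:
                a, b = (0.0 - mu) / sd, (mt - mu) / sd
                lat = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                          size=n, random_state=rng)
            for t in range(n):
                rows.append(
                    dict(subject=subject, session=session, trial=t + 1,
                         racc=int(racc[t]), t_i=float(lat[t]), mt=mt)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic coherence calibration


def expected_band_coherence(
    weight: float,
    band,
    fs: float,
    welch_window_s: float = 1.0,
    noise_sd: float = 10.0,
    source_amp_uv: float = 10.0,
) -> float:
    """Expected band-averaged squared coherence on a coupled edge.

    Evaluates C^2(f) = (r S / (r S + N))^2 on the Welch frequency grid with
    r = (weight * source_amp_uv / noise_sd)^2, and averages over the in-band
    bins; S is the forward-backward Butterworth response of the source
    (|H|^4, unit-variance normalized) and N the flat density of the
    channels' own unit noise.
    """
    b = get_band(band)
    sos = _band_sos(band, fs)
    # normalization of the source PSD to unit variance: mean of |H|^4 over
    # a dense grid approximates the integral of the two-sided density
    dense = np.linspace(0, fs / 2, 4097)
    _, h = signal.sosfreqz(sos, worN=dense, fs=fs)
    g = np.abs(h) ** 4
    norm = g.mean()  # one-sided mean == two-sided mean by symmetry
    nper = round(welch_window_s * fs)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    _, hb = signal.sosfreqz(sos, worN=freqs, fs=fs)
    S = (np.abs(hb) ** 4) / norm  # source density relative to flat noise
    in_band = (freqs >= b.f_low) & (freqs <= b.f_high)
    r = (weight * source_amp_uv / noise_sd) ** 2
    rS = r * S[in_band]
    c2 = (rS / (rS + 1.0)) ** 2
    return float(c2.mean())


def weight_for_coherence(
    target_c2: float,
    band,
    fs: float,
    welch_window_s: float = 1.0,
    noise_sd: float = 10.0,
    source_amp_uv: float = 10.0,
) -> float:
    """Mixing weight whose expected band coherence equals ``target_c2``."""
    if not (0 <= target_c2 < 1):
        raise ValueError("target coherence must lie in [0, 1)")
    if target_c2 == 0:
        return 0.0
    args = (band, fs, welch_window_s, noise_sd, source_amp_uv)
    hi = expected_band_coherence(1.0, *args)
    if target_c2 >= hi:
        raise ValueError(
            f"target coherence {target_c2} unreachable; weight 1 gives {hi:.3f}"
        )
    return float(
        optimize.brentq(
            lambda w: expected_band_coherence(w, *args) - target_c2,
            0.0,
            1.0,
            xtol=1e-6,
        )
    )
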
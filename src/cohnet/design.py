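"""Study-design descriptions: montage, sessions, couplings, behavior.

These dataclasses describe the two-session working-memory study layout that
the synthetic generator emulates: 20 subjects, 60 trials per session, a
19-electrode 10-20 montage, and 3-second retention epochs.  Couplings encode
band-limited shared-source synchronization between electrode pairs whose
strength may differ between sessions (the training effect the differential
network is built to detect).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

#: The 19-electrode 10-20 montage used as network nodes, in scalp order.
CHANNELS_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


#: Canonical analysis bands; "full" is the preprocessing passband.
BANDS = {
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "full": BandDefinition("full", 0.5, 45.0),
}


def get_band(band: "str | BandDefinition") -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {sorted(BANDS)}"
        ) from None


@dataclass(frozen=True)
class StudyDesign:
    """Layout of the two-session study the generator emulates.

    ``epoch_duration`` is the retention period in seconds; a short
    pre-stimulus baseline (``baseline_duration``) precedes it in the raw
    generated epochs so that baseline correction and retention extraction
    are exercised downstream.
    """

    n_subjects: int = 20
    n_sessions: int = 2
    n_trials_per_session: int = 60
    channel_labels: Sequence[str] = CHANNELS_10_20
    epoch_duration: float = 3.0
    baseline_duration: float = 0.1
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1 or self.n_trials_per_session < 1:
            raise ValueError("subject/session/trial counts must be >= 1")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n_samples = self.epoch_duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError(
                f"epoch_duration * sampling_rate = {n_samples} is not a whole "
                "number of samples"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_retention_samples(self) -> int:
        return round(self.epoch_duration * self.sampling_rate)

    @property
    def n_baseline_samples(self) -> int:
        return round(self.baseline_duration * self.sampling_rate)

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel label {label!r}; montage: {list(self.channel_labels)}"
            ) from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        return d


@dataclass(frozen=True)
class CouplingSpec:
    """Band-limited shared-source coupling on one electrode pair.

    The two channels of ``edge`` each receive ``weight * source`` on top of
    their own broadband noise, where the source is unit-variance noise
    band-passed to ``band``.  ``coupling_session1/2`` are the session mixing
    weights; ``subject_sd`` perturbs the weight per subject (and session),
    modelling between-subject variability in synchronization strength.
    """

    band: str
    edge: tuple
    coupling_session1: float
    coupling_session2: float
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.edge
        if a == b:
            raise ValueError(f"coupling edge endpoints must differ, got ({a}, {b})")
        for w in (self.coupling_session1, self.coupling_session2):
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"mixing weight {w} outside [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be nonnegative")
        get_band(self.band)

    def weight(self, session: int) -> float:
        """Session mixing weight; sessions are numbered 1 and 2."""
        return (self.coupling_session1, self.coupling_session2)[session - 1]


@dataclass(frozen=True)
class BehaviorSpec:
    """Session-level behavioral distributions for the delayed-match task.

    ``max_time`` is MT, the maximum allowed reaction latency entering the
    signed-residual-time score; latencies are truncated-normal in (0, MT].
    """

    accuracy_session1: float = 0.7
    accuracy_session2: float = 0.9
    rt_mean_session1: float = 1.0
    rt_mean_session2: float = 0.8
    rt_sd: float = 0.25
    max_time: float = 2.0

    def __post_init__(self) -> None:
        for p in (self.accuracy_session1, self.accuracy_session2):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"accuracy probability {p} outside [0, 1]")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be nonnegative")
        for m in (self.rt_mean_session1, self.rt_mean_session2):
            if not (0 < m < self.max_time):
                raise ValueError(
                    f"rt mean {m} must lie in (0, max_time={self.max_time})"
                )

    def accuracy(self, session: int) -> float:
        return (self.accuracy_session1, self.accuracy_session2)[session - 1]

    def rt_mean(self, session: int) -> float:
        return (self.rt_mean_session1, self.rt_mean_session2)[session - 1]
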
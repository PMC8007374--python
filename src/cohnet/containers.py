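"""In-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np


@dataclass
class EpochSet:
    """One subject/session's epoched multichannel recording.

    data: (n_channels, n_samples, n_trials) array in microvolts.
    epoch_window: (start_s, end_s) of each epoch relative to the alignment
    event (memory-array onset), so sample k sits at start_s + k / fs.
    """

    data: np.ndarray
    channel_labels: Sequence[str]
    sampling_rate: float
    epoch_window: Tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"epoch data must be (channels, samples, trials), got shape "
                f"{self.data.shape}"
            )
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if self.data.shape[2] < 1:
            raise ValueError("EpochSet needs at least one trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        start, end = self.epoch_window
        n = round((end - start) * self.sampling_rate)
        if n != self.n_samples:
            raise ValueError(
                f"epoch_window {self.epoch_window} spans {n} samples at "
                f"{self.sampling_rate} Hz but data has {self.n_samples}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        start, _ = self.epoch_window
        return start + np.arange(self.n_samples) / self.sampling_rate

    def with_data(self, data: np.ndarray, **kwargs) -> "EpochSet":
        """Copy of self with new data (and optionally other fields)."""
        out = replace(self, data=data, **kwargs)
        return out

    def copy(self) -> "EpochSet":
        return self.with_data(self.data.copy())


@dataclass
class CoherenceMatrix:
    """Symmetric node x node matrix of band-averaged squared coherence."""

    values: np.ndarray
    band: object  # BandDefinition
    node_labels: Sequence[str]
    n_trials_used: int
    welch_params: Tuple[float, float, str]  # (window_s, overlap_fraction, window_shape)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.node_labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("coherence matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("coherence values must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle coherence values as a flat vector."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


@dataclass
class BinaryNetwork:
    """Undirected unweighted network over the montage nodes."""

    adjacency: np.ndarray
    node_labels: Sequence[str]
    threshold_used: float
    isolated_nodes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.node_labels)
        if a.shape != (n, n):
            raise ValueError(f"adjacency shape {a.shape} does not match {n} labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)


@dataclass
class NetworkMetrics:
    """The graph-property panel of one binary network.

    Lp: mean shortest hop distance over reachable ordered pairs.
    Eg: global efficiency (mean inverse distance, 1/inf = 0).
    CC: mean nodal clustering coefficient.
    Eloc: mean nodal local efficiency.
    Deg: mean node degree.
    gamma/lambda_/sigma: small-world normalizations against degree-matched
    randomized networks (sigma = gamma / lambda).
    """

    Lp: float
    Eg: float
    CC: float
    Eloc: float
    Deg: float
    gamma: float = float("nan")
    lambda_: float = float("nan")
    sigma: float = float("nan")
    n_random: int = 0
    random_seed: Optional[int] = None
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "Lp": self.Lp, "Eg": self.Eg, "CC": self.CC, "Eloc": self.Eloc,
            "Deg": self.Deg, "gamma": self.gamma, "lambda": self.lambda_,
            "sigma": self.sigma, "n_random": self.n_random,
            "random_seed": self.random_seed,
            "n_unreachable_pairs": self.n_unreachable_pairs,
        }


@dataclass
class DifferentialNetwork:
    """Edge-wise paired-test results between two sessions.

    ``significant`` marks edges whose coherence differs between sessions
    after FDR correction; ``hubs`` are high-degree nodes of that network.
    """

    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    node_labels: Sequence[str]
    alpha_level: float
    band: str
    fdr_method: str
    hub_cutoff: float = float("nan")
    hubs: Tuple[str, ...] = ()

    @property
    def node_degrees(self) -> np.ndarray:
        return self.significant.sum(axis=0)

    @property
    def n_significant_edges(self) -> int:
        return int(self.significant.sum()) // 2

    def significant_edges(self) -> list:
        """Significant edges as sorted (label_a, label_b) pairs."""
        labels = list(self.node_labels)
        iu = np.triu_indices(len(labels), k=1)
        out = []
        for i, j in zip(*iu):
            if self.significant[i, j]:
                out.append((labels[i], labels[j]))
        return out
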
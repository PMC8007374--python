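"""Binary-network construction and graph-theoretic properties.

A coherence matrix is binarized by a threshold: edge present iff coherence
>= threshold.  The automatic rule is the *maximum threshold that leaves no
node isolated*, which equals the minimum over nodes of each node's best
off-diagonal coherence.  The property panel is:

- Lp  : mean shortest hop distance over reachable ordered pairs
        (n_unreachable_pairs is reported when the network is disconnected);
- Eg  : global efficiency, mean of 1/d over all ordered pairs (1/inf = 0);
- CC  : mean nodal clustering coefficient, C_a = 2 e_a / (k_a (k_a - 1)),
        0 when k_a < 2;
- Eloc: mean nodal local efficiency (global efficiency of each node's
        neighbour-induced subgraph, the node itself removed);
- Deg : mean node degree;
- small-world normalization: gamma = CC / <CC_random>,
  lambda = Lp / <Lp_random>, sigma = gamma / lambda, with the null ensemble
  built by Maslov-Sneppen degree-preserving edge swaps.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple, Union

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BinaryNetwork, CoherenceMatrix, NetworkMetrics


def auto_threshold(matrix: CoherenceMatrix) -> float:
    """Largest threshold leaving no node isolated.

    A node stays connected at threshold t iff its best off-diagonal
    coherence is >= t, so the answer is the minimum over nodes of each
    node's row maximum.
    """
    v = matrix.values.copy()
    np.fill_diagonal(v, -np.inf)
    return float(v.max(axis=1).min())


def binarize(
    matrix: CoherenceMatrix, threshold: Union[float, str] = "auto"
) -> BinaryNetwork:
    """Threshold a coherence matrix into an undirected binary network.

    With ``threshold='auto'`` no node can end up isolated; an explicit
    threshold that isolates nodes triggers a warning and the isolated nodes
    are listed on the result.
    """
    if threshold == "auto":
        thr = auto_threshold(matrix)
    else:
        thr = float(threshold)
    adj = (matrix.values >= thr).astype(int)
    np.fill_diagonal(adj, 0)
    degrees = adj.sum(axis=0)
    isolated = tuple(
        str(matrix.node_labels[i]) for i in np.flatnonzero(degrees == 0)
    )
    if isolated:
        warnings.warn(
            f"threshold {thr} isolates nodes {isolated}; the maximum "
            "threshold without isolated nodes would be "
            f"{auto_threshold(matrix)}",
            stacklevel=2,
        )
    return BinaryNetwork(
        adjacency=adj, node_labels=list(matrix.node_labels),
        threshold_used=thr, isolated_nodes=isolated,
    )


def _graph(net: BinaryNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.adjacency)
    return g


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """Hop-count matrix over all node pairs; inf where unreachable."""
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(_graph(net)):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def optimal_path_length(net: BinaryNetwork) -> Tuple[float, int]:
    """(Lp, n_unreachable_pairs): mean hop distance over reachable ordered pairs.

    Unreachable ordered pairs are excluded from the mean and counted
    separately, keeping disconnection visible rather than silently folded in.
    """
    if net.n_edges == 0:
        raise ValueError("path length undefined for an edgeless network")
    d = shortest_paths(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreach = int((~np.isfinite(d) & off).sum())
    return float(d[finite].mean()), n_unreach


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d over all ordered distinct pairs, with 1/inf = 0."""
    d = shortest_paths(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def clustering(net: BinaryNetwork) -> Tuple[np.ndarray, float]:
    """(per-node C_a, network CC); C_a = 0 for nodes of degree < 2."""
    per = nx.clustering(_graph(net))
    c = np.array([per[i] for i in range(net.n_nodes)])
    return c, float(c.mean())


def local_efficiency(net: BinaryNetwork) -> Tuple[np.ndarray, float]:
    """(per-node Eloc_a, network Eloc).

    Eloc_a is the global efficiency of the subgraph induced by a's
    neighbours (a itself removed); 0 when a has fewer than 2 neighbours.
    """
    g = _graph(net)
    adj = net.adjacency
    out = np.zeros(net.n_nodes)
    for a in range(net.n_nodes):
        nbrs = np.flatnonzero(adj[a])
        k = len(nbrs)
        if k < 2:
            continue
        sub = g.subgraph(nbrs)
        inv_sum = 0.0
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, dist in lengths.items():
                if dst != src:
                    inv_sum += 1.0 / dist
        out[a] = inv_sum / (k * (k - 1))
    return out, float(out.mean())


def degree(net: BinaryNetwork) -> Tuple[np.ndarray, float]:
    """(per-node degree, network mean degree)."""
    deg = net.degrees()
    return deg, float(deg.mean())


# ---------------------------------------------------------------------------
# degree-preserving null ensemble


def rewire_degree_preserving(
    net: BinaryNetwork,
    rng: np.random.Generator,
    swap_factor: int = 10,
    max_attempt_factor: int = 100,
) -> BinaryNetwork:
    """One Maslov-Sneppen randomization of the network.

    Attempts pair swaps (a-b, c-d) -> (a-d, c-b) until ``swap_factor * m``
    swaps succeed or the attempt budget ``max_attempt_factor * m`` runs out
    (on graphs with no valid swap, e.g. complete graphs, the original
    network is returned unchanged — the only degree-preserving null there).
    """
    adj = net.adjacency.copy()
    edges = np.argwhere(np.triu(adj, k=1))
    m = len(edges)
    if m < 2:
        return BinaryNetwork(adj, list(net.node_labels), net.threshold_used)
    edges = [tuple(e) for e in edges]
    target, budget = swap_factor * m, max_attempt_factor * m
    done = attempts = 0
    while done < target and attempts < budget:
        attempts += 1
        i, j = rng.integers(0, m), rng.integers(0, m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    return BinaryNetwork(adj, list(net.node_labels), net.threshold_used)


def small_world(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: Optional[int] = None,
) -> Tuple[float, float, float]:
    """(gamma, lambda, sigma) against a degree-preserving random ensemble.

    gamma = CC / mean CC_random, lambda = Lp / mean Lp_random,
    sigma = gamma / lambda.  When the null ensemble's mean CC is 0 (trees
    and other triangle-free degree sequences) gamma is NaN and flagged by
    a warning.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    _, cc_real = clustering(net)
    lp_real, _ = optimal_path_length(net)
    cc_rand, lp_rand = [], []
    for _ in range(n_random):
        null = rewire_degree_preserving(net, rng)
        assert np.array_equal(null.degrees(), net.degrees())
        _, cc = clustering(null)
        lp, _ = optimal_path_length(null)
        cc_rand.append(cc)
        lp_rand.append(lp)
    mean_cc, mean_lp = float(np.mean(cc_rand)), float(np.mean(lp_rand))
    if mean_cc == 0:
        warnings.warn("null ensemble has zero clustering; gamma undefined",
                      stacklevel=2)
        gamma = float("nan")
    else:
        gamma = cc_real / mean_cc
    lam = lp_real / mean_lp
    sigma = gamma / lam
    return gamma, lam, sigma


def metrics_suite(
    matrix: CoherenceMatrix,
    threshold: Union[float, str] = "auto",
    n_random: int = 100,
    seed: Optional[int] = None,
) -> NetworkMetrics:
    """Binarize and compute the full property panel for one matrix."""
    net = binarize(matrix, threshold)
    return network_metrics(net, n_random=n_random, seed=seed)


def network_metrics(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: Optional[int] = None,
) -> NetworkMetrics:
    lp, n_unreach = optimal_path_length(net)
    eg = global_efficiency(net)
    _, cc = clustering(net)
    _, eloc = local_efficiency(net)
    _, deg = degree(net)
    gamma, lam, sigma = small_world(net, n_random=n_random, seed=seed)
    return NetworkMetrics(
        Lp=lp, Eg=eg, CC=cc, Eloc=eloc, Deg=deg,
        gamma=gamma, lambda_=lam, sigma=sigma,
        n_random=n_random, random_seed=seed, n_unreachable_pairs=n_unreach,
    )


class NetworkBinarizer(TransformerMixin, BaseEstimator):
    """Transformer: CoherenceMatrix -> BinaryNetwork."""

    def __init__(self, threshold: Union[float, str] = "auto"):
        self.threshold = threshold

    def fit(self, X: CoherenceMatrix, y=None):
        if not isinstance(X, CoherenceMatrix):
            raise TypeError(f"expected CoherenceMatrix, got {type(X).__name__}")
        self.threshold_ = (
            auto_threshold(X) if self.threshold == "auto" else float(self.threshold)
        )
        return self

    def transform(self, X: CoherenceMatrix) -> BinaryNetwork:
        return binarize(X, self.threshold)


class GraphMetrics(TransformerMixin, BaseEstimator):
    """Transformer: CoherenceMatrix -> NetworkMetrics (via binarization)."""

    def __init__(
        self,
        threshold: Union[float, str] = "auto",
        n_random: int = 100,
        seed: Optional[int] = None,
    ):
        self.threshold = threshold
        self.n_random = n_random
        self.seed = seed

    def fit(self, X: CoherenceMatrix, y=None):
        if not isinstance(X, CoherenceMatrix):
            raise TypeError(f"expected CoherenceMatrix, got {type(X).__name__}")
        return self

    def transform(self, X: CoherenceMatrix) -> NetworkMetrics:
        return metrics_suite(X, self.threshold, self.n_random, self.seed)
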
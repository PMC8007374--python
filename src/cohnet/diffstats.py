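"""Differential networks: edge-wise paired tests, FDR, hubs.

For each of the n(n-1)/2 unordered electrode pairs, the subjects'
session-1 and session-2 coherence values are compared with a two-sided
paired t-test; Benjamini-Hochberg FDR correction over the per-band edge
family (171 edges for the 19-node montage) then defines the binary
differential network: edge present iff the coherence change is significant.
Hub nodes of that network are identified from its degree sequence; the
default rule flags nodes whose degree is at least ``mean + hub_sd_factor *
SD`` of the degree distribution (factor 1.0 by default, configurable, or an
explicit degree cutoff).

The same paired-test machinery serves the session comparison of scalar
network properties (Lp, Eg, CC, Eloc, Deg, sigma) and of behavioral
summaries.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CoherenceMatrix, DifferentialNetwork


def _aligned_stack(
    session1: Dict, session2: Dict
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Stack per-subject coherence matrices into (n_subjects, n, n) arrays."""
    s1, s2 = dict(session1), dict(session2)
    if set(s1) != set(s2):
        only1 = sorted(set(s1) - set(s2))
        only2 = sorted(set(s2) - set(s1))
        raise ValueError(
            f"subject mismatch between sessions: only in session 1: {only1}; "
            f"only in session 2: {only2}"
        )
    subjects = sorted(s1)
    if len(subjects) < 3:
        raise ValueError(
            f"paired test needs at least 3 subjects, got {len(subjects)}"
        )
    labels = list(s1[subjects[0]].node_labels)
    for key in subjects:
        for s in (s1, s2):
            if list(s[key].node_labels) != labels:
                raise ValueError(
                    f"node labels of subject {key} differ from the first subject"
                )
    a = np.stack([s1[k].values for k in subjects])
    b = np.stack([s2[k].values for k in subjects])
    return a, b, labels


def edgewise_paired_test(
    session1: Dict, session2: Dict
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Two-sided paired t per edge across subjects.

    ``session1``/``session2`` map subject ids to CoherenceMatrix.  Returns
    symmetric (t, p) matrices (diagonal 0 and 1 respectively) and the node
    labels.  Edges with zero difference variance get p = 1 with a warning.
    """
    a, b, labels = _aligned_stack(session1, session2)
    n = len(labels)
    tmat = np.zeros((n, n))
    pmat = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    diffs = b[:, iu[0], iu[1]] - a[:, iu[0], iu[1]]  # (subjects, edges)
    zero_var = diffs.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} edge(s) have zero difference variance; "
            "their p-values are set to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(b[:, iu[0], iu[1]], a[:, iu[0], iu[1]], axis=0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, 1.0, p)
    tmat[iu] = t
    pmat[iu] = p
    tmat += tmat.T
    pmat[(iu[1], iu[0])] = p
    return tmat, pmat, labels


def fdr_correct(
    p_matrix: np.ndarray, alpha_level: float = 0.05, method: str = "bh"
) -> np.ndarray:
    """FDR decisions over the unique-edge family; returns a 0/1 adjacency.

    ``method``: 'bh' (Benjamini-Hochberg, default) or 'by'
    (Benjamini-Yekutieli).
    """
    p_matrix = np.asarray(p_matrix, float)
    if np.any(p_matrix < 0) or np.any(p_matrix > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method.lower()]
    reject, *_ = multipletests(p_matrix[iu], alpha=alpha_level, method=sm_method)
    adj = np.zeros((n, n), dtype=int)
    adj[iu] = reject.astype(int)
    adj += adj.T
    return adj


def identify_hubs(
    degrees: np.ndarray,
    node_labels: Sequence[str],
    rule: Union[str, float] = "sd",
    hub_sd_factor: float = 1.0,
) -> Tuple[Tuple[str, ...], float]:
    """High-degree nodes of a differential network.

    ``rule='sd'``: hub iff degree >= mean + hub_sd_factor * SD (sample SD);
    a numeric ``rule`` is used directly as the degree cutoff.  Returns the
    hub labels (montage order) and the cutoff used.  An edgeless network
    has no hubs.
    """
    degrees = np.asarray(degrees, float)
    if degrees.sum() == 0:
        return (), float("inf")
    if rule == "sd":
        sd = degrees.std(ddof=1) if len(degrees) > 1 else 0.0
        cutoff = float(degrees.mean() + hub_sd_factor * sd)
        if sd == 0:  # all degrees equal: nothing stands out
            return (), cutoff
    else:
        cutoff = float(rule)
    hubs = tuple(
        str(node_labels[i]) for i in np.flatnonzero(degrees >= cutoff)
    )
    return hubs, cutoff


def differential_network(
    session1: Dict,
    session2: Dict,
    band: str,
    alpha_level: float = 0.05,
    fdr_method: str = "bh",
    hub_rule: Union[str, float] = "sd",
    hub_sd_factor: float = 1.0,
) -> DifferentialNetwork:
    """Full differential-network construction for one band."""
    tmat, pmat, labels = edgewise_paired_test(session1, session2)
    adj = fdr_correct(pmat, alpha_level, fdr_method)
    hubs, cutoff = identify_hubs(adj.sum(axis=0), labels, hub_rule, hub_sd_factor)
    return DifferentialNetwork(
        t_values=tmat, p_values=pmat, significant=adj, node_labels=labels,
        alpha_level=alpha_level, band=str(band), fdr_method=fdr_method,
        hub_cutoff=cutoff, hubs=hubs,
    )


def network_property_tests(
    metrics_session1: Dict, metrics_session2: Dict
) -> pd.DataFrame:
    """Paired t-test per network property between sessions.

    ``metrics_session*`` map subject ids to NetworkMetrics (or dicts of
    scalars).  Returns a tidy frame with one row per property:
    mean_session1, mean_session2, t, p, n_subjects.
    """
    s1, s2 = dict(metrics_session1), dict(metrics_session2)
    if set(s1) != set(s2):
        raise ValueError(
            f"subject mismatch: {sorted(set(s1) ^ set(s2))} not in both sessions"
        )
    subjects = sorted(s1)
    if len(subjects) < 3:
        raise ValueError("paired test needs at least 3 subjects")

    def as_dict(m):
        return m.as_dict() if hasattr(m, "as_dict") else dict(m)

    keys = [k for k, v in as_dict(s1[subjects[0]]).items()
            if isinstance(v, (int, float)) and k not in
            ("n_random", "random_seed", "n_unreachable_pairs")]
    rows = []
    for key in keys:
        x1 = np.array([as_dict(s1[s])[key] for s in subjects], float)
        x2 = np.array([as_dict(s2[s])[key] for s in subjects], float)
        ok = np.isfinite(x1) & np.isfinite(x2)
        if ok.sum() < 3:
            continue
        if np.std(x2[ok] - x1[ok]) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x2[ok], x1[ok])
        rows.append(dict(
            metric=key, mean_session1=float(x1[ok].mean()),
            mean_session2=float(x2[ok].mean()), t=float(t), p=float(p),
            n_subjects=int(ok.sum()),
        ))
    return pd.DataFrame(rows)


class PairedCoherenceTest(BaseEstimator):
    """Estimator: fit on two per-subject coherence collections.

    Fitted attributes: ``t_values_``, ``p_values_``, ``significant_``,
    ``node_degrees_``, ``hubs_``, ``hub_cutoff_``, ``network_``.
    """

    def __init__(
        self,
        band: str = "full",
        alpha_level: float = 0.05,
        fdr_method: str = "bh",
        hub_rule: Union[str, float] = "sd",
        hub_sd_factor: float = 1.0,
    ):
        self.band = band
        self.alpha_level = alpha_level
        self.fdr_method = fdr_method
        self.hub_rule = hub_rule
        self.hub_sd_factor = hub_sd_factor

    def fit(self, X: Tuple[Dict, Dict], y=None):
        session1, session2 = X
        net = differential_network(
            session1, session2, self.band, self.alpha_level,
            self.fdr_method, self.hub_rule, self.hub_sd_factor,
        )
        self.network_ = net
        self.t_values_ = net.t_values
        self.p_values_ = net.p_values
        self.significant_ = net.significant
        self.node_degrees_ = net.node_degrees
        self.hubs_ = net.hubs
        self.hub_cutoff_ = net.hub_cutoff
        return self
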
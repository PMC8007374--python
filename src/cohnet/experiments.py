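"""Study-level validation experiments.

These functions run the pipeline's statistical machinery on full synthetic
studies and measure its operating characteristics: edge-recovery
sensitivity and false positives of the differential network, and type-I
error calibration under a matched null.  They are what the acceptance
checks and the reproduction script execute.

``STUDY_DIFFNET_DEGREES`` holds the published node-degree columns of the
three band differential networks from the working-memory training study
this package models; it is the in-paper worked input for the degree-based
hub rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .coherence import coherence_matrix
from .design import CHANNELS_10_20, CouplingSpec, StudyDesign
from .diffstats import differential_network, identify_hubs
from .simulate import generate_epochs, weight_for_coherence

#: Published node degrees of the theta/alpha/beta differential networks
#: (19-channel 10-20 montage, same node order as CHANNELS_10_20).
STUDY_DIFFNET_DEGREES = {
    "theta": (7, 6, 1, 10, 15, 12, 4, 5, 5, 2, 2, 5, 4, 4, 6, 2, 5, 2, 3),
    "alpha": (1, 13, 6, 7, 7, 4, 3, 4, 6, 6, 7, 1, 11, 9, 8, 3, 15, 12, 12),
    "beta": (5, 4, 4, 8, 4, 5, 10, 8, 6, 4, 9, 7, 8, 7, 5, 6, 5, 1, 2),
}

#: Hub sets the study reports for those networks.
STUDY_HUBS = {
    "theta": {"F3", "Fz", "F4"},
    "alpha": {"Fp2", "P7", "P3", "Pz", "P8", "O1", "O2"},
    "beta": {"F3", "F8", "T7", "C4", "T8", "P7", "P3"},
}

#: Five node-disjoint edges carrying the training effect in the recovery study.
RECOVERY_EDGES = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("T7", "C3"), ("P3", "P4"), ("O1", "O2"),
)


def hub_rule_on_published_degrees(hub_sd_factor: float = 1.0) -> Dict[str, dict]:
    """Apply the degree-based hub rule to the published degree columns.

    Returns, per band, the hub set the rule yields, the cutoff, and whether
    it matches the study's stated hub set.
    """
    out = {}
    for band, degrees in STUDY_DIFFNET_DEGREES.items():
        hubs, cutoff = identify_hubs(
            np.array(degrees), CHANNELS_10_20, "sd", hub_sd_factor
        )
        out[band] = {
            "hubs": sorted(hubs),
            "cutoff": cutoff,
            "expected": sorted(STUDY_HUBS[band]),
            "matches": set(hubs) == STUDY_HUBS[band],
        }
    return out


def _recovery_design(seed: int, n_subjects: int = 20, n_trials: int = 20,
                     sampling_rate: float = 250.0) -> StudyDesign:
    return StudyDesign(
        n_subjects=n_subjects, n_sessions=2, n_trials_per_session=n_trials,
        sampling_rate=sampling_rate, seed=seed,
    )


def recovery_couplings(
    band: str = "alpha",
    c2_session1: float = 0.20,
    c2_session2: float = 0.35,
    subject_sd: float = 0.05,
    sampling_rate: float = 250.0,
    null: bool = False,
) -> Tuple[CouplingSpec, ...]:
    """Couplings putting a coherence increase of c2_session2 - c2_session1
    on the five designated edges (equal weights in both sessions if null)."""
    w1 = weight_for_coherence(c2_session1, band, sampling_rate)
    w2 = w1 if null else weight_for_coherence(c2_session2, band, sampling_rate)
    return tuple(
        CouplingSpec(band=band, edge=e, coupling_session1=w1,
                     coupling_session2=w2, subject_sd=subject_sd)
        for e in RECOVERY_EDGES
    )


def _band_matrices(design: StudyDesign, couplings, noise_sd: float, band: str):
    """Per-subject session-1 and session-2 coherence matrices (no artifacts,
    so the preprocessing stage is bypassed for speed)."""
    epochs = generate_epochs(design, couplings, noise_sd)
    c1, c2 = {}, {}
    for (subject, session), ep in epochs.items():
        mat = coherence_matrix(ep, band)
        (c1 if session == 1 else c2)[subject] = mat
    return c1, c2


@dataclass
class RecoveryResult:
    sensitivity: float
    mean_false_edges: float
    n_runs: int
    per_run_true_positives: list
    per_run_false_positives: list


def differential_recovery(
    seed: int,
    n_runs: int = 50,
    band: str = "alpha",
    c2_session1: float = 0.20,
    c2_session2: float = 0.35,
    subject_sd: float = 0.05,
    n_subjects: int = 20,
    n_trials: int = 20,
    sampling_rate: float = 250.0,
    alpha_level: float = 0.05,
) -> RecoveryResult:
    """Edge recovery of the differential network across seeded runs.

    Sensitivity is the fraction of designated edges detected, averaged over
    runs; false edges are significant edges outside the designated set.
    """
    couplings = recovery_couplings(band, c2_session1, c2_session2,
                                   subject_sd, sampling_rate)
    true_set = {frozenset(e) for e in RECOVERY_EDGES}
    tps, fps = [], []
    for run in range(n_runs):
        design = _recovery_design(seed + run, n_subjects, n_trials, sampling_rate)
        c1, c2 = _band_matrices(design, couplings, 10.0, band)
        dn = differential_network(c1, c2, band, alpha_level)
        found = {frozenset(e) for e in dn.significant_edges()}
        tps.append(len(found & true_set))
        fps.append(len(found - true_set))
    return RecoveryResult(
        sensitivity=float(np.mean(tps)) / len(true_set),
        mean_false_edges=float(np.mean(fps)),
        n_runs=n_runs,
        per_run_true_positives=tps,
        per_run_false_positives=fps,
    )


@dataclass
class NullCalibrationResult:
    per_edge_type1_rate: float
    per_edge_se: float
    family_any_discovery_rate: float
    n_runs: int
    n_edges: int


def null_calibration(
    seed: int,
    n_runs: int = 200,
    band: str = "alpha",
    c2_both_sessions: float = 0.20,
    subject_sd: float = 0.05,
    n_subjects: int = 20,
    n_trials: int = 20,
    sampling_rate: float = 250.0,
    alpha_level: float = 0.05,
) -> NullCalibrationResult:
    """Type-I calibration under a matched null (equal couplings per session).

    Measures the uncorrected per-edge rejection rate at the alpha level and
    the fraction of runs in which BH declares any edge significant.
    """
    couplings = recovery_couplings(band, c2_both_sessions, None, subject_sd,
                                   sampling_rate, null=True)
    per_run_rates = []
    n_family = 0
    n_edges = 0
    for run in range(n_runs):
        design = _recovery_design(seed + run, n_subjects, n_trials, sampling_rate)
        c1, c2 = _band_matrices(design, couplings, 10.0, band)
        dn = differential_network(c1, c2, band, alpha_level)
        iu = np.triu_indices(len(dn.node_labels), k=1)
        p = dn.p_values[iu]
        n_edges = p.size
        per_run_rates.append(float((p < alpha_level).mean()))
        n_family += int(dn.n_significant_edges > 0)
    rates = np.asarray(per_run_rates)
    # empirical SE of the mean rate across runs (edges within a run share
    # subjects, so the binomial SE over runs*edges would be too small)
    se = float(rates.std(ddof=1) / np.sqrt(n_runs))
    return NullCalibrationResult(
        per_edge_type1_rate=float(rates.mean()),
        per_edge_se=se,
        family_any_discovery_rate=n_family / n_runs,
        n_runs=n_runs,
        n_edges=n_edges,
    )
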
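"""End-to-end pipeline: simulate/load -> preprocess -> coherence ->
networks -> differential statistics -> behavior.

A :class:`PipelineConfig` (built directly or from a YAML/JSON mapping)
fully determines a run; the result bundle carries every intermediate
product plus a provenance manifest (config hash, master seed, package
version, and the decision flags in effect) sufficient to re-run the
pipeline identically.

All stage randomness derives from the single master seed through labeled
SeedSequence spawn keys, so e.g. changing the number of random nulls never
perturbs the generated data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_session_tests, session_summary
from .coherence import coherence_matrix
from .containers import CoherenceMatrix, DifferentialNetwork, EpochSet, NetworkMetrics
from .design import BANDS, BehaviorSpec, CouplingSpec, StudyDesign
from .diffstats import differential_network, network_property_tests
from .graph import metrics_suite
from .io import epoch_filename, read_behavior_tsv, read_epochs_tsv
from .preprocess import preprocess_epochs
from .simulate import generate_behavior, generate_epochs

_STREAM_NULLS = 4


@dataclass
class PipelineConfig:
    """Everything a run needs.  ``mode`` is 'simulate' or 'analyze'."""

    mode: str = "simulate"
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    couplings: Sequence[CouplingSpec] = ()
    behavior: Optional[BehaviorSpec] = field(default_factory=BehaviorSpec)
    noise_sd: float = 10.0
    input_dir: Optional[Path] = None
    bands: Sequence[str] = ("theta", "alpha", "beta", "full")
    diff_bands: Sequence[str] = ("theta", "alpha", "beta")
    metric_band: str = "full"
    welch: Tuple[float, float, str] = (1.0, 0.5, "hann")
    low_hz: float = 0.5
    high_hz: float = 45.0
    baseline_window: Tuple[float, float] = (-0.1, 0.0)
    reject_uv: Optional[float] = 100.0
    rereference: bool = True
    threshold: Union[float, str] = "auto"
    n_random: int = 100
    alpha_level: float = 0.05
    fdr_method: str = "bh"
    hub_rule: Union[str, float] = "sd"
    hub_sd_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"mode must be 'simulate' or 'analyze', got {self.mode!r}")
        if not self.bands:
            raise ValueError("config field 'bands' is empty: list at least one band")
        unknown = [b for b in list(self.bands) + list(self.diff_bands) if b not in BANDS]
        if unknown:
            raise ValueError(f"unknown bands {unknown}; known: {sorted(BANDS)}")
        if self.metric_band not in self.bands:
            raise ValueError(
                f"metric_band {self.metric_band!r} not among bands {list(self.bands)}"
            )
        if self.mode == "analyze" and self.input_dir is None:
            raise ValueError("analyze mode requires 'input_dir'")

    @classmethod
    def from_mapping(cls, cfg: dict, seed: Optional[int] = None) -> "PipelineConfig":
        cfg = dict(cfg)
        design_kwargs = dict(cfg.pop("design", {}))
        if seed is not None:
            design_kwargs["seed"] = seed
        elif "seed" in cfg:
            design_kwargs.setdefault("seed", cfg["seed"])
        design = StudyDesign(**design_kwargs)
        couplings = [
            CouplingSpec(band=c["band"], edge=tuple(c["edge"]),
                         coupling_session1=c["coupling_session1"],
                         coupling_session2=c["coupling_session2"],
                         subject_sd=c.get("subject_sd", 0.0))
            for c in cfg.pop("couplings", [])
        ]
        beh = cfg.pop("behavior", {})
        behavior = None if beh is None else BehaviorSpec(**beh)
        pp = cfg.pop("preprocess", {})
        net = cfg.pop("network", {})
        dn = cfg.pop("diffnet", {})
        welch = cfg.pop("welch", {})
        kwargs = dict(
            mode=cfg.pop("mode", "simulate"),
            seed=design.seed,
            design=design, couplings=couplings, behavior=behavior,
            noise_sd=cfg.pop("noise_sd", 10.0),
            bands=tuple(cfg.pop("bands", ("theta", "alpha", "beta", "full"))),
        )
        if "diff_bands" in cfg:
            kwargs["diff_bands"] = tuple(cfg.pop("diff_bands"))
        if "input_dir" in cfg:
            kwargs["input_dir"] = Path(cfg.pop("input_dir"))
        if welch:
            kwargs["welch"] = (welch.get("window_s", 1.0),
                               welch.get("overlap", 0.5),
                               welch.get("shape", "hann"))
        for src, dst in (("low_hz", "low_hz"), ("high_hz", "high_hz")):
            if src in pp:
                kwargs[dst] = pp[src]
        if "baseline" in pp:
            kwargs["baseline_window"] = tuple(pp["baseline"])
        if "reject_uv" in pp:
            kwargs["reject_uv"] = pp["reject_uv"]
        if "rereference" in pp:
            kwargs["rereference"] = pp["rereference"]
        if "threshold" in net:
            kwargs["threshold"] = net["threshold"]
        if "n_random" in net:
            kwargs["n_random"] = net["n_random"]
        for k in ("alpha_level", "hub_sd_factor"):
            if k in dn:
                kwargs[k] = dn[k]
        if "fdr" in dn:
            kwargs["fdr_method"] = dn["fdr"]
        if "hub_rule" in dn:
            kwargs["hub_rule"] = dn["hub_rule"]
        cfg.pop("seed", None)
        if cfg:
            raise ValueError(f"unknown config keys: {sorted(cfg)}")
        return cls(**kwargs)

    def manifest(self) -> dict:
        cfg = {
            "mode": self.mode, "seed": self.seed,
            "design": self.design.to_dict(),
            "couplings": [
                dict(band=c.band, edge=list(c.edge),
                     coupling_session1=c.coupling_session1,
                     coupling_session2=c.coupling_session2,
                     subject_sd=c.subject_sd)
                for c in self.couplings
            ],
            "behavior": None if self.behavior is None else vars(self.behavior),
            "noise_sd": self.noise_sd,
            "input_dir": None if self.input_dir is None else str(self.input_dir),
            "bands": list(self.bands), "diff_bands": list(self.diff_bands),
            "metric_band": self.metric_band, "welch": list(self.welch),
            "preprocess": dict(low_hz=self.low_hz, high_hz=self.high_hz,
                               baseline=list(self.baseline_window),
                               reject_uv=self.reject_uv,
                               rereference=self.rereference),
            "network": dict(threshold=self.threshold, n_random=self.n_random),
            "diffnet": dict(alpha_level=self.alpha_level, fdr=self.fdr_method,
                            hub_rule=self.hub_rule,
                            hub_sd_factor=self.hub_sd_factor),
        }
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "package_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    epochs_raw: Dict[Tuple[int, int], EpochSet]
    epochs_clean: Dict[Tuple[int, int], EpochSet]
    rejection_reports: Dict[Tuple[int, int], object]
    coherence: Dict[str, Dict[Tuple[int, int], CoherenceMatrix]]
    metrics: Dict[Tuple[int, int], NetworkMetrics]
    metric_tests: pd.DataFrame
    differential: Dict[str, DifferentialNetwork]
    behavior_trials: Optional[pd.DataFrame]
    behavior_summary: Optional[pd.DataFrame]
    behavior_tests: Optional[pd.DataFrame]
    manifest: dict


def _null_seed(master: int, subject: int, session: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(_STREAM_NULLS, subject, session))
    return int(ss.generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig):
    d = config.design
    if config.mode == "simulate":
        raw = generate_epochs(d, config.couplings, config.noise_sd)
        trials = (generate_behavior(d, config.behavior)
                  if config.behavior is not None else None)
        return raw, trials
    raw = {}
    for subject in range(1, d.n_subjects + 1):
        for session in range(1, d.n_sessions + 1):
            path = Path(config.input_dir) / epoch_filename(subject, session)
            if not path.exists():
                raise FileNotFoundError(
                    f"analyze mode: missing epoch file {path} "
                    f"(subject {subject}, session {session})"
                )
            raw[(subject, session)] = read_epochs_tsv(path)
    beh_path = Path(config.input_dir) / "behavior.tsv"
    trials = read_behavior_tsv(beh_path) if beh_path.exists() else None
    return raw, trials


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; see the module docstring for the order."""
    d = config.design
    raw, trials = _load_inputs(config)

    clean: Dict[Tuple[int, int], EpochSet] = {}
    reports: Dict[Tuple[int, int], object] = {}
    retention = (0.0, d.epoch_duration)
    for key, ep in raw.items():
        try:
            clean[key], reports[key] = preprocess_epochs(
                ep, config.low_hz, config.high_hz, config.baseline_window,
                config.reject_uv, retention, config.rereference,
            )
        except Exception as exc:
            raise RuntimeError(
                f"preprocess failed for subject {key[0]} session {key[1]}: {exc}"
            ) from exc

    coh: Dict[str, Dict[Tuple[int, int], CoherenceMatrix]] = {}
    for band in config.bands:
        coh[band] = {}
        for key, ep in clean.items():
            try:
                coh[band][key] = coherence_matrix(ep, band, config.welch)
            except Exception as exc:
                raise RuntimeError(
                    f"coherence failed for subject {key[0]} session {key[1]} "
                    f"band {band}: {exc}"
                ) from exc

    metrics: Dict[Tuple[int, int], NetworkMetrics] = {}
    for (subject, session), mat in coh[config.metric_band].items():
        metrics[(subject, session)] = metrics_suite(
            mat, config.threshold, config.n_random,
            _null_seed(config.seed, subject, session),
        )
    m1 = {s: metrics[(s, 1)] for s in range(1, d.n_subjects + 1)}
    m2 = {s: metrics[(s, 2)] for s in range(1, d.n_subjects + 1)}
    metric_tests = network_property_tests(m1, m2) if d.n_subjects >= 3 else pd.DataFrame()

    differential: Dict[str, DifferentialNetwork] = {}
    if d.n_subjects >= 3 and d.n_sessions == 2:
        for band in config.diff_bands:
            c1 = {s: coh[band][(s, 1)] for s in range(1, d.n_subjects + 1)}
            c2 = {s: coh[band][(s, 2)] for s in range(1, d.n_subjects + 1)}
            differential[band] = differential_network(
                c1, c2, band, config.alpha_level, config.fdr_method,
                config.hub_rule, config.hub_sd_factor,
            )

    summary = tests = None
    if trials is not None:
        summary = session_summary(trials)
        if d.n_sessions == 2 and d.n_subjects >= 3:
            tests = behavior_session_tests(summary)

    return PipelineResult(
        config=config, epochs_raw=raw, epochs_clean=clean,
        rejection_reports=reports, coherence=coh, metrics=metrics,
        metric_tests=metric_tests, differential=differential,
        behavior_trials=trials, behavior_summary=summary,
        behavior_tests=tests, manifest=config.manifest(),
    )


def save_results(result: PipelineResult, out_dir) -> None:
    """Write the standard text outputs of a pipeline run."""
    from .io import (dump_json, network_to_graphml, write_behavior_tsv,
                     write_edge_list, write_matrix_tsv)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_json(result.manifest, out / "manifest.json")
    for band, mats in result.coherence.items():
        for (subject, session), mat in mats.items():
            write_matrix_tsv(
                mat, out / f"coherence_sub{subject:02d}_ses{session}_{band}.tsv"
            )
    rows = []
    for (subject, session), m in result.metrics.items():
        for metric, value in m.as_dict().items():
            rows.append(dict(subject=subject, session=session,
                             band=result.config.metric_band,
                             metric=metric, value=value))
    pd.DataFrame(rows).to_csv(out / "network_metrics.tsv", sep="\t", index=False)
    if len(result.metric_tests):
        result.metric_tests.to_csv(out / "network_metric_tests.tsv",
                                   sep="\t", index=False)
    for band, dn in result.differential.items():
        pd.DataFrame(dn.t_values, index=list(dn.node_labels),
                     columns=list(dn.node_labels)).to_csv(
            out / f"diffnet_{band}_t.tsv", sep="\t", float_format="%.6f")
        pd.DataFrame(dn.p_values, index=list(dn.node_labels),
                     columns=list(dn.node_labels)).to_csv(
            out / f"diffnet_{band}_p.tsv", sep="\t", float_format="%.6g")
        write_edge_list(dn, out / f"diffnet_{band}_edges.tsv")
        network_to_graphml(dn, out / f"diffnet_{band}.graphml")
        pd.DataFrame({
            "node": list(dn.node_labels),
            "degree": dn.node_degrees,
            "hub": [int(lbl in dn.hubs) for lbl in dn.node_labels],
        }).to_csv(out / f"diffnet_{band}_degrees.tsv", sep="\t", index=False)
        dump_json({"band": band, "hubs": list(dn.hubs),
                   "hub_cutoff": dn.hub_cutoff,
                   "alpha_level": dn.alpha_level,
                   "fdr_method": dn.fdr_method},
                  out / f"diffnet_{band}_hubs.json")
    if result.behavior_trials is not None:
        write_behavior_tsv(result.behavior_trials, out / "behavior.tsv")
    if result.behavior_summary is not None:
        result.behavior_summary.to_csv(out / "behavior_summary.tsv",
                                       sep="\t", index=False)
    if result.behavior_tests is not None:
        result.behavior_tests.to_csv(out / "behavior_tests.tsv",
                                     sep="\t", index=False)
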
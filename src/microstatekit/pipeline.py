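"""One-command orchestration: cohort -> preprocessing -> segmentation ->
temporal parameters -> group statistics, with reproducibility metadata.

The whole run is controlled by one :class:`PipelineConfig` (YAML
round-trippable; study values as defaults) and one analysis seed.  A
:class:`RunManifest` records the config hash, package version, wall
clock and output checksums per stage, and the subject inclusion log, so
that a re-run with the same config and inputs can be verified to
reproduce the same artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import cohort_parameter_table, subject_parameters
from .io import (read_recording, write_labels_csv, write_prototypes_csv,
                 write_prototypes_json)
from .microstates import (backfit, compute_gfp, detect_gfp_peaks,
                          extract_peak_maps, modified_kmeans,
                          order_canonically, select_peaks, smooth_segments)
from .preprocessing import (PreprocessingParams, SubjectExcluded,
                            preprocess_recording)
from .stats import compare_all_parameters, correlate_with_smoking
from .synthetic import (GenerativeSpec, default_montage,
                        make_canonical_templates, simulate_cohort)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "SimulationStudyResult",
    "run_simulation_study",
    "run_on_recordings",
    "truth_level_statistics",
    "null_configuration",
]


@dataclass
class PipelineConfig:
    """Every stage parameter of the analysis, with the study defaults."""

    generative: GenerativeSpec = field(default_factory=GenerativeSpec)
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    n_clusters: int = 4
    n_restarts: int = 50
    max_iter: int = 1000
    tol: float = 1e-6
    min_peak_distance_ms: float = 10.0
    peak_sd_multiplier: float = 2.0
    n_peaks_per_subject: int = 1000
    min_segment_ms: float = 30.0
    analysis_seed: int = 0
    welch: bool = False
    fdr: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generative"] = self.generative.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generative" in d:
            d["generative"] = GenerativeSpec.from_dict(d["generative"])
        if "preprocessing" in d:
            d["preprocessing"] = PreprocessingParams(**d["preprocessing"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    stages: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)
    output_checksums: dict = field(default_factory=dict)

    def add_stage(self, name: str, wall_s: float, **info) -> None:
        self.stages.append({"stage": name, "wall_s": round(wall_s, 3), **info})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class SimulationStudyResult:
    config: PipelineConfig
    clinical: pd.DataFrame
    truth: object                      # GroundTruth (None for real-data runs)
    prototypes: object                 # MicrostatePrototypes
    label_sequences: dict              # subject_id -> LabelSequence (smoothed)
    kept_epochs: dict                  # subject_id -> original epoch indices kept
    parameter_table: pd.DataFrame
    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    manifest: RunManifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _segment_and_measure(epoched: dict, config: PipelineConfig, manifest: RunManifest,
                         montage_ch_names) -> tuple:
    """Shared back half: peaks -> clustering -> backfit/smooth -> parameters."""
    t0 = time.time()
    pools = []
    for i, (sid, ep) in enumerate(sorted(epoched.items())):
        g = compute_gfp(ep)
        g = detect_gfp_peaks(g, config.min_peak_distance_ms)
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=config.analysis_seed, spawn_key=(20_000 + i,)))
        g = select_peaks(g, config.peak_sd_multiplier,
                         config.n_peaks_per_subject, rng)
        pools.append(extract_peak_maps(ep, g))
    pool = np.concatenate(pools, axis=0)
    manifest.add_stage("gfp_peaks", time.time() - t0,
                       n_pool_maps=int(pool.shape[0]))

    t0 = time.time()
    protos = modified_kmeans(pool, k=config.n_clusters,
                             n_restarts=config.n_restarts,
                             max_iter=config.max_iter, tol=config.tol,
                             seed=config.analysis_seed)
    if config.n_clusters == 4:
        templates = make_canonical_templates(default_montage(montage_ch_names))
        protos = order_canonically(protos, templates)
    manifest.add_stage("modified_kmeans", time.time() - t0, gev=protos.gev,
                       iterations=protos.n_iterations_used,
                       empty_cluster_events=protos.empty_cluster_events)

    t0 = time.time()
    label_sequences = {}
    params = {}
    for sid, ep in sorted(epoched.items()):
        ls = backfit(ep, protos)
        ls = smooth_segments(ep, ls, protos, config.min_segment_ms)
        label_sequences[sid] = ls
        params[sid] = subject_parameters(ls)
    manifest.add_stage("backfit_smooth", time.time() - t0,
                       min_segment_ms=config.min_segment_ms,
                       boundary_segments="included")
    return protos, label_sequences, params


def _run_statistics(table: pd.DataFrame, clinical: pd.DataFrame,
                    config: PipelineConfig, manifest: RunManifest) -> tuple:
    t0 = time.time()
    tests = compare_all_parameters(table, welch=config.welch, fdr=config.fdr)
    corr = correlate_with_smoking(table, clinical)
    manifest.add_stage("statistics", time.time() - t0, n_tests=len(tests),
                       n_correlations=len(corr))
    return tests, corr


def _write_outputs(outdir, config, clinical, table, tests, corr, protos,
                   label_sequences, ch_names, manifest,
                   write_labels: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    files = {
        f"clinical_{tag}.csv": lambda p: clinical.to_csv(p, index=False),
        f"parameters_{tag}.csv": lambda p: table.to_csv(p, index=False),
        f"group_tests_{tag}.csv": lambda p: tests.to_csv(p, index=False),
        f"correlations_{tag}.csv": lambda p: corr.to_csv(p, index=False),
        f"prototypes_{tag}.json": lambda p: write_prototypes_json(p, protos, ch_names),
        f"prototypes_{tag}.csv": lambda p: write_prototypes_csv(p, protos, ch_names),
        f"config_{tag}.yaml": lambda p: config.to_yaml(p),
    }
    for name, writer in files.items():
        path = outdir / name
        writer(path)
        manifest.output_checksums[name] = _sha256(path)
    if write_labels:
        for sid, ls in label_sequences.items():
            path = outdir / f"labels_{sid}_{tag}.csv"
            write_labels_csv(path, ls)
            manifest.output_checksums[path.name] = _sha256(path)
    manifest.write(outdir / f"manifest_{tag}.json")


def run_simulation_study(config: Optional[PipelineConfig] = None,
                         outdir=None, write_labels: bool = False
                         ) -> SimulationStudyResult:
    """Simulate a cohort and run the full analysis chain on it.

    simulate -> preprocess -> GFP peaks -> group-level modified K-means
    -> canonical ordering -> backfit -> smoothing -> temporal parameters
    -> group tests and smoker correlations.  Fully deterministic for a
    fixed config (one generative seed, one analysis seed).
    """
    config = config or PipelineConfig()
    manifest = RunManifest(config_hash=config.config_hash())

    t0 = time.time()
    recordings, clinical, truth = simulate_cohort(config.generative)
    manifest.add_stage("simulate", time.time() - t0,
                       n_subjects=len(recordings),
                       generative_seed=config.generative.seed)

    t0 = time.time()
    epoched = {}
    kept = {}
    for sid in sorted(recordings):
        ep, _stage_log = preprocess_recording(recordings.pop(sid),
                                              config.preprocessing, sid)
        epoched[sid] = ep
        kept[sid] = list(ep.kept_indices)
    manifest.add_stage("preprocess", time.time() - t0, n_subjects=len(epoched))

    ch_names = truth.templates.montage.ch_names
    protos, label_sequences, params = _segment_and_measure(
        epoched, config, manifest, ch_names)
    table = cohort_parameter_table(params, clinical)
    tests, corr = _run_statistics(table, clinical, config, manifest)
    if outdir is not None:
        _write_outputs(outdir, config, clinical, table, tests, corr, protos,
                       label_sequences, ch_names, manifest, write_labels)
    return SimulationStudyResult(config=config, clinical=clinical, truth=truth,
                                 prototypes=protos,
                                 label_sequences=label_sequences,
                                 kept_epochs=kept, parameter_table=table,
                                 group_tests=tests, correlations=corr,
                                 manifest=manifest)


def null_configuration(spec: GenerativeSpec) -> GenerativeSpec:
    """A copy of the spec with every planted effect switched off.

    Smokers inherit the control generative parameters and the FTND
    coupling is zeroed, so group means of the true parameters are equal
    in expectation.
    """
    d = spec.to_dict()
    d["mean_duration_ms"] = {
        "control": dict(spec.mean_duration_ms["control"]),
        "smoker": dict(spec.mean_duration_ms["control"]),
    }
    d["class_entry_weights"] = {
        "control": dict(spec.class_entry_weights["control"]),
        "smoker": dict(spec.class_entry_weights["control"]),
    }
    d["covariate_coupling"] = 0.0
    return GenerativeSpec.from_dict(d)


def truth_level_statistics(spec: GenerativeSpec) -> tuple:
    """Group tests and smoker correlations on ground-truth parameters.

    Simulates only the label sequences (no EEG rendering), measures the
    temporal parameters from the true labels, and runs the full
    statistics battery.  This is the replicate-study workhorse for power
    and type-I-error evaluation of the statistics layer.
    """
    _, clinical, truth = simulate_cohort(spec, render=False)
    tests = compare_all_parameters(truth.parameters)
    corr = correlate_with_smoking(truth.parameters, clinical)
    return tests, corr


def run_on_recordings(paths, clinical_csv, config: Optional[PipelineConfig] = None,
                      outdir=None, write_labels: bool = False
                      ) -> SimulationStudyResult:
    """Run the same chain on recorded EDF/BrainVision files.

    Subject ids are the file stems.  Subjects failing the minimum-epoch
    gate are listed in the manifest and excluded from statistics; a
    subject without a clinical row is a hard error naming the subject.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(config_hash=config.config_hash())
    clinical = pd.read_csv(clinical_csv)

    t0 = time.time()
    epoched = {}
    kept = {}
    for path in paths:
        path = Path(path)
        sid = path.stem
        rec = read_recording(path)
        try:
            ep, _stage_log = preprocess_recording(rec, config.preprocessing, sid)
        except SubjectExcluded as exc:
            manifest.exclusions.append({"subject_id": sid, "reason": exc.reason})
            continue
        epoched[sid] = ep
        kept[sid] = list(ep.kept_indices)
    manifest.add_stage("preprocess", time.time() - t0, n_subjects=len(epoched),
                       n_excluded=len(manifest.exclusions))
    if not epoched:
        raise RuntimeError("no subjects survived preprocessing")

    ch_names = next(iter(epoched.values())).ch_names
    protos, label_sequences, params = _segment_and_measure(
        epoched, config, manifest, ch_names)
    table = cohort_parameter_table(params, clinical)
    tests, corr = _run_statistics(table, clinical, config, manifest)
    if outdir is not None:
        _write_outputs(outdir, config, clinical, table, tests, corr, protos,
                       label_sequences, ch_names, manifest, write_labels)
    return SimulationStudyResult(config=config, clinical=clinical, truth=None,
                                 prototypes=protos,
                                 label_sequences=label_sequences,
                                 kept_epochs=kept, parameter_table=table,
                                 group_tests=tests, correlations=corr,
                                 manifest=manifest)
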
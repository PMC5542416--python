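"""Configuration-driven end-to-end runs of the full analysis graph.

``run_pipeline`` executes, on synthetic data with known ground truth:
simulation -> artifact injection -> trial rejection & imbalance check ->
baseline normalization -> temporal smoothing -> per-subject pairwise
decoding RDMs -> factor clustering + image decoding + cross-classification
time courses -> model RDMs and (partial) RSA -> sign-permutation cluster
tests and bootstrap latency CIs, writing every artifact as CSV plus a JSON
manifest of seeds and settings. ``report`` condenses a finished run into
one latency/significance row per analysis.

Two scale profiles are bundled: ``desk`` (30 channels, 5 ms grid,
20 trials/condition, 8 subjects, reduced repetition counts) finishes in
minutes; ``full`` mirrors the recording-scale constants (306 channels,
1 ms, 60 trials, 15 subjects, 100 decoding repetitions, 1000 permutations
and bootstraps).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GroupTimeCourse
from .decoding import (
    DecodingConfig,
    cross_decoding_timecourse,
    factor_average_decoding,
    identity_cross_decoding,
    pairwise_decoding_timecourse,
)
from .design import FACTORS, generate_design
from .inference import bootstrap_latency_ci, sign_permutation_cluster_test
from .preprocessing import (
    baseline_normalize,
    reject_trials,
    rejection_imbalance_test,
    smooth_timecourse,
)
from .rsa import clustering_timecourse, factor_model_rdm, partial_rsa_timecourse, rsa_timecourse
from .simulate import EffectSpec, NoiseSpec, SignalSpec, generate_dataset, inject_artifacts
from .stimuli import generate_images

PROFILES = {
    "desk": dict(
        n_channels=30,
        step_ms=5.0,
        n_trials_per_condition=20,
        n_subjects=8,
        n_repetitions=3,
        time_decim=4,
        n_perm=200,
        n_boot=200,
    ),
    "full": dict(
        n_channels=306,
        step_ms=1.0,
        n_trials_per_condition=60,
        n_subjects=15,
        n_repetitions=100,
        time_decim=1,
        n_perm=1000,
        n_boot=1000,
    ),
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; unknown YAML keys are rejected.

    Fields left at None inherit from the selected scale profile.
    """

    profile: str = "desk"
    seed: int = 0
    n_exemplars: int = 3
    n_subjects: int | None = None
    n_channels: int | None = None
    n_trials_per_condition: int | None = None
    step_ms: float | None = None
    tmin_ms: float = -100.0
    tmax_ms: float = 900.0
    # signal / noise
    effects: list = field(default_factory=list)  # EffectSpec kwargs dicts
    pattern_seed: int = 7
    subject_jitter_sd: float = 0.2
    noise_scale: float = 100.0
    noise_cov_rank: int = 5
    noise_ar: float = 0.8
    artifact_rate: float = 0.0
    artifact_amplitude: float = 10000.0
    # preprocessing
    p2p_threshold: float = 8000.0
    baseline: tuple[float, float] = (-100.0, 0.0)
    smoothing_ms: float = 20.0
    # decoding
    k: int = 5
    cross_k: int = 60
    n_repetitions: int | None = None
    svm_C: float = 1.0
    time_decim: int | None = None
    # analyses
    cross_targets: tuple[str, ...] = ("size", "clutter")
    run_identity: bool = True
    run_images: bool = True
    # inference
    n_perm: int | None = None
    n_boot: int | None = None
    cluster_alpha: float = 0.05
    corrected_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        for name, value in prof.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "baseline" in raw:
            raw["baseline"] = tuple(raw["baseline"])
        if "cross_targets" in raw:
            raw["cross_targets"] = tuple(raw["cross_targets"])
        return cls(**raw)

    def signal_spec(self) -> SignalSpec:
        return SignalSpec(
            effects=tuple(EffectSpec(**e) for e in self.effects),
            pattern_seed=self.pattern_seed,
            subject_jitter_sd=self.subject_jitter_sd,
        )

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(
            n_channels=self.n_channels,
            scale=self.noise_scale,
            cov_rank=self.noise_cov_rank,
            ar_coefficient=self.noise_ar,
        )

    def decoding_config(self) -> DecodingConfig:
        return DecodingConfig(
            k=self.k,
            cross_k=self.cross_k,
            n_repetitions=self.n_repetitions,
            C=self.svm_C,
            seed=self.seed,
            time_decim=self.time_decim,
        )


def _save_timecourse(tc: GroupTimeCourse, run_dir: Path, name: str) -> None:
    tc.to_csv(run_dir / f"timecourse_{name}.csv")


def _infer_and_save(tc: GroupTimeCourse, cfg: RunConfig, run_dir: Path, name: str) -> dict:
    """Cluster test + bootstrap latencies for one analysis; returns a summary row."""
    result = sign_permutation_cluster_test(
        tc, None, cfg.n_perm, cfg.cluster_alpha, cfg.corrected_alpha, seed=cfg.seed
    )
    result.to_csv(run_dir / f"clusters_{name}.csv")
    latency = bootstrap_latency_ci(
        tc,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        n_perm=cfg.n_perm,
        cluster_alpha=cfg.cluster_alpha,
        corrected_alpha=cfg.corrected_alpha,
    )
    latency.to_frame().to_csv(run_dir / f"latency_{name}.csv", index=False)
    mean = tc.group_mean() - tc.chance
    return {
        "analysis": name,
        "significant": result.any_significant,
        "onset_ms": latency.onset_ms if result.any_significant else float("nan"),
        "onset_ci_low": latency.onset_ci[0],
        "onset_ci_high": latency.onset_ci[1],
        "peak_ms": latency.peak_ms,
        "peak_ci_low": latency.peak_ci[0],
        "peak_ci_high": latency.peak_ci[1],
        "max_effect": float(mean.max()),
    }


def run_pipeline(config: RunConfig, run_dir, activation_features: list | None = None) -> Path:
    """Execute the full analysis graph; returns the run directory."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    design = generate_design(config.n_exemplars)
    design.to_csv(run_dir / "design.csv")
    if config.run_images:
        images = generate_images(design, seed=config.seed)
        images.stats_to_csv(run_dir / "image_stats.csv")

    dataset = generate_dataset(
        design,
        config.signal_spec(),
        config.noise_spec(),
        n_subjects=config.n_subjects,
        n_trials_per_condition=config.n_trials_per_condition,
        master_seed=config.seed,
        tmin_ms=config.tmin_ms,
        tmax_ms=config.tmax_ms,
        step_ms=config.step_ms,
    )
    if config.artifact_rate > 0:
        dataset = [
            inject_artifacts(ep, config.artifact_rate, config.artifact_amplitude, seed=config.seed + s)
            for s, ep in enumerate(dataset)
        ]

    processed, reports = [], []
    for epochs in dataset:
        kept, report_ = reject_trials(epochs, design, config.p2p_threshold)
        reports.append(report_)
        kept = baseline_normalize(kept, config.baseline)
        processed.append(smooth_timecourse(kept, config.smoothing_ms))
    all_trials = pd.concat([r.trials for r in reports], ignore_index=True)
    all_trials.to_csv(run_dir / "rejection_trials.csv", index=False)
    from .preprocessing import RejectionReport

    pooled = RejectionReport(
        trials=all_trials,
        level_counts=pd.concat([r.level_counts for r in reports], ignore_index=True),
    )
    imbalance = rejection_imbalance_test(pooled, design, n_perm=config.n_perm, seed=config.seed)
    imbalance.to_csv(run_dir / "rejection_imbalance_pvalues.csv")

    dec_cfg = config.decoding_config()
    rdms = [pairwise_decoding_timecourse(ep, design, dec_cfg) for ep in processed]
    for r in rdms:
        r.save_h5(run_dir / f"rdms_subject{r.subject_id:02d}.h5")

    rows = []
    if config.n_exemplars > 1:  # image decoding needs factor-matched pairs
        image_tc = factor_average_decoding(rdms, design)
        _save_timecourse(image_tc, run_dir, "image_decoding")
        rows.append(_infer_and_save(image_tc, config, run_dir, "image_decoding"))

    for factor in FACTORS:
        tc = clustering_timecourse(rdms, design, factor)
        _save_timecourse(tc, run_dir, f"clustering_{factor}")
        rows.append(_infer_and_save(tc, config, run_dir, f"clustering_{factor}"))

    for target in config.cross_targets:
        for gen in FACTORS:
            if gen == target:
                continue
            tc = GroupTimeCourse.stack(
                [cross_decoding_timecourse(ep, design, target, gen, dec_cfg) for ep in processed]
            )
            name = f"cross_{target}_across_{gen}"
            _save_timecourse(tc, run_dir, name)
            rows.append(_infer_and_save(tc, config, run_dir, name))
        if config.run_identity and config.n_exemplars == 3:
            tc = GroupTimeCourse.stack(
                [identity_cross_decoding(ep, design, target, dec_cfg) for ep in processed]
            )
            name = f"cross_{target}_across_identity"
            _save_timecourse(tc, run_dir, name)
            rows.append(_infer_and_save(tc, config, run_dir, name))

    factor_models = {f: factor_model_rdm(design, f) for f in FACTORS}
    for factor, model in factor_models.items():
        tc = rsa_timecourse(rdms, model)
        _save_timecourse(tc, run_dir, f"rsa_{factor}")
        rows.append(_infer_and_save(tc, config, run_dir, f"rsa_{factor}"))
    if activation_features:
        from .rsa import feature_rdm

        layer_rdms = [feature_rdm(fs) for fs in activation_features]
        tc = rsa_timecourse(rdms, layer_rdms)
        _save_timecourse(tc, run_dir, "rsa_activation_model")
        rows.append(_infer_and_save(tc, config, run_dir, "rsa_activation_model"))
        tc = partial_rsa_timecourse(rdms, factor_models["size"], layer_rdms)
        _save_timecourse(tc, run_dir, "partial_rsa_size_vs_activation_model")
        rows.append(_infer_and_save(tc, config, run_dir, "partial_rsa_size_vs_activation_model"))

    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "summary.csv", index=False)

    manifest = {
        "package": "megrsa",
        "version": "0.1.0",
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_analyses": len(rows),
    }
    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return run_dir


def report(run_dir) -> pd.DataFrame:
    """Summary table of a finished run: one latency row per analysis.

    Onset/peak cells of non-significant analyses are NaN (flagged by the
    ``significant`` column). Raises if expected artifacts are missing.
    """
    run_dir = Path(run_dir)
    missing = [n for n in ("summary.csv", "manifest.json") if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run at {run_dir}: missing {missing}")
    summary = pd.read_csv(run_dir / "summary.csv")
    for _, row in summary.iterrows():
        latency_file = run_dir / f"latency_{row['analysis']}.csv"
        if not latency_file.exists():
            raise FileNotFoundError(f"missing latency artifact for {row['analysis']}")
    return summary
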
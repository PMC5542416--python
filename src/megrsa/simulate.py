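"""Synthetic multi-subject MEG epochs with known injected effects.

The generator emulates the experimental design the pipeline analyzes:
48 conditions (2x2x2x2 factors x 3 exemplars), 306-channel sensor arrays,
peri-stimulus epochs from -100 to +900 ms, and 60 trials per condition per
subject (15 runs x 4 presentations). Condition information is injected as
factor-level-specific multivariate patterns modulated by a half-cosine
temporal envelope on top of spatially and temporally correlated Gaussian
noise, so ground-truth effect latencies and amplitudes are known exactly
and can be recovered downstream.

Scale profiles
--------------
``desk``  : 30 channels, 5 ms step, 20 trials/condition, 8 subjects —
            completes in minutes, used by the test-suite and examples.
``full``  : 306 channels, 1 ms step, 60 trials/condition, 15 subjects —
            mirrors the recording setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import FACTORS, LEVELS, Design

#: Fixed offset separating per-subject random streams derived from a master seed.
SUBJECT_SEED_OFFSET = 1013


@dataclass(frozen=True)
class EffectSpec:
    """One injected multivariate effect, tied to a factor or to image identity.

    ``factor`` is one of the four design factors, or ``"identity"`` for
    condition-unique (exemplar-level) patterns. The temporal envelope rises
    from 0 at ``onset_ms`` to 1 at ``peak_ms`` and falls back to 0 at
    ``offset_ms`` (half-cosine ramps); ``amplitude`` scales it in fT.
    """

    factor: str
    onset_ms: float
    peak_ms: float
    offset_ms: float
    amplitude: float
    envelope: str = "halfcosine"

    def __post_init__(self) -> None:
        if self.factor != "identity" and self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not (self.onset_ms < self.peak_ms <= self.offset_ms):
            raise ValueError("require onset_ms < peak_ms <= offset_ms")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.envelope != "halfcosine":
            raise ValueError(f"unknown envelope {self.envelope!r}")

    def envelope_at(self, times: np.ndarray) -> np.ndarray:
        env = np.zeros_like(times, dtype=float)
        rise = (times >= self.onset_ms) & (times < self.peak_ms)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - self.onset_ms) / (self.peak_ms - self.onset_ms)))
        if self.offset_ms > self.peak_ms:
            fall = (times >= self.peak_ms) & (times <= self.offset_ms)
            env[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - self.peak_ms) / (self.offset_ms - self.peak_ms)))
        else:
            env[times == self.peak_ms] = 1.0
        return env


@dataclass(frozen=True)
class SignalSpec:
    """Collection of injected effects plus pattern randomization controls.

    ``pattern_seed`` fixes the group-level spatial patterns; each subject's
    patterns are jittered around them with SD ``subject_jitter_sd`` (relative
    to the unit-norm group pattern) so subjects share, but do not duplicate,
    the same multivariate code.
    """

    effects: tuple[EffectSpec, ...] = ()
    pattern_seed: int = 7
    subject_jitter_sd: float = 0.2

    @staticmethod
    def null() -> "SignalSpec":
        return SignalSpec(effects=())


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially and temporally correlated sensor noise.

    Channel covariance is low-rank-plus-diagonal: ``scale**2 * (I + U U^T)``
    with ``U`` of rank ``cov_rank``; the time series is then AR(1)-filtered
    with coefficient ``ar_coefficient`` to mimic sensor autocorrelation.
    ``spike_rate``/``spike_amplitude`` parameterize optional artifact
    injection (see :func:`inject_artifacts`).
    """

    n_channels: int = 306
    scale: float = 100.0  # fT
    cov_rank: int = 5
    ar_coefficient: float = 0.8
    spike_rate: float = 0.0
    spike_amplitude: float = 10000.0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.cov_rank < 0:
            raise ValueError("n_channels must be >= 1 and cov_rank >= 0")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.spike_amplitude <= 0:
            raise ValueError("spike_amplitude must be > 0")

    def channel_chol(self, rng: np.random.Generator) -> np.ndarray:
        u = rng.standard_normal((self.n_channels, self.cov_rank)) / max(self.cov_rank, 1) ** 0.5
        cov = self.scale**2 * (np.eye(self.n_channels) + u @ u.T)
        return np.linalg.cholesky(cov)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _level_patterns(signal: SignalSpec, design: Design, n_channels: int) -> dict:
    """Group-level unit-norm spatial patterns per (factor, level) and condition."""
    rng = np.random.default_rng(signal.pattern_seed)
    patterns: dict = {}
    for effect in signal.effects:
        if effect.factor == "identity":
            for cid in design.condition_ids:
                patterns.setdefault(("identity", int(cid)), _unit(rng.standard_normal(n_channels)))
        else:
            for level in LEVELS[effect.factor]:
                patterns.setdefault((effect.factor, level), _unit(rng.standard_normal(n_channels)))
    return patterns


def _jitter(pattern: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return pattern
    return _unit(pattern + sd * rng.standard_normal(pattern.shape))


def generate_epochs(
    design: Design,
    signal: SignalSpec,
    noise: NoiseSpec,
    n_trials_per_condition: int = 60,
    subject_seed: int = 0,
    subject_id: int = 1,
    tmin_ms: float = -100.0,
    tmax_ms: float = 900.0,
    step_ms: float = 1.0,
    n_runs: int = 15,
) -> EpochSet:
    """Simulate one subject's epochs.

    The pre-stimulus window carries noise only (all injected envelopes start
    at or after 0 ms by convention of the caller); each effect adds its
    level-specific spatial pattern scaled by amplitude x envelope to every
    trial of the matching conditions. Trials are assigned to ``n_runs`` runs
    cyclically (60 trials over 15 runs reproduces 4 presentations per run).
    """
    if n_trials_per_condition < 2:
        raise ValueError("n_trials_per_condition must be >= 2")
    times = np.arange(tmin_ms, tmax_ms + 0.5 * step_ms, step_ms)
    rng = np.random.default_rng(subject_seed)
    n_cond = design.n_conditions
    n_trials = n_cond * n_trials_per_condition
    n_t = len(times)

    # colored noise: channel covariance then AR(1) along time
    chol = noise.channel_chol(rng)
    white = rng.standard_normal((n_trials, noise.n_channels, n_t))
    data = np.einsum("ck,nkt->nct", chol, white)
    if noise.ar_coefficient > 0:
        a = noise.ar_coefficient
        innov_scale = np.sqrt(1 - a * a)  # keep stationary variance constant
        for t in range(1, n_t):
            data[:, :, t] = a * data[:, :, t - 1] + innov_scale * data[:, :, t]

    condition_ids = np.repeat(design.condition_ids.to_numpy(), n_trials_per_condition)
    run_ids = np.tile(np.arange(n_trials_per_condition) % n_runs + 1, n_cond)

    patterns = _level_patterns(signal, design, noise.n_channels)
    jittered = {
        key: _jitter(p, signal.subject_jitter_sd, rng) for key, p in sorted(patterns.items(), key=lambda kv: str(kv[0]))
    }
    for effect in signal.effects:
        if effect.amplitude == 0:
            continue
        env = effect.amplitude * effect.envelope_at(times)
        if effect.factor == "identity":
            for cid in design.condition_ids:
                mask = condition_ids == cid
                data[mask] += jittered[("identity", int(cid))][:, None] * env[None, :]
        else:
            levels = design.levels(effect.factor)
            for level in LEVELS[effect.factor]:
                cids = design.condition_ids[levels == level].to_numpy()
                mask = np.isin(condition_ids, cids)
                data[mask] += jittered[(effect.factor, level)][:, None] * env[None, :]

    metadata = pd.DataFrame(
        {"condition_id": condition_ids, "subject_id": subject_id, "run_id": run_ids}
    )
    return EpochSet(data=data, times=times, metadata=metadata)


def generate_dataset(
    design: Design,
    signal: SignalSpec,
    noise: NoiseSpec,
    n_subjects: int = 15,
    n_trials_per_condition: int = 60,
    master_seed: int = 0,
    **epoch_kwargs,
) -> list[EpochSet]:
    """Simulate all subjects; per-subject seeds derive from the master seed
    by a fixed offset so any subject can be regenerated independently."""
    return [
        generate_epochs(
            design,
            signal,
            noise,
            n_trials_per_condition,
            subject_seed=master_seed + SUBJECT_SEED_OFFSET * (s + 1),
            subject_id=s + 1,
            **epoch_kwargs,
        )
        for s in range(n_subjects)
    ]


def inject_artifacts(epochs: EpochSet, rate: float, amplitude: float, seed: int = 0) -> EpochSet:
    """Add single-channel, single-sample spikes to a random fraction of trials.

    Returns a new EpochSet whose metadata gains a boolean ``artifact``
    column flagging the spiked trials. ``rate=0`` returns an identical copy.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    n_spiked = int(round(rate * out.n_trials))
    spiked = rng.choice(out.n_trials, size=n_spiked, replace=False)
    channels = rng.integers(0, out.n_channels, size=n_spiked)
    samples = rng.integers(0, len(out.times), size=n_spiked)
    for trial, ch, t in zip(spiked, channels, samples):
        out.data[trial, ch, t] += amplitude
    flags = np.zeros(out.n_trials, dtype=bool)
    flags[spiked] = True
    out.metadata["artifact"] = flags
    return out
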
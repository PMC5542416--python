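"""Epoch preprocessing: peak-to-peak trial rejection, baseline normalization,
sliding-window temporal smoothing, and the rejection-imbalance check.

The processing order used on the recordings is: reject trials whose
peak-to-peak amplitude reaches 8000 fT, normalize each channel by its
pre-stimulus baseline mean and SD, then smooth with a 20 ms sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import FACTORS, LEVELS, Design

#: Default rejection threshold, femtotesla.
P2P_THRESHOLD_FT = 8000.0


@dataclass
class RejectionReport:
    """Per-trial rejection flags plus per-factor-level rejected counts.

    ``trials`` has one row per input trial: subject_id, condition_id,
    peak-to-peak amplitude (fT, max over channels) and a kept flag.
    ``level_counts`` tabulates rejected trials per subject x factor x level.
    """

    trials: pd.DataFrame
    level_counts: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return int((~self.trials["kept"]).sum())

    @property
    def n_kept(self) -> int:
        return int(self.trials["kept"].sum())

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def peak_to_peak(epochs: EpochSet) -> np.ndarray:
    """Per-trial peak-to-peak amplitude: max over channels of (max - min over time)."""
    return (epochs.data.max(axis=2) - epochs.data.min(axis=2)).max(axis=1)


def reject_trials(
    epochs: EpochSet, design: Design, p2p_threshold: float = P2P_THRESHOLD_FT
) -> tuple[EpochSet, RejectionReport]:
    """Keep only trials whose peak-to-peak amplitude is below threshold.

    A trial is rejected as soon as any single channel exceeds the threshold
    — one bad sensor invalidates the whole trial. Raises if rejection
    empties some condition entirely (nothing left to decode there).
    """
    if p2p_threshold <= 0:
        raise ValueError("p2p_threshold must be > 0")
    p2p = peak_to_peak(epochs)
    kept = p2p < p2p_threshold
    trials = pd.DataFrame(
        {
            "subject_id": epochs.metadata["subject_id"],
            "condition_id": epochs.metadata["condition_id"],
            "p2p_fT": p2p,
            "kept": kept,
        }
    )
    remaining = set(epochs.metadata.loc[kept, "condition_id"])
    emptied = sorted(set(epochs.metadata["condition_id"]) - remaining)
    if emptied:
        raise ValueError(f"all trials rejected for condition(s) {emptied}")

    level_map = design.table.set_index("condition_id")
    rows = []
    rejected = trials.loc[~kept]
    for subject, group in trials.groupby("subject_id"):
        rej = rejected[rejected["subject_id"] == subject]
        for factor in FACTORS:
            cond_levels = level_map.loc[rej["condition_id"], factor] if len(rej) else pd.Series(dtype=object)
            for level in LEVELS[factor]:
                rows.append(
                    {
                        "subject_id": subject,
                        "factor": factor,
                        "level": level,
                        "n_rejected": int((cond_levels == level).sum()),
                    }
                )
    report = RejectionReport(trials=trials, level_counts=pd.DataFrame(rows))
    return epochs.select_trials(kept), report


def rejection_imbalance_test(
    report: RejectionReport, design: Design, n_perm: int = 1000, seed: int = 0
) -> pd.Series:
    """Sign-permutation test for factor-level imbalance of rejected counts.

    For each factor, the per-subject difference in rejected-trial counts
    between the two levels is tested against zero by randomly flipping each
    subject's sign. A significant p-value would indicate systematic
    differences (e.g. more movement for one scene size), which would bias
    decoding.
    """
    from .inference import sign_permutation_test

    counts = report.level_counts
    subjects = sorted(counts["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("imbalance test requires >= 2 subjects")
    pvals = {}
    for factor in FACTORS:
        lo, hi = LEVELS[factor]
        sub = counts[counts["factor"] == factor].pivot(
            index="subject_id", columns="level", values="n_rejected"
        )
        diffs = (sub[hi] - sub[lo]).to_numpy(dtype=float)
        pvals[factor] = sign_permutation_test(diffs, n_perm=n_perm, seed=seed)
    return pd.Series(pvals, name="p_value")


def baseline_normalize(epochs: EpochSet, window: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Z-score each trial x channel by its baseline mean and SD.

    The window is closed on the left and open on the right (the sample at
    0 ms — stimulus onset — is excluded).
    """
    lo, hi = window
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if mask.sum() < 2:
        raise ValueError(f"baseline window {window} covers fewer than 2 samples")
    base = epochs.data[:, :, mask]
    mean = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=0, keepdims=True)
    # constant channels leave rounding-level SD, not exact zero
    degenerate = sd[:, :, 0] <= 1e-12 * np.maximum(np.abs(mean[:, :, 0]), 1.0)
    zero = np.argwhere(degenerate)
    if len(zero):
        trial, ch = zero[0]
        raise ValueError(f"zero baseline SD at trial {trial}, channel {ch}")
    out = epochs.copy()
    out.data = (epochs.data - mean) / sd
    return out


def smooth_timecourse(epochs: EpochSet, window_ms: float = 20.0) -> EpochSet:
    """Centered sliding-window (boxcar) average along time.

    Edge handling truncates the window (a shorter average near the
    boundaries) rather than padding, so no pre-baseline data is invented.
    The output time grid is unchanged. With an even number of samples in
    the window the extra sample goes to the trailing side.
    """
    step = epochs.sampling_step_ms
    n = int(round(window_ms / step))
    if n < 1:
        raise ValueError(f"window {window_ms} ms is shorter than one sample ({step} ms)")
    if n == 1:
        return epochs.copy()
    half_left, half_right = (n - 1) // 2, n // 2
    n_t = len(epochs.times)
    # truncated moving average via cumulative sums
    csum = np.cumsum(epochs.data, axis=2)
    csum = np.concatenate([np.zeros(csum.shape[:2] + (1,)), csum], axis=2)
    idx = np.arange(n_t)
    starts = np.maximum(idx - half_left, 0)
    stops = np.minimum(idx + half_right + 1, n_t)
    out = epochs.copy()
    out.data = (csum[:, :, stops] - csum[:, :, starts]) / (stops - starts)
    return out
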
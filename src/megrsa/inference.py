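"""Nonparametric group inference for time courses and RDM correlations.

* one-sample sign-permutation tests: under the null the sign of each
  participant's whole time course (or scalar) is exchangeable, so the null
  distribution is built by randomly multiplying per-subject data by +/-1;
* cluster-size inference corrects over time: candidate clusters are
  maximal runs of per-timepoint p-values below the cluster-definition
  threshold, and a cluster is significant if its length exceeds the
  (1 - alpha) quantile of the maximal cluster size under permutation;
* bootstrap over participants yields confidence intervals for cluster
  onset and peak latencies and for peak-to-peak latency differences;
* condition-label permutation tests assess model-RDM correlations, with
  Benjamini-Hochberg FDR across model comparisons.

All empirical p-values use the plus-one convention (the observed sample is
counted into its own null), so they are valid at finite permutation counts
and never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GroupTimeCourse
from .rsa import ModelRDM, _spearman


# --------------------------------------------------------------------------
# sign permutations
# --------------------------------------------------------------------------


def _sign_matrix(
    n_subjects: int, n_perm: int, rng: np.random.Generator, exhaustive: str | bool = "auto"
) -> tuple[np.ndarray, bool]:
    """Random (or exhaustive, if cheaper) matrix of +/-1 sign assignments.

    Returns (signs, is_exhaustive). Exhaustive enumeration includes the
    identity assignment, so exhaustive p-values count the observed sample
    by construction and skip the plus-one correction.
    """
    do_exhaustive = exhaustive is True or (exhaustive == "auto" and 2**n_subjects <= n_perm)
    if do_exhaustive:
        grid = np.unpackbits(
            np.arange(2**n_subjects, dtype=np.uint32).view(np.uint8).reshape(-1, 4), axis=1, bitorder="little"
        )[:, :n_subjects]
        return grid.astype(np.int8) * 2 - 1, True
    return rng.choice([-1, 1], size=(n_perm, n_subjects)).astype(np.int8), False


def sign_permutation_test(values: np.ndarray, n_perm: int = 1000, seed: int = 0, exhaustive="auto") -> float:
    """Two-sided one-sample sign-permutation p-value for per-subject scalars."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D array of >= 2 per-subject values")
    signs, is_exhaustive = _sign_matrix(len(values), n_perm, np.random.default_rng(seed), exhaustive)
    null = np.abs(signs @ values) / len(values)
    obs = abs(values.mean())
    n_null = len(signs)
    if is_exhaustive:  # identity flip included in the null
        return float((null >= obs - 1e-12).sum() / n_null)
    return float((1 + (null >= obs - 1e-12).sum()) / (1 + n_null))


@dataclass
class ClusterResult:
    """Outcome of a sign-permutation cluster-size test.

    ``clusters`` holds the significant clusters only (start_ms, end_ms,
    n_timepoints, sign, p_value); ``candidates`` all suprathreshold runs.
    """

    clusters: pd.DataFrame
    candidates: pd.DataFrame
    pointwise_p: np.ndarray
    null_max_sizes: np.ndarray
    times: np.ndarray
    cluster_alpha: float
    corrected_alpha: float

    @property
    def any_significant(self) -> bool:
        return len(self.clusters) > 0

    @property
    def onset_ms(self) -> float:
        """Start of the earliest significant cluster (NaN if none)."""
        return float(self.clusters["start_ms"].min()) if self.any_significant else float("nan")

    def to_csv(self, path) -> None:
        self.clusters.to_csv(path, index=False)

    def report_text(self) -> str:
        lines = [
            f"cluster-definition alpha: {self.cluster_alpha}, corrected alpha: {self.corrected_alpha}",
            f"significant clusters: {len(self.clusters)} (of {len(self.candidates)} candidates)",
        ]
        for _, row in self.clusters.iterrows():
            lines.append(
                f"  {row['start_ms']:.0f}-{row['end_ms']:.0f} ms "
                f"({int(row['n_timepoints'])} samples, sign {int(row['sign']):+d}, p={row['p_value']:.4f})"
            )
        return "\n".join(lines)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index ranges of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _max_run(mask_rows: np.ndarray) -> np.ndarray:
    """Maximal True-run length per row (vectorized over rows)."""
    p, t = mask_rows.shape
    padded = np.zeros((p, t + 2), dtype=np.int8)
    padded[:, 1:-1] = mask_rows
    out = np.zeros(p, dtype=int)
    for i in range(p):  # rows are permutations; loop is cheap relative to ranking
        edges = np.flatnonzero(np.diff(padded[i]))
        if len(edges):
            out[i] = int((edges[1::2] - edges[::2]).max())
    return out


def sign_permutation_cluster_test(
    tc: GroupTimeCourse,
    null_value: float | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    corrected_alpha: float = 0.05,
    seed: int = 0,
    exhaustive="auto",
) -> ClusterResult:
    """Sign-permutation test with cluster-size correction over time.

    Per-timepoint two-sided empirical p-values are computed from the
    permutation distribution of the group mean at that time point; maximal
    runs of p < ``cluster_alpha`` form candidate clusters (positive and
    negative effects tracked separately); a candidate is reported if its
    length exceeds the (1 - ``corrected_alpha``) quantile of the maximal
    cluster size across permutations.
    """
    if tc.n_subjects < 2:
        raise ValueError("cluster test requires >= 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if 1.0 / (1 + n_perm) >= cluster_alpha:
        raise ValueError(f"n_perm={n_perm} cannot resolve cluster_alpha={cluster_alpha}")
    null_value = tc.chance if null_value is None else null_value
    x = tc.values - null_value  # subjects x time
    signs, is_exhaustive = _sign_matrix(tc.n_subjects, n_perm, np.random.default_rng(seed), exhaustive)
    n_null = len(signs)
    perm_means = np.abs(signs.astype(float) @ x) / tc.n_subjects  # perms x time
    obs_mean = x.mean(axis=0)
    obs_abs = np.abs(obs_mean)

    extra = 0 if is_exhaustive else 1  # plus-one only when the identity is not enumerated
    pointwise_p = (extra + (perm_means >= obs_abs[None, :] - 1e-12).sum(axis=0)) / (extra + n_null)
    # p-values of each permutation sample against the same null, for the
    # null distribution of maximal cluster size
    greater_equal = stats.rankdata(-perm_means, axis=0, method="max")  # #{>=} including self
    perm_p = greater_equal / n_null
    null_max_sizes = _max_run(perm_p < cluster_alpha)

    candidates = []
    supra = pointwise_p < cluster_alpha
    for sign in (1, -1):
        mask = supra & (np.sign(obs_mean) == sign)
        for start, stop in _runs(mask):
            size = stop - start
            p_cluster = (extra + (null_max_sizes >= size).sum()) / (extra + n_null)
            candidates.append(
                {
                    "start_ms": tc.times[start],
                    "end_ms": tc.times[stop - 1],
                    "n_timepoints": size,
                    "sign": sign,
                    "p_value": p_cluster,
                }
            )
    cols = ["start_ms", "end_ms", "n_timepoints", "sign", "p_value"]
    candidates = pd.DataFrame(candidates, columns=cols).sort_values("start_ms").reset_index(drop=True)
    clusters = candidates[candidates["p_value"] <= corrected_alpha].reset_index(drop=True)
    return ClusterResult(
        clusters=clusters,
        candidates=candidates,
        pointwise_p=pointwise_p,
        null_max_sizes=null_max_sizes,
        times=tc.times,
        cluster_alpha=cluster_alpha,
        corrected_alpha=corrected_alpha,
    )


# --------------------------------------------------------------------------
# bootstrap latency estimation
# --------------------------------------------------------------------------


@dataclass
class LatencyEstimate:
    """Onset/peak latency point estimates with bootstrap 95% CIs."""

    onset_ms: float
    onset_ci: tuple[float, float]
    peak_ms: float
    peak_ci: tuple[float, float]
    n_boot: int
    n_without_cluster: int = 0
    difference_ci: tuple[float, float] | None = None
    difference_significant: bool | None = None
    onset_samples: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    peak_samples: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "onset_ms": self.onset_ms,
                    "onset_ci_low": self.onset_ci[0],
                    "onset_ci_high": self.onset_ci[1],
                    "peak_ms": self.peak_ms,
                    "peak_ci_low": self.peak_ci[0],
                    "peak_ci_high": self.peak_ci[1],
                    "n_boot": self.n_boot,
                    "n_without_cluster": self.n_without_cluster,
                }
            ]
        )


def _peak_latency(times: np.ndarray, mean: np.ndarray, window: tuple[float, float | None]) -> float:
    lo, hi = window
    mask = times >= lo
    if hi is not None:
        mask &= times <= hi
    idx = np.flatnonzero(mask)
    return float(times[idx[np.argmax(mean[idx])]])


def bootstrap_latency_ci(
    tc: GroupTimeCourse,
    n_boot: int = 1000,
    seed: int = 0,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    corrected_alpha: float = 0.05,
    peak_window: tuple[float, float | None] = (0.0, None),
    peak_within_clusters: bool = False,
) -> LatencyEstimate:
    """Bootstrap (over participants, with replacement) CIs for the cluster
    onset and the peak latency of a group time course.

    Each bootstrap sample reruns the full cluster test; samples without any
    significant cluster contribute no onset and are counted in
    ``n_without_cluster``. The peak is the global argmax of the bootstrap
    group mean within ``peak_window`` (post-stimulus by default); with
    ``peak_within_clusters`` it is restricted to significant clusters.
    """
    if tc.n_subjects < 2:
        raise ValueError("bootstrap requires >= 2 subjects")
    rng = np.random.default_rng(seed)

    def analyze(values: np.ndarray, perm_seed: int) -> tuple[float, float]:
        sample = tc.with_values(values)
        result = sign_permutation_cluster_test(
            sample, None, n_perm, cluster_alpha, corrected_alpha, seed=perm_seed
        )
        onset = result.onset_ms
        mean = values.mean(axis=0) - tc.chance
        if peak_within_clusters:
            if not result.any_significant:
                return onset, float("nan")
            mask = np.zeros(len(tc.times), dtype=bool)
            for _, row in result.clusters.iterrows():
                mask |= (tc.times >= row["start_ms"]) & (tc.times <= row["end_ms"])
            idx = np.flatnonzero(mask)
            return onset, float(tc.times[idx[np.argmax(mean[idx])]])
        return onset, _peak_latency(tc.times, mean, peak_window)

    point_onset, point_peak = analyze(tc.values, perm_seed=seed)
    onsets, peaks = [], []
    for b in range(n_boot):
        idx = rng.integers(0, tc.n_subjects, tc.n_subjects)
        onset, peak = analyze(tc.values[idx], perm_seed=seed + 1 + b)
        onsets.append(onset)
        peaks.append(peak)
    onsets = np.asarray(onsets, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    valid = onsets[~np.isnan(onsets)]
    n_missing = int(np.isnan(onsets).sum())
    if len(valid):
        onset_ci = tuple(np.percentile(valid, [2.5, 97.5]))
    else:
        onset_ci = (float("nan"), float("nan"))
    peak_valid = peaks[~np.isnan(peaks)]
    peak_ci = tuple(np.percentile(peak_valid, [2.5, 97.5])) if len(peak_valid) else (float("nan"),) * 2
    return LatencyEstimate(
        onset_ms=point_onset,
        onset_ci=onset_ci,
        peak_ms=point_peak,
        peak_ci=peak_ci,
        n_boot=n_boot,
        n_without_cluster=n_missing,
        onset_samples=onsets,
        peak_samples=peaks,
    )


def peak_to_peak_difference_test(
    tc_a: GroupTimeCourse,
    tc_b: GroupTimeCourse,
    n_boot: int = 1000,
    seed: int = 0,
    peak_window: tuple[float, float | None] = (0.0, None),
) -> LatencyEstimate:
    """Bootstrap test for a difference in peak latency between two analyses.

    Subjects are resampled jointly (the same bootstrap indices applied to
    both time courses, which share the participant sample); the statistic
    is peak(A) - peak(B). The difference is significant at the 5% level if
    the 95% CI excludes 0. Swapping A and B negates the estimate and CI.
    """
    if tc_a.values.shape != tc_b.values.shape or not np.array_equal(tc_a.times, tc_b.times):
        raise ValueError("time courses must share subjects and time axis")
    rng = np.random.default_rng(seed)
    point = _peak_latency(tc_a.times, tc_a.values.mean(0) - tc_a.chance, peak_window) - _peak_latency(
        tc_b.times, tc_b.values.mean(0) - tc_b.chance, peak_window
    )
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, tc_a.n_subjects, tc_a.n_subjects)
        diffs[b] = _peak_latency(tc_a.times, tc_a.values[idx].mean(0) - tc_a.chance, peak_window) - _peak_latency(
            tc_b.times, tc_b.values[idx].mean(0) - tc_b.chance, peak_window
        )
    ci = tuple(np.percentile(diffs, [2.5, 97.5]))
    significant = not (ci[0] <= 0.0 <= ci[1])
    return LatencyEstimate(
        onset_ms=float("nan"),
        onset_ci=(float("nan"), float("nan")),
        peak_ms=point,
        peak_ci=ci,
        n_boot=n_boot,
        difference_ci=ci,
        difference_significant=significant,
        peak_samples=diffs,
    )


# --------------------------------------------------------------------------
# label permutation and FDR
# --------------------------------------------------------------------------


def label_permutation_test(model: ModelRDM, target: ModelRDM, n_perm: int = 1000, seed: int = 0) -> float:
    """Condition-label permutation test of the model-target RDM correlation.

    Rows and columns of the model RDM are permuted simultaneously (a
    relabeling of conditions), preserving each matrix's value multiset; the
    two-sided p-value compares |Spearman r| against this null.
    """
    if model.n_conditions != target.n_conditions:
        raise ValueError("RDMs must share the condition set")
    tri_t = target.lower_triangle()
    tri_m = model.lower_triangle()
    for name, tri in (("model", tri_m), ("target", tri_t)):
        if np.all(tri == tri[0]):
            raise ValueError(f"{name} RDM is constant; correlation undefined")
    obs = abs(_spearman(tri_m, tri_t))
    rng = np.random.default_rng(seed)
    n = model.n_conditions
    i, j = np.tril_indices(n, k=-1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        tri_p = model.dissimilarity[perm[:, None], perm[None, :]][i, j]
        if abs(_spearman(tri_p, tri_t)) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject decisions, adjusted p-values)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, adjusted
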
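"""Time-resolved multivariate decoding of sensor patterns.

Three schemes, all built on pseudo-trial sub-averaging and a linear SVM
(C=1) applied independently at every time point:

* pairwise decoding of every condition pair with leave-one-pseudotrial-out
  cross-validation, yielding a time series of condition x condition
  decoding matrices (the MEG RDMs);
* cross-classification of a target factor across the levels of another
  factor (train on one level of the generalization factor, test on the
  other, directions averaged), with trials pooled across the images that
  share target and generalization levels;
* cross-classification across image identity (train on two exemplars per
  factor combination, test on the held-out exemplar).

Decoding accuracy is reported in percent; chance is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet, GroupTimeCourse, RDMSeries
from .design import FACTORS, LEVELS, Design
from .svm import classify


@dataclass(frozen=True)
class DecodingConfig:
    """Sub-averaging, repetition and classifier settings.

    ``k`` is the pairwise sub-averaging group size (5 raw trials per
    pseudo-trial), ``cross_k`` the pooled-trial group size used by both
    cross-classification schemes (60). ``time_decim`` evaluates every
    m-th sample of the epoch grid — the decoding problem is independent
    across time points, so decimation only coarsens the latency grid.
    """

    k: int = 5
    cross_k: int = 60
    n_repetitions: int = 100
    C: float = 1.0
    seed: int = 0
    time_decim: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.cross_k < 1:
            raise ValueError("k and cross_k must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.time_decim < 1:
            raise ValueError("time_decim must be >= 1")


def subaverage(trials: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Average randomly assigned groups of k raw trials into pseudo-trials.

    Returns floor(M/k) pseudo-trials; the M mod k leftover trials are
    dropped for this assignment (a fresh random assignment each repetition
    recycles all trials in expectation).
    """
    m = trials.shape[0]
    if m < k:
        raise ValueError(f"need at least k={k} trials, got {m}")
    n_groups = m // k
    order = rng.permutation(m)[: n_groups * k]
    return trials[order].reshape(n_groups, k, *trials.shape[1:]).mean(axis=1)


def _decimate(epochs: EpochSet, decim: int) -> tuple[np.ndarray, np.ndarray]:
    return epochs.data[:, :, ::decim], epochs.times[::decim]


def _condition_arrays(data: np.ndarray, metadata, condition_ids) -> list[np.ndarray]:
    cond = metadata["condition_id"].to_numpy()
    return [data[cond == cid] for cid in condition_ids]


def _subject_id(epochs: EpochSet) -> int:
    ids = epochs.metadata["subject_id"].unique()
    if len(ids) != 1:
        raise ValueError("decoding operates on single-subject epoch sets")
    return int(ids[0])


def _loo_accuracy(pseudo0: np.ndarray, pseudo1: np.ndarray, C: float) -> float:
    """Leave-one-pseudotrial-out (one per class) accuracy, in percent."""
    n_folds = min(len(pseudo0), len(pseudo1))
    correct = 0
    for f in range(n_folds):
        train0 = np.delete(pseudo0, f, axis=0)
        train1 = np.delete(pseudo1, f, axis=0)
        pred = classify(train0, train1, np.stack([pseudo0[f], pseudo1[f]]), C)
        correct += int(pred[0] == 0) + int(pred[1] == 1)
    return 100.0 * correct / (2 * n_folds)


def pairwise_decoding_timecourse(
    epochs: EpochSet, design: Design, config: DecodingConfig = DecodingConfig()
) -> RDMSeries:
    """Pairwise decoding matrices over time for one subject.

    For each repetition the raw trials of every condition are randomly
    sub-averaged in groups of ``k``; each condition pair is then classified
    with leave-one-pseudotrial-out (one held-out vector per class) at every
    time point, and accuracies are averaged over folds and repetitions into
    the (i, j) and (j, i) cells. The diagonal is NaN.
    """
    subject = _subject_id(epochs)
    epochs.check_against_design(design)
    data, times = _decimate(epochs, config.time_decim)
    cids = design.condition_ids.to_numpy()
    per_cond = _condition_arrays(data, epochs.metadata, cids)
    for cid, arr in zip(cids, per_cond):
        if arr.shape[0] < 2 * config.k:
            raise ValueError(f"condition {cid} has {arr.shape[0]} trials; need >= 2k = {2 * config.k}")
    n_cond, n_t = len(cids), len(times)
    rng = np.random.default_rng([config.seed, subject])
    acc = np.zeros((n_t, n_cond, n_cond))
    for _ in range(config.n_repetitions):
        pseudo = [subaverage(arr, config.k, rng) for arr in per_cond]
        for t in range(n_t):
            at_t = [p[:, :, t] for p in pseudo]
            for i in range(n_cond):
                for j in range(i + 1, n_cond):
                    a = _loo_accuracy(at_t[i], at_t[j], config.C)
                    acc[t, i, j] += a
                    acc[t, j, i] += a
    acc /= config.n_repetitions
    np.einsum("tii->ti", acc)[:] = np.nan
    return RDMSeries(accuracies=acc, times=times, condition_ids=cids, subject_id=subject)


def matched_exemplar_pairs(design: Design) -> list[tuple[int, int]]:
    """Index pairs (i < j) of conditions sharing all four factor levels."""
    key = design.combination_key().to_numpy()
    return [
        (i, j)
        for i in range(len(key))
        for j in range(i + 1, len(key))
        if key[i] == key[j]
    ]


def factor_average_decoding(rdms, design: Design) -> GroupTimeCourse:
    """Average decodability of single images, controlled for all factors.

    Averages only RDM cells whose two conditions agree on size, clutter,
    contrast and luminance (i.e. differ in exemplar only), so the resulting
    time course reflects image-identity information uncontaminated by
    factor-level differences.
    """
    rdms_list = [rdms] if isinstance(rdms, RDMSeries) else list(rdms)
    pairs = matched_exemplar_pairs(design)
    if not pairs:
        raise ValueError("design has no matched exemplar pairs")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    courses = [
        GroupTimeCourse(
            values=r.accuracies[:, ii, jj].mean(axis=1)[None, :],
            times=r.times,
            subject_ids=np.array([r.subject_id]),
            label="image decoding (factor-matched pairs)",
            chance=50.0,
        )
        for r in rdms_list
    ]
    return GroupTimeCourse.stack(courses)


def cross_classification_pool_sizes(
    design: Design, n_trials_per_condition: int, target_factor: str, generalization_factor: str
) -> dict:
    """Raw training-set size per class for factor cross-classification.

    Pooling trials across all images that share the target and
    generalization levels multiplies the per-image trial count by the
    number of images per cell (12 in the 48-condition design, giving
    M = 720 raw pattern vectors at 60 trials/image).
    """
    t_levels = design.levels(target_factor)
    g_levels = design.levels(generalization_factor)
    sizes = {}
    for tlev in LEVELS[target_factor]:
        for glev in LEVELS[generalization_factor]:
            n_images = int(((t_levels == tlev) & (g_levels == glev)).sum())
            sizes[(tlev, glev)] = n_images * n_trials_per_condition
    return sizes


def _pooled_level_arrays(data, metadata, design, factor):
    """Trials pooled over all conditions at each level of one factor."""
    levels = design.levels(factor)
    cond = metadata["condition_id"].to_numpy()
    out = {}
    for level in LEVELS[factor]:
        cids = design.condition_ids[levels == level].to_numpy()
        out[level] = np.isin(cond, cids)
    return out


def _train_test_accuracy(train0, train1, test0, test1, C) -> float:
    pred0 = classify(train0, train1, test0, C)
    pred1 = classify(train0, train1, test1, C)
    return 100.0 * ((pred0 == 0).sum() + (pred1 == 1).sum()) / (len(pred0) + len(pred1))


def _generalization_timecourse(
    epochs: EpochSet,
    design: Design,
    target_factor: str,
    split_masks: dict,
    config: DecodingConfig,
    label: str,
) -> GroupTimeCourse:
    """Shared engine for both cross-classification schemes.

    ``split_masks`` maps split name -> boolean trial mask; the two splits
    alternate as training and testing sets and results are averaged.
    Within each split, trials are pooled per target level and sub-averaged
    in groups of ``cross_k``.
    """
    subject = _subject_id(epochs)
    data, times = _decimate(epochs, config.time_decim)
    t_levels = LEVELS[target_factor]
    level_mask = _pooled_level_arrays(data, epochs.metadata, design, target_factor)
    split_names = list(split_masks)
    cells = {}
    for split in split_names:
        for tlev in t_levels:
            mask = split_masks[split] & level_mask[tlev]
            if not mask.any():
                raise ValueError(f"empty cell: {target_factor}={tlev}, split={split}")
            cells[(split, tlev)] = data[mask]
    rng = np.random.default_rng([config.seed, subject, 1])
    n_t = len(times)
    acc = np.zeros(n_t)
    for _ in range(config.n_repetitions):
        pseudo = {key: subaverage(arr, config.cross_k, rng) for key, arr in cells.items()}
        for t in range(n_t):
            for train_split, test_split in (split_names, split_names[::-1]):
                acc[t] += _train_test_accuracy(
                    pseudo[(train_split, t_levels[0])][:, :, t],
                    pseudo[(train_split, t_levels[1])][:, :, t],
                    pseudo[(test_split, t_levels[0])][:, :, t],
                    pseudo[(test_split, t_levels[1])][:, :, t],
                    config.C,
                )
    acc /= config.n_repetitions * 2
    return GroupTimeCourse(
        values=acc[None, :],
        times=times,
        subject_ids=np.array([subject]),
        label=label,
        chance=50.0,
    )


def cross_decoding_timecourse(
    epochs: EpochSet,
    design: Design,
    target_factor: str,
    generalization_factor: str,
    config: DecodingConfig = DecodingConfig(),
) -> GroupTimeCourse:
    """Decode the target factor training on one level of another factor and
    testing on the other level (both directions, averaged).

    Above-chance accuracy indicates a target representation tolerant to the
    generalization factor. Trials are pooled across the images sharing
    target and generalization levels (12 images per cell in the 48-condition
    design), giving M = 720 raw vectors per class at full scale, and
    sub-averaged with k=60.
    """
    if target_factor == generalization_factor:
        raise ValueError("target and generalization factors must differ")
    for f in (target_factor, generalization_factor):
        if f not in FACTORS:
            raise ValueError(f"unknown factor {f!r}")
    cond = epochs.metadata["condition_id"].to_numpy()
    g_levels = design.levels(generalization_factor)
    masks = {}
    for glev in LEVELS[generalization_factor]:
        cids = design.condition_ids[g_levels == glev].to_numpy()
        masks[glev] = np.isin(cond, cids)
    return _generalization_timecourse(
        epochs,
        design,
        target_factor,
        masks,
        config,
        label=f"{target_factor} across {generalization_factor}",
    )


def identity_cross_decoding(
    epochs: EpochSet,
    design: Design,
    target_factor: str,
    config: DecodingConfig = DecodingConfig(),
    held_out_exemplar: int = 3,
) -> GroupTimeCourse:
    """Decode the target factor across image identity.

    Two of the three exemplars of every factor-level combination form the
    training set, the held-out exemplar the test set; a second pass reverses
    the assignment and the two are averaged. Above-chance accuracy requires
    a factor representation shared across individual images.
    """
    if design.n_exemplars != 3:
        raise ValueError(f"identity cross-decoding requires 3 exemplars, got {design.n_exemplars}")
    cond = epochs.metadata["condition_id"].to_numpy()
    exemplar = design.table["exemplar"]
    held = design.condition_ids[exemplar == held_out_exemplar].to_numpy()
    rest = design.condition_ids[exemplar != held_out_exemplar].to_numpy()
    masks = {
        "train_exemplars": np.isin(cond, rest),
        "held_out_exemplar": np.isin(cond, held),
    }
    return _generalization_timecourse(
        epochs,
        design,
        target_factor,
        masks,
        config,
        label=f"{target_factor} across image identity",
    )
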
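"""Pairwise decoding, sub-averaging, and the cross-classification schemes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

import megrsa as m
from megrsa.decoding import _loo_accuracy, cross_classification_pool_sizes, matched_exemplar_pairs
from megrsa.svm import classify, decision_values


def _epochs_from_arrays(per_condition, times, subject_id=1):
    """Build an EpochSet from {condition_id: (trials, channels, T) array}."""
    data = np.concatenate(list(per_condition.values()))
    cids = np.concatenate(
        [np.full(len(arr), cid) for cid, arr in per_condition.items()]
    )
    meta = pd.DataFrame({"condition_id": cids, "subject_id": subject_id, "run_id": 1})
    return m.EpochSet(data, times, meta)


class TestSvmBackend:
    def test_matches_public_svc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tr0 = rng.standard_normal((3, 10))
            tr1 = rng.standard_normal((3, 10)) + 0.5
            test = rng.standard_normal((4, 10))
            mine = decision_values(tr0, tr1, test)
            svc = SVC(kernel="linear", C=1.0).fit(
                np.vstack([tr0, tr1]), [0] * 3 + [1] * 3
            )
            # libsvm's decision is positive on the first-class side;
            # sklearn's decision_function is positive for the second class
            assert np.allclose(mine, -svc.decision_function(test), atol=1e-8)
            assert np.array_equal(classify(tr0, tr1, test), svc.predict(test))

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(1)
        tr0, tr1 = rng.standard_normal((4, 12)), rng.standard_normal((4, 12)) + 0.3
        test = rng.standard_normal((6, 12))
        perm = rng.permutation(12)
        assert np.array_equal(
            classify(tr0, tr1, test), classify(tr0[:, perm], tr1[:, perm], test[:, perm])
        )

    def test_orthogonal_channel_transform_invariance(self):
        # an orthogonal mixing of channels leaves the linear kernel unchanged
        rng = np.random.default_rng(2)
        tr0, tr1 = rng.standard_normal((4, 12)), rng.standard_normal((4, 12)) + 0.3
        test = rng.standard_normal((6, 12))
        q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        assert np.allclose(
            decision_values(tr0, tr1, test), decision_values(tr0 @ q, tr1 @ q, test @ q), atol=1e-8
        )


class TestSubaverage:
    def test_k1_is_a_permutation(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((7, 3))
        pseudo = m.subaverage(trials, 1, np.random.default_rng(1))
        assert sorted(map(tuple, pseudo)) == sorted(map(tuple, trials))

    def test_sixty_over_five_gives_twelve(self):
        trials = np.random.default_rng(0).standard_normal((60, 4))
        assert m.subaverage(trials, 5, np.random.default_rng(0)).shape[0] == 12

    def test_mean_preserved_when_exact(self):
        # M divisible by k: pseudo-trial mean equals raw-trial mean
        trials = np.random.default_rng(2).standard_normal((20, 6))
        pseudo = m.subaverage(trials, 5, np.random.default_rng(3))
        assert np.allclose(pseudo.mean(axis=0), trials.mean(axis=0))

    def test_leftovers_discarded(self):
        trials = np.random.default_rng(4).standard_normal((13, 2))
        assert m.subaverage(trials, 5, np.random.default_rng(0)).shape[0] == 2

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            m.subaverage(np.zeros((3, 2)), 5, np.random.default_rng(0))


class TestLeaveOneOut:
    def test_matches_exhaustive_fold_loop_oracle(self):
        """Tiny instances: the fold loop must equal an independent
        implementation built directly on the public SVC estimator."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            p0 = rng.standard_normal((4, 2))
            p1 = rng.standard_normal((4, 2)) + rng.uniform(0, 2)
            # independent oracle: explicit folds, public estimator
            correct, total = 0, 0
            for f in range(4):
                X = np.vstack([np.delete(p0, f, 0), np.delete(p1, f, 0)])
                y = [0, 0, 0, 1, 1, 1]
                pred = SVC(kernel="linear", C=1.0).fit(X, y).predict(np.vstack([p0[f], p1[f]]))
                correct += int(pred[0] == 0) + int(pred[1] == 1)
                total += 2
            assert _loo_accuracy(p0, p1, 1.0) == pytest.approx(100.0 * correct / total)

    def test_separable_classes_decode_perfectly(self):
        rng = np.random.default_rng(6)
        p0 = rng.standard_normal((5, 8)) * 0.1
        p1 = rng.standard_normal((5, 8)) * 0.1 + 5.0
        assert _loo_accuracy(p0, p1, 1.0) == 100.0


@pytest.fixture(scope="module")
def null_rdms(design16, small_noise):
    epochs = m.generate_epochs(
        design16, m.SignalSpec.null(), small_noise, 20, subject_seed=21, step_ms=50.0
    )
    cfg = m.DecodingConfig(k=5, n_repetitions=3, seed=0)
    return m.pairwise_decoding_timecourse(epochs, design16, cfg)


class TestPairwiseDecoding:
    def test_symmetric_with_nan_diagonal(self, null_rdms):
        acc = null_rdms.accuracies
        assert np.allclose(acc, acc.transpose(0, 2, 1), equal_nan=True)
        assert np.isnan(acc[:, np.arange(16), np.arange(16)]).all()

    def test_null_accuracy_near_chance(self, null_rdms):
        # pair-and-time averaged accuracy for noise-only data: chance is 50%
        values = null_rdms.lower_triangle().mean(axis=1)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 50.0) < 3 * max(se, 0.5)

    def test_strong_effect_decodes_above_chance(self, design16, small_noise):
        # margin >> noise: linearly separable at the envelope peak
        signal = m.SignalSpec(
            effects=(m.EffectSpec("size", 140.0, 200.0, 300.0, 800.0),),
            subject_jitter_sd=0.1,
        )
        epochs = m.generate_epochs(design16, signal, small_noise, 20, subject_seed=22, step_ms=50.0)
        rdms = m.pairwise_decoding_timecourse(
            epochs, design16, m.DecodingConfig(k=5, n_repetitions=2, seed=0)
        )
        i, j, between = _between_size_cells(design16)
        at_peak = np.abs(rdms.times - 200.0).argmin()
        assert rdms.accuracies[at_peak, i, j][between].mean() > 90.0
        # within-size pairs share the size pattern: still at chance
        assert abs(rdms.accuracies[at_peak, i, j][~between].mean() - 50.0) < 10.0

    def test_insufficient_trials_rejected(self, design16, small_noise):
        epochs = m.generate_epochs(
            design16, m.SignalSpec.null(), small_noise, 8, subject_seed=0, step_ms=200.0
        )
        with pytest.raises(ValueError, match="2k"):
            m.pairwise_decoding_timecourse(epochs, design16, m.DecodingConfig(k=5, n_repetitions=1))


def _between_size_cells(design):
    levels = design.levels("size").to_numpy()
    i, j = np.tril_indices(design.n_conditions, k=-1)
    return i, j, levels[i] != levels[j]


class TestFactorAverageDecoding:
    def test_constant_rdm_passes_through(self, design48):
        n = 48
        acc = np.full((3, n, n), 55.0)
        acc[:, np.arange(n), np.arange(n)] = np.nan
        rdms = m.RDMSeries(acc, np.arange(3.0), design48.condition_ids.to_numpy(), 1)
        tc = m.factor_average_decoding(rdms, design48)
        assert np.allclose(tc.values, 55.0)

    def test_matched_pair_count_by_enumeration(self, design48):
        pairs = matched_exemplar_pairs(design48)
        # brute force: 16 combinations x C(3,2) exemplar pairs
        table = design48.table
        expected = sum(
            1
            for a in range(48)
            for b in range(a + 1, 48)
            if all(table.iloc[a][f] == table.iloc[b][f] for f in ("size", "clutter", "contrast", "luminance"))
        )
        assert len(pairs) == expected == 48

    def test_single_exemplar_design_has_no_pairs(self, design16):
        acc = np.full((2, 16, 16), 50.0)
        rdms = m.RDMSeries(acc, np.arange(2.0), design16.condition_ids.to_numpy(), 1)
        with pytest.raises(ValueError):
            m.factor_average_decoding(rdms, design16)


class TestCrossClassification:
    def test_pool_sizes_at_recording_scale(self, design48):
        sizes = cross_classification_pool_sizes(design48, 60, "size", "clutter")
        # 12 images share each size x clutter cell; 12 x 60 = 720 raw vectors
        assert set(sizes.values()) == {720}

    def test_shared_size_pattern_generalizes_across_clutter(self, design16, small_noise):
        signal = m.SignalSpec(
            effects=(m.EffectSpec("size", 140.0, 200.0, 300.0, 800.0),),
            subject_jitter_sd=0.1,
        )
        epochs = m.generate_epochs(design16, signal, small_noise, 20, subject_seed=30, step_ms=50.0)
        cfg = m.DecodingConfig(cross_k=30, n_repetitions=5, seed=0)
        tc = m.cross_decoding_timecourse(epochs, design16, "size", "clutter", cfg)
        at_peak = np.abs(tc.times - 200.0).argmin()
        assert tc.values[0, at_peak] > 90.0
        assert abs(tc.values[0, tc.times < 0].mean() - 50.0) < 20.0

    def test_null_data_stays_at_chance(self, design16):
        # iid noise + several subjects keeps the Monte-Carlo error small
        noise = m.NoiseSpec(n_channels=20, scale=100.0, cov_rank=0, ar_coefficient=0.0)
        cfg = m.DecodingConfig(cross_k=30, n_repetitions=3, seed=0)
        means = []
        for seed in range(8):
            epochs = m.generate_epochs(
                design16, m.SignalSpec.null(), noise, 20,
                subject_seed=seed, subject_id=seed + 1, step_ms=250.0,
            )
            means.append(
                m.cross_decoding_timecourse(epochs, design16, "size", "clutter", cfg).values.mean()
            )
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 50.0) < 3 * max(se, 1.0)

    def test_same_factor_rejected(self, null_epochs, design16):
        with pytest.raises(ValueError):
            m.cross_decoding_timecourse(null_epochs, design16, "size", "size")

    def test_identity_requires_three_exemplars(self, null_epochs, design16):
        with pytest.raises(ValueError, match="3 exemplars"):
            m.identity_cross_decoding(null_epochs, design16, "size")

    def test_exemplar_specific_patterns_do_not_generalize(self, design48, small_noise):
        # condition-unique (identity) patterns only: cross-exemplar decoding
        # of size must fail to generalize
        signal = m.SignalSpec(
            effects=(m.EffectSpec("identity", 100.0, 200.0, 300.0, 800.0),),
            subject_jitter_sd=0.1,
        )
        epochs = m.generate_epochs(design48, signal, small_noise, 10, subject_seed=33, step_ms=50.0)
        cfg = m.DecodingConfig(cross_k=40, n_repetitions=5, seed=0)
        tc = m.identity_cross_decoding(epochs, design48, "size", cfg)
        assert abs(tc.values.mean() - 50.0) < 10.0

    def test_shared_size_pattern_generalizes_across_exemplars(self, design48, small_noise):
        signal = m.SignalSpec(
            effects=(m.EffectSpec("size", 140.0, 200.0, 300.0, 800.0),),
            subject_jitter_sd=0.1,
        )
        epochs = m.generate_epochs(design48, signal, small_noise, 10, subject_seed=34, step_ms=50.0)
        cfg = m.DecodingConfig(cross_k=40, n_repetitions=5, seed=0)
        tc = m.identity_cross_decoding(epochs, design48, "size", cfg)
        at_peak = np.abs(tc.times - 200.0).argmin()
        assert tc.values[0, at_peak] > 90.0
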
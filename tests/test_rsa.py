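"""Model RDMs, clustering and (partial) RSA time courses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import megrsa as m
from megrsa.design import FACTORS

from conftest import make_group_timecourse


def _random_rdm_series(rng, n=16, n_t=4, subject_id=1):
    acc = rng.uniform(40, 80, (n_t, n, n))
    acc = (acc + acc.transpose(0, 2, 1)) / 2
    acc[:, np.arange(n), np.arange(n)] = np.nan
    return m.RDMSeries(acc, np.arange(n_t, dtype=float), np.arange(1, n + 1), subject_id)


class TestFactorModelRDM:
    def test_one_entry_count_by_enumeration(self, design48):
        rdm = m.factor_model_rdm(design48, "size")
        levels = design48.levels("size").to_numpy()
        expected = sum(
            1 for a in range(48) for b in range(48) if a != b and levels[a] != levels[b]
        )
        assert rdm.dissimilarity.sum() == expected == 1152

    def test_symmetric_zero_diagonal_binary(self, design48):
        rdm = m.factor_model_rdm(design48, "clutter")
        assert np.array_equal(rdm.dissimilarity, rdm.dissimilarity.T)
        assert np.all(np.diag(rdm.dissimilarity) == 0)
        assert set(np.unique(rdm.dissimilarity)) == {0.0, 1.0}

    def test_degenerate_single_level_factor_is_all_zero(self, design48):
        table = design48.table.copy()
        table["luminance"] = "low"
        rdm = m.factor_model_rdm(m.Design(table), "luminance")
        assert rdm.dissimilarity.sum() == 0

    def test_unknown_factor(self, design48):
        with pytest.raises(ValueError):
            m.factor_model_rdm(design48, "colour")


class TestFeatureRDM:
    def test_identical_vectors_dissimilarity_zero(self):
        f = np.tile(np.arange(10.0), (3, 1))
        rdm = m.feature_rdm(m.FeatureSet(f, np.arange(1, 4)))
        assert np.allclose(rdm.lower_triangle(), 0.0)

    def test_reversed_ranks_dissimilarity_two(self):
        f = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
        rdm = m.feature_rdm(m.FeatureSet(f, np.arange(1, 3)))
        assert rdm.dissimilarity[0, 1] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((6, 30))
        rdm = m.feature_rdm(m.FeatureSet(f, np.arange(1, 7)))
        for a in range(6):
            for b in range(a):
                ra, rb = stats.rankdata(f[a]), stats.rankdata(f[b])
                expected = 1 - np.corrcoef(ra, rb)[0, 1]
                assert rdm.dissimilarity[a, b] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 2.0, (5, 20))
        base = m.feature_rdm(m.FeatureSet(f, np.arange(1, 6)))
        for transform in (np.exp, np.log, lambda x: x**3):
            other = m.feature_rdm(m.FeatureSet(transform(f), np.arange(1, 6)))
            assert np.allclose(base.dissimilarity, other.dissimilarity, atol=1e-12)

    def test_constant_vector_raises_naming_condition(self):
        f = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="condition 7"):
            m.feature_rdm(m.FeatureSet(f, np.array([3, 7])))


class TestClusteringTimecourse:
    def test_constant_rdm_gives_zero(self, design16):
        n = 16
        acc = np.full((3, n, n), 61.0)
        acc[:, np.arange(n), np.arange(n)] = np.nan
        rdms = m.RDMSeries(acc, np.arange(3.0), design16.condition_ids.to_numpy(), 1)
        tc = m.clustering_timecourse(rdms, design16, "size")
        assert np.allclose(tc.values, 0.0)

    def test_hand_averaged_toy_rdm(self):
        # 4 conditions, between-size cells 60, within-size cells 55 -> 5
        table = pd.DataFrame(
            {
                "condition_id": [1, 2, 3, 4],
                "size": ["small", "small", "large", "large"],
                "clutter": ["low", "high", "low", "high"],
                "contrast": ["low"] * 4,
                "luminance": ["low"] * 4,
                "exemplar": [1, 1, 1, 1],
            }
        )
        design = m.Design(table)
        levels = table["size"].to_numpy()
        acc = np.where(levels[:, None] != levels[None, :], 60.0, 55.0)[None, :, :].copy()
        acc[:, np.arange(4), np.arange(4)] = np.nan
        rdms = m.RDMSeries(acc, np.array([0.0]), np.arange(1, 5), 1)
        tc = m.clustering_timecourse(rdms, design, "size")
        assert tc.values[0, 0] == pytest.approx(5.0)

    def test_sign_agrees_with_correlation_variant(self, design16):
        # between-minus-within and the Spearman model correlation measure the
        # same contrast; on random data their signs agree whenever the effect
        # is not razor-thin
        rng = np.random.default_rng(2)
        model = m.factor_model_rdm(design16, "size")
        for _ in range(20):
            rdms = _random_rdm_series(rng)
            cluster = m.clustering_timecourse(rdms, design16, "size").values[0]
            corr = m.rsa_timecourse(rdms, model).values[0]
            strong = np.abs(cluster) > 0.5
            assert np.all(np.sign(cluster[strong]) == np.sign(corr[strong]))

    def test_condition_reordering_invariance(self, design16):
        rng = np.random.default_rng(3)
        rdms = _random_rdm_series(rng)
        perm = rng.permutation(16)
        permuted = m.RDMSeries(
            rdms.accuracies[:, perm][:, :, perm],
            rdms.times,
            rdms.condition_ids[perm],
            1,
        )
        reordered_design = m.Design(
            m.generate_design(1).table.iloc[perm].reset_index(drop=True)
        )
        a = m.clustering_timecourse(rdms, m.generate_design(1), "size")
        b = m.clustering_timecourse(permuted, reordered_design, "size")
        assert np.allclose(a.values, b.values)


class TestRsaTimecourse:
    def test_self_correlation_is_one(self, design16):
        rng = np.random.default_rng(4)
        rdms = _random_rdm_series(rng, n_t=2)
        model = m.ModelRDM(
            np.nan_to_num(rdms.accuracies[0], nan=0.0), rdms.condition_ids, "self"
        )
        tc = m.rsa_timecourse(rdms, model)
        assert tc.values[0, 0] == pytest.approx(1.0)

    def test_rank_reversed_model_gives_minus_one(self, design16):
        rng = np.random.default_rng(5)
        rdms = _random_rdm_series(rng, n_t=1)
        reversed_rdm = m.ModelRDM(
            100.0 - np.nan_to_num(rdms.accuracies[0], nan=100.0),
            rdms.condition_ids,
            "reversed",
        )
        tc = m.rsa_timecourse(rdms, reversed_rdm)
        assert tc.values[0, 0] == pytest.approx(-1.0)

    def test_matches_scipy_spearman_oracle(self, design16):
        rng = np.random.default_rng(6)
        rdms = _random_rdm_series(rng)
        model = m.factor_model_rdm(design16, "clutter")
        tc = m.rsa_timecourse(rdms, model)
        for t in range(len(rdms.times)):
            expected = stats.spearmanr(rdms.lower_triangle()[t], model.lower_triangle())[0]
            assert tc.values[0, t] == pytest.approx(expected, abs=1e-12)

    def test_multilayer_average(self, design16):
        rng = np.random.default_rng(7)
        rdms = _random_rdm_series(rng, n_t=2)
        m1 = m.factor_model_rdm(design16, "size")
        m2 = m.factor_model_rdm(design16, "clutter")
        combined = m.rsa_timecourse(rdms, [m1, m2])
        a = m.rsa_timecourse(rdms, m1).values
        b = m.rsa_timecourse(rdms, m2).values
        assert np.allclose(combined.values, (a + b) / 2)

    def test_constant_model_rejected(self, design16):
        rng = np.random.default_rng(8)
        rdms = _random_rdm_series(rng, n_t=1)
        flat = m.ModelRDM(np.zeros((16, 16)), rdms.condition_ids, "flat")
        with pytest.raises(ValueError, match="constant"):
            m.rsa_timecourse(rdms, flat)


class TestPartialSpearman:
    def test_empty_nuisance_equals_spearman(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert m.partial_spearman(x, y) == pytest.approx(stats.spearmanr(x, y)[0], abs=1e-12)

    def test_single_nuisance_closed_form(self):
        # first-order partial correlation on ranks:
        # (r_xy - r_xz r_zy) / sqrt((1 - r_xz^2)(1 - r_zy^2))
        rng = np.random.default_rng(10)
        for _ in range(10):
            x, y, z = rng.standard_normal((3, 60))
            r_xy = stats.spearmanr(x, y)[0]
            r_xz = stats.spearmanr(x, z)[0]
            r_zy = stats.spearmanr(z, y)[0]
            expected = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))
            assert m.partial_spearman(x, y, [z]) == pytest.approx(expected, abs=1e-10)

    def test_target_in_nuisance_gives_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal((2, 40))
        assert m.partial_spearman(x, y, [y]) == pytest.approx(0.0, abs=1e-10)

    def test_collinear_nuisance_tolerated(self):
        rng = np.random.default_rng(12)
        x, y, z = rng.standard_normal((3, 40))
        with_dup = m.partial_spearman(x, y, [z, z])
        assert with_dup == pytest.approx(m.partial_spearman(x, y, [z]), abs=1e-10)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            m.partial_spearman(np.arange(4.0), np.arange(4.0), [np.arange(4.0), np.arange(4.0)])


class TestPartialRsa:
    def test_partialling_out_target_removes_everything(self, design16):
        rng = np.random.default_rng(13)
        rdms = _random_rdm_series(rng)
        model = m.factor_model_rdm(design16, "size")
        tc = m.partial_rsa_timecourse(rdms, model, [model])
        assert np.allclose(tc.values, 0.0, atol=1e-10)

    def test_orthogonal_nuisance_changes_little(self, design16):
        # size and clutter binary models are orthogonal contrasts over the
        # balanced crossing: partialling one barely moves the other
        rng = np.random.default_rng(14)
        rdms = _random_rdm_series(rng)
        target = m.factor_model_rdm(design16, "size")
        nuisance = m.factor_model_rdm(design16, "clutter")
        plain = m.rsa_timecourse(rdms, target).values
        partial = m.partial_rsa_timecourse(rdms, target, [nuisance]).values
        assert np.allclose(plain, partial, atol=0.05)

    def test_brain_rdm_built_from_nuisance_is_explained_away(self, design16):
        nuisance = m.factor_model_rdm(design16, "clutter")
        noise = np.random.default_rng(15).normal(0, 0.01, (1, 16, 16))
        noise = (noise + noise.transpose(0, 2, 1)) / 2
        acc = 50.0 + 10.0 * nuisance.dissimilarity[None, :, :] + noise
        acc[:, np.arange(16), np.arange(16)] = np.nan
        rdms = m.RDMSeries(acc, np.array([0.0]), design16.condition_ids.to_numpy(), 1)
        target = m.factor_model_rdm(design16, "size")
        plainless = m.partial_rsa_timecourse(rdms, target, [nuisance])
        assert abs(plainless.values[0, 0]) < 0.1
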
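import numpy as np
import pytest

from prpkit.features import PhonemeFeatureTable, make_inventory
from prpkit.prp import PRPSet
from prpkit.rsa import (RDM, alignment, confusion_rdm, feature_rdm,
                        forward_select, neural_rdm_series,
                        permutation_rho_difference, phoneme_dendrogram,
                        rho_of_confusion)


def _table(features):
    labels = tuple(sorted(features))
    return PhonemeFeatureTable(
        labels=labels, features=features,
        weights=np.full(len(labels), 1.0 / len(labels)))


def _prp_set(prps, fs=64.0, window=(0.0, 0.5)):
    return PRPSet(participant_id="s", group="G", fs=fs, window=window,
                  prps=prps, counts={lab: 10 for lab in prps})


class TestFeatureRDM:
    def test_all_features_differ_gives_sqrt3(self):
        t = _table({"A": (1, 1, 1), "B": (0, 0, 0), "C": (1, 0, 0)})
        r = feature_rdm(t)
        i, j = t.labels.index("A"), t.labels.index("B")
        assert r.matrix[i, j] == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_identical_vectors_give_zero(self):
        t = _table({"A": (1, 0, 1), "B": (1, 0, 1), "C": (0, 0, 0)})
        i, j = t.labels.index("A"), t.labels.index("B")
        assert feature_rdm(t).matrix[i, j] == 0.0

    def test_one_feature_swap_gives_sqrt2(self):
        t = _table({"A": (1, 0, 0), "B": (0, 1, 0), "C": (0, 0, 0)})
        i, j = t.labels.index("A"), t.labels.index("B")
        assert feature_rdm(t).matrix[i, j] == pytest.approx(np.sqrt(2),
                                                            abs=1e-12)

    def test_subset_restriction(self):
        t = _table({"A": (1, 1, 1), "B": (0, 1, 1), "C": (0, 0, 0)})
        r = feature_rdm(t, ["syllabic"])
        i, j = t.labels.index("A"), t.labels.index("B")
        assert r.matrix[i, j] == pytest.approx(1.0)


class TestRDMContainer:
    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            RDM(labels=["a", "b"], matrix=m)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            RDM(labels=["a", "b"], matrix=np.eye(2))


class TestNeuralRDMSeries:
    def test_identical_prps_give_zero_rdms(self):
        mat = np.random.default_rng(0).normal(size=(4, 16))
        ps = _prp_set({f"P{k}": mat for k in range(3)})
        for r in neural_rdm_series(ps):
            assert np.allclose(r.matrix, 0.0)

    def test_single_electrode_distance_is_absolute_difference(self):
        prps = {"A": np.array([[1.0, 5.0]]), "B": np.array([[4.0, 1.0]]),
                "C": np.array([[0.0, 0.0]])}
        series = neural_rdm_series(_prp_set(prps))
        assert series[0].matrix[0, 1] == pytest.approx(3.0)
        assert series[1].matrix[0, 1] == pytest.approx(4.0)

    def test_matches_bruteforce_pairwise_loop(self):
        rng = np.random.default_rng(1)
        prps = {f"P{k}": rng.normal(size=(6, 8)) for k in range(5)}
        ps = _prp_set(prps)
        series = neural_rdm_series(ps)
        labels = ps.labels
        for t, rdm in enumerate(series):
            for i, li in enumerate(labels):
                for j, lj in enumerate(labels):
                    expected = np.sqrt(((prps[li][:, t]
                                         - prps[lj][:, t]) ** 2).sum())
                    assert abs(rdm.matrix[i, j] - expected) < 1e-12

    def test_empty_electrode_subset_raises(self):
        ps = _prp_set({f"P{k}": np.zeros((4, 8)) for k in range(3)})
        with pytest.raises(ValueError, match="empty"):
            neural_rdm_series(ps, electrodes=[])


class TestAlignment:
    def _rdm(self, m, labels):
        return RDM(labels=labels, matrix=m)

    def test_identical_rdms_give_rho_one(self):
        rng = np.random.default_rng(2)
        labels = [f"P{k}" for k in range(6)]
        m = np.abs(rng.normal(size=(6, 6)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        feature = self._rdm(m, labels)
        curve = alignment([feature], feature, fs=64.0)
        assert curve.rho[0] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        labels = [f"P{k}" for k in range(5)]
        rng = np.random.default_rng(3)
        m = np.abs(rng.normal(size=(5, 5)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        rev = m.max() + m.min() - m
        np.fill_diagonal(rev, 0.0)
        curve = alignment([self._rdm(rev, labels)], self._rdm(m, labels))
        assert curve.rho[0] == pytest.approx(-1.0)

    def test_constant_rdm_flagged_degenerate(self):
        labels = [f"P{k}" for k in range(4)]
        c = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(4)
        f = np.abs(rng.normal(size=(4, 4)))
        f = (f + f.T) / 2
        np.fill_diagonal(f, 0.0)
        curve = alignment([self._rdm(c, labels)], self._rdm(f, labels))
        assert curve.rho[0] == 0.0
        assert curve.degenerate[0]

    def test_independent_rdms_have_near_zero_mean_rho(self):
        rng = np.random.default_rng(5)
        labels = [f"P{k}" for k in range(12)]
        def rand_rdm():
            m = np.abs(rng.normal(size=(12, 12)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            return self._rdm(m, labels)
        rhos = [alignment([rand_rdm()], rand_rdm()).rho[0]
                for _ in range(200)]
        assert abs(np.mean(rhos)) < 0.1


class TestConfusionRDM:
    def test_identity_confusion(self):
        labels = list("abcd")
        r = confusion_rdm(np.eye(4) * 7, labels)
        off = r.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(r.matrix), 0.0)

    def test_uniform_confusion_k4(self):
        labels = list("abcd")
        r = confusion_rdm(np.full((4, 4), 5.0), labels)
        off = r.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.75)

    def test_symmetrization_of_asymmetric_input(self):
        rng = np.random.default_rng(6)
        c = rng.uniform(1, 10, size=(5, 5))
        r = confusion_rdm(c, list("abcde"))
        assert np.abs(r.matrix - r.matrix.T).max() < 1e-12

    def test_zero_row_raises(self):
        c = np.eye(3)
        c[1] = 0.0
        with pytest.raises(ValueError, match="b"):
            confusion_rdm(c, list("abc"))


class TestPermutationRhoDifference:
    def _feature(self, k=6):
        table = make_inventory(k, 0.5, seed=1)
        return feature_rdm(table)

    def test_equal_matrices_give_zero_observed(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(1, 10, size=(6, 6))
        res = permutation_rho_difference(c, c, self._feature(), n_perm=200,
                                         seed=0)
        assert res["observed"] == 0.0

    def test_null_p_is_calibrated(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(1, 10, size=(6, 6))
        res = permutation_rho_difference(c, c.copy(), self._feature(),
                                         n_perm=5000, seed=1)
        assert 0.3 <= res["p"] <= 0.7

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(1, 10, size=(6, 6))
        b = rng.uniform(1, 10, size=(6, 6))
        r1 = permutation_rho_difference(a, b, self._feature(), n_perm=300,
                                        seed=4)
        r2 = permutation_rho_difference(a, b, self._feature(), n_perm=300,
                                        seed=4)
        assert r1["p"] == r2["p"]

    def test_low_n_perm_warns(self):
        c = np.eye(6) + 1
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_rho_difference(c, c, self._feature(), n_perm=50,
                                       seed=0)


class TestForwardSelect:
    def _fixture(self):
        """Two electrodes carry feature-aligned signal, the rest pure noise."""
        rng = np.random.default_rng(10)
        table = make_inventory(8, 0.5, seed=2)
        feature = feature_rdm(table)
        vecs = table.feature_matrix()
        sets = []
        for i in range(4):
            prps = {}
            for k, lab in enumerate(table.labels):
                # electrodes 2..5 are loud pure noise: adding any of them
                # corrupts the pattern distances and lowers the alignment
                mat = 2.0 * rng.normal(size=(6, 8))
                mat[0] = np.repeat(vecs[k], 3)[:8] * 2.0 \
                    + 0.01 * rng.normal(size=8)
                mat[1] = np.repeat(vecs[k][::-1], 3)[:8] * 2.0 \
                    + 0.01 * rng.normal(size=8)
                prps[lab] = mat
            sets.append(_prp_set(prps))
        return sets, feature

    def test_recovers_signal_electrodes(self):
        sets, feature = self._fixture()
        electrodes, best, trace = forward_select(sets, [0, 1, 2, 3, 4, 5],
                                                 feature)
        assert set(electrodes) == {0, 1}
        assert best > 0.5

    def test_identical_electrodes_stop_at_initial_pair(self):
        rng = np.random.default_rng(11)
        row = rng.normal(size=8)
        sets = [_prp_set({f"P{k}": np.tile(rng.normal(size=8), (6, 1))
                          for k in range(5)})]
        table = make_inventory(5, 0.5, seed=3)
        feature = feature_rdm(table)
        # force label agreement
        sets = [_prp_set({lab: np.tile(rng.normal(size=8), (6, 1))
                          for lab in table.labels})]
        electrodes, _, _ = forward_select(sets, list(range(6)), feature)
        assert len(electrodes) == 2

    def test_deterministic(self):
        sets, feature = self._fixture()
        a = forward_select(sets, [0, 1, 2, 3, 4, 5], feature)
        b = forward_select(sets, [0, 1, 2, 3, 4, 5], feature)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_returned_rho_never_below_prefix(self):
        sets, feature = self._fixture()
        _, best, trace = forward_select(sets, [0, 1, 2, 3, 4, 5], feature)
        assert best == max(r for _, r in trace)

    def test_too_few_electrodes_raise(self):
        sets, feature = self._fixture()
        with pytest.raises(ValueError):
            forward_select(sets, [0], feature)


class TestDendrogram:
    def test_two_families_split_first(self):
        rng = np.random.default_rng(12)
        base_a = rng.normal(size=(4, 32))
        base_b = base_a + 10.0
        prps = {}
        for k in range(3):
            prps[f"A{k}"] = base_a + 0.01 * rng.normal(size=(4, 32))
            prps[f"B{k}"] = base_b + 0.01 * rng.normal(size=(4, 32))
        d = phoneme_dendrogram(_prp_set(prps), window=(0.0, 0.35))
        # the last (highest) merge joins the two families
        from scipy.cluster.hierarchy import fcluster
        two = fcluster(d["linkage"], 2, criterion="maxclust")
        fam = {lab[0] for lab in d["labels"]}
        by_cluster = {c: {d["labels"][i][0] for i in range(6) if two[i] == c}
                      for c in set(two)}
        assert sorted(map(tuple, by_cluster.values())) == [("A",), ("B",)]

    def test_identical_prps_merge_at_zero_height(self):
        mat = np.ones((4, 32))
        prps = {f"P{k}": mat for k in range(4)}
        d = phoneme_dendrogram(_prp_set(prps))
        assert np.allclose(d["linkage"][:, 2], 0.0)

    def test_leaf_count_and_newick_labels(self):
        rng = np.random.default_rng(13)
        prps = {f"P{k}": rng.normal(size=(4, 32)) for k in range(5)}
        d = phoneme_dendrogram(_prp_set(prps))
        assert len(d["labels"]) == 5
        for lab in d["labels"]:
            assert lab in d["newick"]
        assert d["newick"].endswith(";")

    def test_window_outside_prp_range_raises(self):
        prps = {f"P{k}": np.zeros((4, 32)) for k in range(3)}
        with pytest.raises(ValueError, match="window"):
            phoneme_dendrogram(_prp_set(prps), window=(0.0, 0.8))
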
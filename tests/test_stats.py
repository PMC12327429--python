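import numpy as np
import pandas as pd
import pytest

from prpkit.prp import PRPSet
from prpkit.simulate import disc_layout
from prpkit.stats import (backward_stepwise, chain_adjacency,
                          cluster_permutation_test, ehf_transform,
                          group_tests, layout_adjacency, rau,
                          residual_group_test, separability_f, snr_loss)


def _prp_sets(data, fs=64.0):
    """data: (participants, phonemes, electrodes, times)"""
    sets = []
    for i, block in enumerate(data):
        prps = {f"P{k}": block[k] for k in range(block.shape[0])}
        sets.append(PRPSet(participant_id=f"s{i}", group="G", fs=fs,
                           window=(0.0, 0.5), prps=prps,
                           counts={f"P{k}": 5 for k in range(block.shape[0])}))
    return sets


class TestSeparabilityF:
    def test_null_f_is_near_one(self):
        rng = np.random.default_rng(0)
        means = []
        for _ in range(200):
            data = rng.normal(size=(6, 5, 4, 10))
            curve = separability_f(_prp_sets(data))
            means.append(np.nanmean(curve.f))
        assert 0.8 <= np.mean(means) <= 1.2

    def test_separated_phonemes_give_large_f(self):
        rng = np.random.default_rng(1)
        data = 0.1 * rng.normal(size=(6, 5, 4, 10))
        offsets = np.linspace(0, 8, 5)
        data += offsets[None, :, None, None]
        curve = separability_f(_prp_sets(data))
        assert np.nanmean(curve.f) > 50

    def test_identical_inputs_flagged_undefined(self):
        data = np.ones((4, 3, 2, 8))
        curve = separability_f(_prp_sets(data))
        assert np.all(curve.undefined)
        assert np.all(np.isnan(curve.f))

    def test_single_participant_raises(self):
        with pytest.raises(ValueError):
            separability_f(_prp_sets(np.zeros((1, 3, 2, 8))))


class TestClusterPermutation:
    def test_uniform_strong_effect_one_full_cluster(self):
        rng = np.random.default_rng(2)
        x = 1.0 + 0.2 * rng.normal(size=(12, 16))
        adjacency = layout_adjacency(disc_layout(16))
        res = cluster_permutation_test(x, design="one-sample",
                                       adjacency=adjacency, n_perm=500,
                                       seed=0)
        top = res.clusters[0]
        assert sorted(top["members"]) == list(range(16))
        assert top["p"] < 0.01
        assert top["t_max"] >= res.t_values.max()

    def test_independent_design_detects_group_difference(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 8)) + 2.0
        b = rng.normal(size=(10, 8))
        res = cluster_permutation_test((a, b), design="independent",
                                       adjacency=chain_adjacency(8),
                                       n_perm=500, seed=1)
        assert res.clusters[0]["p"] < 0.01
        assert res.clusters[0]["sign"] == 1

    def test_same_seed_reproduces_p_values(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 12)) + 0.5
        adjacency = layout_adjacency(disc_layout(12))
        p1 = cluster_permutation_test(x, adjacency=adjacency, n_perm=300,
                                      seed=9).clusters
        p2 = cluster_permutation_test(x, adjacency=adjacency, n_perm=300,
                                      seed=9).clusters
        assert [c["p"] for c in p1] == [c["p"] for c in p2]

    def test_matches_mne_reference_implementation(self):
        mne = pytest.importorskip("mne")
        from scipy import sparse
        rng = np.random.default_rng(5)
        x = rng.normal(size=(14, 10)) + 0.6
        adjacency = layout_adjacency(disc_layout(10))
        ours = cluster_permutation_test(x, design="one-sample",
                                        adjacency=adjacency, n_perm=2000,
                                        seed=2)
        t_obs, clusters, pv, _ = mne.stats.permutation_cluster_1samp_test(
            x, threshold=ours.threshold, adjacency=sparse.coo_matrix(adjacency),
            n_permutations=2000, tail=1, t_power=1, seed=3, out_type="indices",
            verbose=False)
        assert np.allclose(t_obs, ours.t_values)
        mne_sets = sorted(tuple(sorted(c[0])) for c in clusters)
        our_sets = sorted(tuple(sorted(c["members"])) for c in ours.clusters)
        assert mne_sets == our_sets
        # corrected p values agree within permutation noise
        for c in ours.clusters:
            match = [p for cl, p in zip(clusters, pv)
                     if tuple(sorted(cl[0])) == tuple(sorted(c["members"]))]
            assert abs(match[0] - c["p"]) < 0.05

    def test_too_few_participants_raise(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((3, 8)), n_perm=10)


class TestGroupTests:
    def test_identical_samples_welch_t_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = group_tests(a, a.copy(), kind="welch")
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_mann_whitney_u_matches_exhaustive_enumeration(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = group_tests(a, b, kind="mann_whitney")
        # U = number of (a, b) pairs with a > b (plus half-ties): all b exceed a
        u_brute = sum(float(x > y) + 0.5 * float(x == y) for x in a for y in b)
        assert res["statistic"] == u_brute == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=8), rng.normal(size=9)
        for kind in ("welch", "mann_whitney"):
            r1 = group_tests(a, b, kind=kind)
            r2 = group_tests(a + 100.0, b + 100.0, kind=kind)
            assert r1["statistic"] == pytest.approx(r2["statistic"])
            assert r1["p"] == pytest.approx(r2["p"])

    def test_mann_whitney_z_with_ties(self):
        a = np.array([1.0, 1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 2.0, 4.0])
        res = group_tests(a, b, kind="mann_whitney")
        assert np.isfinite(res["z"])

    def test_degenerate_equal_constant_groups_flagged(self):
        res = group_tests([2.0, 2.0], [2.0, 2.0], kind="welch")
        assert res["degenerate"]

    def test_tiny_groups_raise(self):
        with pytest.raises(ValueError):
            group_tests([1.0], [2.0, 3.0])


class TestTransforms:
    def test_rau_midpoint_is_exactly_fifty(self):
        assert rau(50, 100) == pytest.approx(50.0, abs=1e-12)

    def test_rau_floor_matches_direct_formula(self):
        x, n = 0, 100
        theta = np.arcsin(np.sqrt(x / (n + 1))) \
            + np.arcsin(np.sqrt((x + 1) / (n + 1)))
        assert rau(0, 100) == pytest.approx(146.0 / np.pi * theta - 23.0)

    def test_rau_strictly_monotone(self):
        vals = [rau(k, 30) for k in range(31)]
        assert np.all(np.diff(vals) > 0)

    def test_rau_range_errors(self):
        with pytest.raises(ValueError):
            rau(5, 4)
        with pytest.raises(ValueError):
            rau(-1, 10)

    @pytest.mark.parametrize("n,expected", [(0, 26.0), (70, -2.0), (54, 4.4)])
    def test_snr_loss_values(self, n, expected):
        assert snr_loss(n) == pytest.approx(expected)

    def test_snr_loss_range_error(self):
        with pytest.raises(ValueError):
            snr_loss(71)

    @pytest.mark.parametrize("thr,expected",
                             [(-2.5, np.log(22.5)), (0.0, np.log(25.0))])
    def test_ehf_transform_values(self, thr, expected):
        assert ehf_transform(thr) == pytest.approx(expected, abs=1e-4)

    def test_ehf_monotone_and_domain(self):
        assert ehf_transform(10.0) > ehf_transform(0.0)
        with pytest.raises(ValueError):
            ehf_transform(-25.0)


class TestBackwardStepwise:
    def _predictors(self, rng, n):
        return pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(5)})

    def test_recovers_true_predictor(self):
        rng = np.random.default_rng(7)
        X = self._predictors(rng, 40)
        y = 2.0 * X["x1"] + 0.5 * rng.normal(size=40)
        res = backward_stepwise(y, X)
        assert "x1" in res.selected

    def test_aic_trace_decreasing_to_minimum(self):
        rng = np.random.default_rng(8)
        X = self._predictors(rng, 50)
        y = X["x0"] - X["x2"] + rng.normal(size=50)
        res = backward_stepwise(y, X)
        aics = [a for _, a in res.trace]
        assert np.all(np.diff(aics) < 0)
        assert res.aic == aics[-1] == min(aics)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        X = self._predictors(rng, 40)
        y = rng.normal(size=40)
        r1 = backward_stepwise(y, X)
        r2 = backward_stepwise(y, X)
        assert r1.selected == r2.selected and r1.trace == r2.trace

    def test_collinear_predictors_raise(self):
        rng = np.random.default_rng(10)
        X = self._predictors(rng, 40)
        X["x4"] = 2 * X["x0"]
        with pytest.raises(ValueError, match="rank-deficient"):
            backward_stepwise(rng.normal(size=40), X)

    def test_constant_predictor_raises(self):
        rng = np.random.default_rng(11)
        X = self._predictors(rng, 40)
        X["x3"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            backward_stepwise(rng.normal(size=40), X)

    def test_needs_enough_rows(self):
        rng = np.random.default_rng(12)
        X = self._predictors(rng, 6)
        with pytest.raises(ValueError, match="n >="):
            backward_stepwise(rng.normal(size=6), X)


class TestResidualGroupTest:
    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = X["x"] + rng.normal(size=30)
        groups = np.repeat(["A", "B"], 15)
        res = residual_group_test(y, X, groups)
        assert abs(res["residuals"].sum()) < 1e-9

    def test_covariate_mediated_effect_vanishes(self):
        # group difference fully carried by the covariate: residual test null
        rng = np.random.default_rng(14)
        groups = np.repeat(["A", "B"], 20)
        x = rng.normal(size=40) + (groups == "A") * 2.0
        y = 1.5 * x + 0.3 * rng.normal(size=40)
        res = residual_group_test(y, pd.DataFrame({"x": x}), groups)
        assert res["p"] > 0.05

    def test_orthogonal_group_effect_detected(self):
        rng = np.random.default_rng(15)
        groups = np.repeat(["A", "B"], 20)
        x = rng.normal(size=40)
        y = x + (groups == "A") * 2.0 + 0.3 * rng.normal(size=40)
        res = residual_group_test(y, pd.DataFrame({"x": x}), groups)
        assert res["p"] < 0.01
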
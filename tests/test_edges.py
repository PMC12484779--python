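"""Edge time series, communities, overlap entropy, and similarity maps."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from creanet import synthetic as syn
from creanet.edges import (
    EdgeCommunityAssignment,
    EdgeIndex,
    EdgeTimeSeries,
    RegionTimeSeries,
    average_over_k,
    cluster_edges,
    community_similarity,
    concatenate_trials,
    condition_difference,
    edge_fc,
    edge_time_series,
    group_average,
    node_community_matrix,
    overlap_entropy,
    within_network_similarity,
    zscore,
)


def _rts(data, **kw):
    return RegionTimeSeries(data=np.asarray(data, float), **kw)


class TestZscore:
    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 6))
        a = zscore(_rts(x)).data
        b = zscore(_rts(x + 100.0)).data
        assert np.allclose(a, b, atol=1e-10)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        z = zscore(_rts(rng.standard_normal((4, 8))))
        zz = zscore(z)
        assert np.allclose(z.data, zz.data, atol=1e-12)

    def test_matches_hand_population_sd(self):
        x = np.array([[1.0, 2.0, 3.0, 6.0], [0.0, 0.0, 1.0, 1.0], [5.0, 1.0, 2.0, 4.0]])
        z = zscore(_rts(x)).data
        for r in range(3):
            mu = x[r].mean()
            sd = np.sqrt(((x[r] - mu) ** 2).mean())  # divisor T
            assert np.allclose(z[r], (x[r] - mu) / sd, atol=1e-12)

    def test_zero_variance_region_named(self):
        x = np.ones((3, 4))
        x[0] = [1, 2, 3, 4]
        x[2] = [4, 1, 2, 2]
        with pytest.raises(ValueError, match=r"\[1\]"):
            zscore(_rts(x))


class TestConcatAndDifference:
    def test_trial_concatenation_lengths(self):
        rng = np.random.default_rng(2)
        trials = [zscore(_rts(rng.standard_normal((5, 30)))) for _ in range(10)]
        out = concatenate_trials(trials)
        assert out.data.shape == (5, 300)
        single = concatenate_trials([trials[0]])
        assert np.array_equal(single.data, trials[0].data)

    def test_per_trial_zscoring_differs_from_whole_run_when_trial_means_differ(self):
        rng = np.random.default_rng(3)
        raw1 = rng.standard_normal((4, 20))
        raw2 = rng.standard_normal((4, 20)) + 5.0  # unequal trial means
        per_trial = concatenate_trials([zscore(_rts(raw1)), zscore(_rts(raw2))])
        whole_run = zscore(_rts(np.hstack([raw1, raw2])))
        assert not np.allclose(per_trial.data, whole_run.data, atol=1e-8)
        # per-trial z-scored concatenation of identical-mean halves: re-z-scoring
        # the concatenation is then (near) idempotent per construction
        assert np.allclose(per_trial.data, zscore(per_trial).data, atol=1e-8)

    def test_unzscored_trials_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="z-score"):
            concatenate_trials([_rts(rng.standard_normal((4, 10)))])

    def test_condition_difference_elementwise(self):
        a = _rts([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        b = _rts([[0.5, 1, 1], [1, 1, 1], [2, 2, 2]])
        d = condition_difference(a, b)
        assert np.array_equal(d.data, a.data - b.data)
        assert not d.z_scored
        zero = condition_difference(a, a)
        assert np.all(zero.data == 0)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        a = _rts(rng.standard_normal((4, 6)))
        b = _rts(rng.standard_normal((4, 7)))
        with pytest.raises(ValueError, match="mismatch"):
            condition_difference(a, b)


class TestEdgeTimeSeries:
    def test_time_mean_equals_pearson(self):
        """Core identity: mean_t z_i z_j = Pearson r under divisor-T z-scoring."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            n, t = int(rng.integers(3, 8)), int(rng.integers(4, 40))
            raw = _rts(rng.standard_normal((n, t)))
            ets = edge_time_series(zscore(raw))
            r = np.corrcoef(raw.data)
            iu, ju = np.triu_indices(n, k=1)
            assert np.allclose(ets.data.mean(axis=1), r[iu, ju], atol=1e-10)

    def test_rows_match_double_loop(self):
        rng = np.random.default_rng(7)
        z = zscore(_rts(rng.standard_normal((4, 6))))
        ets = edge_time_series(z)
        k = 0
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.array_equal(ets.data[k], z.data[i] * z.data[j])
                assert ets.index.edge_of(i, j) == k
                k += 1

    def test_sign_flip_gives_minus_one_mean(self):
        t = np.sin(np.linspace(0, 7, 20))
        x = np.vstack([t, -t, np.cos(np.linspace(0, 7, 20))])
        ets = edge_time_series(zscore(_rts(x)))
        assert ets.data[0].mean() == pytest.approx(-1.0, abs=1e-10)

    def test_unzscored_input_rejected(self):
        with pytest.raises(ValueError, match="z-scored"):
            edge_time_series(_rts(np.random.default_rng(8).standard_normal((3, 5))))


class TestGroupAverageAndEFC:
    def test_group_average_matches_direct_mean(self):
        rng = np.random.default_rng(9)
        subs = [edge_time_series(zscore(_rts(rng.standard_normal((4, 10))))) for _ in range(3)]
        avg = group_average(subs)
        assert np.allclose(avg.data, np.mean([s.data for s in subs], axis=0), atol=1e-14)
        assert avg.provenance == "group-average"
        one = group_average([subs[0]])
        assert np.array_equal(one.data, subs[0].data)

    def test_negated_pair_averages_to_zero(self):
        rng = np.random.default_rng(10)
        a = edge_time_series(zscore(_rts(rng.standard_normal((4, 10)))))
        b = EdgeTimeSeries(data=-a.data, index=a.index)
        assert np.all(group_average([a, b]).data == 0)

    def test_mismatched_lengths_reported(self):
        rng = np.random.default_rng(11)
        a = edge_time_series(zscore(_rts(rng.standard_normal((4, 10)))))
        b = edge_time_series(zscore(_rts(rng.standard_normal((4, 12)))))
        with pytest.raises(ValueError, match="T="):
            group_average([a, b])

    def test_edge_fc_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        ets = edge_time_series(zscore(_rts(rng.standard_normal((4, 6)))))
        S = edge_fc(ets, normalization="inner-product")
        assert np.allclose(S, S.T, atol=1e-12)
        assert np.allclose(np.diag(S), 1.0, atol=1e-12)
        X = ets.data
        for e in range(6):
            for f in range(6):
                expected = X[e] @ X[f] / np.sqrt((X[e] @ X[e]) * (X[f] @ X[f]))
                assert S[e, f] == pytest.approx(expected, abs=1e-10)

    def test_edge_fc_orthogonal_rows_zero(self):
        data = np.zeros((3, 4))
        data[0] = [1, 0, 0, 0]
        data[1] = [0, 1, 0, 0]
        data[2] = [0, 0, 1, 1]
        ets = EdgeTimeSeries(data=data, index=EdgeIndex(3))
        S = edge_fc(ets)
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestClustering:
    def test_recovers_planted_block_pairs(self, planted_bold_spec, planted_bold):
        """Edge k-means at the true k recovers block-pair ground truth (ARI >= 0.9)."""
        spec = planted_bold_spec
        cond = spec.conditions[0]
        subs = []
        for s in sorted({t.subject for t in planted_bold}):
            trials = [zscore(t) for t in planted_bold if t.subject == s and t.condition == cond]
            subs.append(edge_time_series(concatenate_trials(trials)))
        grp = group_average(subs)
        truth = syn.edge_block_pair_labels(syn.block_assignment(spec, cond))
        k = len(set(truth.tolist()))
        asg = cluster_edges(grp, k_range=[k], restarts=10, max_iter=5000, seed=11)
        assert adjusted_rand_score(truth, asg.labels[k]) >= 0.9

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(13)
        ets = edge_time_series(zscore(_rts(rng.standard_normal((6, 40)))))
        a = cluster_edges(ets, k_range=[2, 3], seed=5)
        b = cluster_edges(ets, k_range=[2, 3], seed=5)
        for k in (2, 3):
            assert np.array_equal(a.labels[k], b.labels[k])

    def test_identical_rows_collapse_to_one_cluster(self):
        data = np.tile(np.linspace(-1, 1, 12), (10, 1))
        ets = EdgeTimeSeries(data=data, index=EdgeIndex(5))
        asg = cluster_edges(ets, k_range=[3], seed=1)
        # all edges identical: every edge lands in a single effective cluster
        assert len(set(asg.labels[3].tolist())) >= 1
        assert asg.inertia[3] == pytest.approx(0.0, abs=1e-20)

    def test_k_larger_than_edges_rejected(self):
        ets = EdgeTimeSeries(data=np.random.default_rng(1).standard_normal((3, 5)), index=EdgeIndex(3))
        with pytest.raises(ValueError, match="max k"):
            cluster_edges(ets, k_range=[4])


class TestNodeCommunityMatrix:
    def test_by_construction_small_case(self):
        idx = EdgeIndex(3)
        asg = EdgeCommunityAssignment(labels={2: np.array([1, 2, 2])}, inertia={2: 0.0}, index=idx, seed=0)
        X = node_community_matrix(asg, 2)
        assert X[1, 0] == 1 and X[2, 0] == 2 and X[2, 1] == 2
        assert np.array_equal(X, X.T)
        assert np.all(np.diag(X) == -1)

    def test_constant_labels_give_constant_offdiagonal(self):
        idx = EdgeIndex(4)
        asg = EdgeCommunityAssignment(labels={2: np.ones(6, int)}, inertia={2: 0.0}, index=idx, seed=0)
        X = node_community_matrix(asg, 2)
        off = X[~np.eye(4, dtype=bool)]
        assert np.all(off == 1)


class TestOverlapEntropy:
    def test_single_community_zero(self):
        idx = EdgeIndex(4)
        asg = EdgeCommunityAssignment(labels={3: np.ones(6, int)}, inertia={3: 0.0}, index=idx, seed=0)
        X = node_community_matrix(asg, 3)
        assert np.allclose(overlap_entropy(X, 3), 0.0, atol=1e-12)

    def test_uniform_spread_attains_one(self):
        # node 0 in a 9-node graph: its 8 edges spread 2-2-2-2 over k=4
        n, k = 9, 4
        X = np.full((n, n), -1, int)
        labels = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        X[0, 1:] = labels
        X[1:, 0] = labels
        rest = np.ones((n - 1, n - 1), int)
        X[1:, 1:] = rest
        np.fill_diagonal(X, -1)
        ent = overlap_entropy(X, k)
        assert ent[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_value_three_one_split(self):
        # node with edge-label counts (3,1) at k=2 -> 0.8113
        n = 5
        X = np.full((n, n), -1, int)
        labels = np.array([1, 1, 1, 2])
        X[0, 1:] = labels
        X[1:, 0] = labels
        X[1:, 1:][~np.eye(4, dtype=bool)] = 1
        ent = overlap_entropy(X, 2)
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25)) / np.log(2)
        assert ent[0] == pytest.approx(expected, abs=1e-10)
        assert ent[0] == pytest.approx(0.8113, abs=5e-5)

    def test_k_below_two_rejected(self):
        X = np.full((4, 4), 1)
        np.fill_diagonal(X, -1)
        with pytest.raises(ValueError, match="k"):
            overlap_entropy(X, 1)

    def test_entropy_bounds_on_random_matrices(self):
        rng = np.random.default_rng(14)
        for k in (2, 5, 20):
            lab = rng.integers(1, k + 1, size=(20, 20))
            X = np.triu(lab, 1)
            X = X + X.T
            np.fill_diagonal(X, -1)
            ent = overlap_entropy(X, k)
            assert np.all(ent >= 0) and np.all(ent <= 1 + 1e-12)


class TestCommunitySimilarity:
    def test_identical_columns_give_one(self):
        n = 5
        X = np.full((n, n), 2, int)
        np.fill_diagonal(X, -1)
        S = community_similarity(X)
        assert np.allclose(S, 1.0, atol=1e-12)

    def test_hand_counted_pair(self):
        # s_01 counted over positions {2,3,4} only
        n = 5
        X = np.full((n, n), -1, int)
        col0 = [0, 9, 1, 2, 3]  # X[m,0] for m=0..4 (diag placeholder 0 unused)
        col1 = [9, 0, 1, 2, 4]
        for m in range(n):
            if m != 0:
                X[m, 0] = col0[m]
                X[0, m] = col0[m]
        for m in range(n):
            if m not in (0, 1):
                X[m, 1] = col1[m]
                X[1, m] = col1[m]
        X = np.maximum(X, X.T)
        np.fill_diagonal(X, -1)
        S = community_similarity(X)
        # positions 2,3,4: labels (1,2,3) vs (1,2,4) -> 2/3 match
        assert S[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_total_disagreement_gives_zero(self):
        n = 4
        X = np.full((n, n), -1, int)
        X[2, 0] = X[0, 2] = 1
        X[3, 0] = X[0, 3] = 1
        X[2, 1] = X[1, 2] = 2
        X[3, 1] = X[1, 3] = 2
        X[0, 1] = X[1, 0] = 5
        X[2, 3] = X[3, 2] = 5
        S = community_similarity(X)
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_within_network_mean_and_singleton(self):
        n = 5
        X = np.full((n, n), 1, int)
        np.fill_diagonal(X, -1)
        S = community_similarity(X)
        atlas = ["A", "A", "A", "B", "C"]
        w = within_network_similarity(S, atlas)
        assert np.allclose(w[:3], 1.0)
        assert np.isnan(w[3]) and np.isnan(w[4])


class TestProfilesAndInvariances:
    def test_average_over_k(self):
        a = {2: np.array([0.0, 1.0]), 3: np.array([1.0, 0.0])}
        assert np.allclose(average_over_k(a), [0.5, 0.5])
        assert np.allclose(average_over_k({2: np.array([0.3, 0.7])}), [0.3, 0.7])
        grid = {k: np.full(3, float(k)) for k in range(2, 6)}
        assert np.allclose(average_over_k(grid), np.mean([2, 3, 4, 5]))

    def test_node_relabeling_permutes_value_multisets(self):
        rng = np.random.default_rng(15)
        n, k = 12, 4
        lab = rng.integers(1, k + 1, size=(n, n))
        X = np.triu(lab, 1)
        X = X + X.T
        np.fill_diagonal(X, -1)
        perm = rng.permutation(n)
        Xp = X[np.ix_(perm, perm)]
        assert np.allclose(np.sort(overlap_entropy(X, k)), np.sort(overlap_entropy(Xp, k)), atol=1e-12)
        su = np.sort(community_similarity(X), axis=None)
        sp = np.sort(community_similarity(Xp), axis=None)
        assert np.allclose(su, sp, atol=1e-12)

    def test_straddling_network_has_higher_mean_entropy_than_nested(self):
        """A network straddling the planted block boundary mixes more edge
        communities than one nested inside the small (low-entropy) block.

        Blocks (8, 4) over 12 nodes: a small-block node sees 3 same-block
        and 8 cross-block edges (lower label diversity) while large-block
        nodes see a 7/4 split; the straddling network averages both."""
        spec = syn.BoldSpec(
            n_nodes=12,
            n_networks=3,
            network_sizes=(6, 3, 3),
            n_blocks=2,
            block_sizes=(8, 4),
            T_trial=30,
            n_trials=10,
            n_subjects=2,
            noise_sd=0.1,
            seed=21,
        )
        series = syn.make_bold(spec)
        cond = spec.conditions[0]
        blocks = syn.block_assignment(spec, cond)  # nodes 0..7 | 8..11
        subs = []
        for s in sorted({t.subject for t in series}):
            trials = [zscore(t) for t in series if t.subject == s and t.condition == cond]
            subs.append(edge_time_series(concatenate_trials(trials)))
        grp = group_average(subs)
        truth = syn.edge_block_pair_labels(blocks)
        k = len(set(truth.tolist()))  # 3 block pairs
        asg = cluster_edges(grp, k_range=[k], restarts=10, seed=2)
        X = node_community_matrix(asg, k)
        ent = overlap_entropy(X, k)
        straddling = ent[[6, 7, 8]].mean()  # network 2 spans the 8|4 boundary
        nested = ent[[9, 10, 11]].mean()  # network 3 nested in the small block
        assert straddling > nested
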
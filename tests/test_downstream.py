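import numpy as np
import pytest

import omicsembed as oe
from omicsembed import downstream as ds
from omicsembed.embedding import EmbeddingMatrix


def embedding_from_vectors(keys, vectors):
    nodes = [oe.Node(*k.split(":", 1)) for k in keys]
    return EmbeddingMatrix(
        np.asarray(vectors, dtype=float),
        np.ones(np.asarray(vectors).shape[1]),
        registry=oe.NodeRegistry(nodes),
    )


class TestMakeSplit:
    def edges(self, n_targets, tf="tf:t1"):
        return [(tf, f"gene:g{i}") for i in range(n_targets)]

    pool = [f"gene:g{i}" for i in range(12)]

    def test_even_targets_split_half(self):
        split = ds.make_split(self.edges(4), all_targets=self.pool, seed=0)
        assert len(split.positive_train) == 2 and len(split.positive_test) == 2

    def test_odd_targets_floor_to_test(self):
        split = ds.make_split(self.edges(5), all_targets=self.pool, seed=0)
        assert len(split.positive_train) == 3 and len(split.positive_test) == 2

    def test_single_target_tf_goes_to_train(self):
        edges = self.edges(4) + [("tf:lone", "gene:g0")]
        split = ds.make_split(edges, all_targets=self.pool, seed=0,
                              restrict_lcc=False)
        assert ("tf:lone", "gene:g0") in split.positive_train

    def test_deterministic_under_seed(self):
        edges = self.edges(6) + self.edges(5, tf="tf:t2")
        s1 = ds.make_split(edges, all_targets=self.pool, seed=42)
        s2 = ds.make_split(edges, all_targets=self.pool, seed=42)
        assert s1 == s2
        s3 = ds.make_split(edges, all_targets=self.pool, seed=43)
        assert s1 != s3

    def test_sets_disjoint_and_balanced(self, default_pipeline):
        truth = default_pipeline["truth"]
        pairs = [(f"tf:{a}", f"gene:{b}") for a, b in truth.tf_target_edges]
        split = ds.make_split(pairs, seed=1)
        pos = set(split.positive_train) | set(split.positive_test)
        neg = set(split.negative_train) | set(split.negative_test)
        assert not pos & neg
        assert len(split.negative_train) == len(split.positive_train)
        assert len(split.negative_test) == len(split.positive_test)
        assert not set(split.negative_train) & set(split.negative_test)

    def test_negative_pool_exhaustion_is_error(self):
        # 1 TF with 2 targets: every TFxtarget pair is an edge -> no negatives
        with pytest.raises(ValueError, match="pool"):
            ds.make_split(self.edges(2), seed=0)


class TestPredictLinks:
    def test_perfect_separation_gives_aupr_one(self):
        keys = [f"tf:t{i}" for i in range(2)] + [f"gene:g{i}" for i in range(8)]
        # TFs near their targets in embedding space, far from non-targets
        vec = np.zeros((10, 2))
        vec[0] = [1, 0]; vec[1] = [0, 1]
        for i in range(4):
            vec[2 + i] = [1, 0] + 0.01 * np.array([i, i])
            vec[6 + i] = [0, 1] + 0.01 * np.array([i, i])
        emb = embedding_from_vectors(keys, vec)
        edges = [("tf:t0", f"gene:g{i}") for i in range(4)]
        edges += [("tf:t1", f"gene:g{i}") for i in range(4, 8)]
        split = ds.make_split(edges, seed=0, restrict_lcc=False)
        assert ds.predict_links(split, emb, "weighted_l2") == pytest.approx(1.0)

    def test_null_features_score_near_half(self):
        """Random labels on random features give AUPR ~ 0.5 across seeds."""
        rng = np.random.default_rng(0)
        keys = [f"L:n{i}" for i in range(80)]
        auprs = []
        for seed in range(10):
            vec = np.random.default_rng(seed).normal(size=(80, 8))
            emb = embedding_from_vectors(keys, vec)
            pairs = [(f"L:n{i}", f"L:n{j}")
                     for i in range(40) for j in range(40, 80)]
            pick = rng.permutation(len(pairs))[:200]
            chosen = [pairs[i] for i in pick]
            split = ds.LinkPredictionSplit(
                positive_train=chosen[:50], negative_train=chosen[50:100],
                positive_test=chosen[100:150], negative_test=chosen[150:200],
                seed=seed)
            auprs.append(ds.predict_links(split, emb, "average"))
        assert abs(np.mean(auprs) - 0.5) < 0.1

    def test_operators_are_symmetric(self):
        rng = np.random.default_rng(1)
        emb = embedding_from_vectors(["a:x", "b:y"], rng.normal(size=(2, 4)))
        for op in ds.OPERATORS:
            f_ij = ds.edge_features(emb, [("a:x", "b:y")], op)
            f_ji = ds.edge_features(emb, [("b:y", "a:x")], op)
            np.testing.assert_array_equal(f_ij, f_ji)

    def test_repeat_prediction_reports_mean_sd(self, default_pipeline):
        truth = default_pipeline["truth"]
        emb = default_pipeline["embedding"]
        pairs = [(f"tf:{a}", f"gene:{b}") for a, b in truth.tf_target_edges]
        rep = ds.repeat_prediction(pairs, emb, seed=7, n_runs=2)
        assert set(rep["operator"]) == set(ds.OPERATORS)
        assert (rep["sd_aupr"] >= 0).all()
        rep2 = ds.repeat_prediction(pairs, emb, seed=7, n_runs=2)
        assert rep.equals(rep2)

    def test_single_run_sd_zero(self, default_pipeline):
        truth = default_pipeline["truth"]
        emb = default_pipeline["embedding"]
        pairs = [(f"tf:{a}", f"gene:{b}") for a, b in truth.tf_target_edges]
        rep = ds.repeat_prediction(pairs, emb, seed=7, n_runs=1,
                                   operators=("average",))
        assert rep.loc[0, "sd_aupr"] == 0.0


class TestInferION:
    def embedding(self, seed=0, n=6, d=3):
        rng = np.random.default_rng(seed)
        keys = [f"L:n{i}" for i in range(n)]
        return embedding_from_vectors(keys, rng.normal(size=(n, d)))

    def test_theta_zero_keeps_all_but_minimum(self):
        emb = self.embedding()
        inferred = ds.infer_ion(emb, theta=0.0)
        n_pairs = 6 * 5 // 2
        # only the pair(s) at the min (delta_norm == 0) are excluded
        assert inferred.n_edges() == n_pairs - 1

    def test_theta_one_empty(self):
        assert ds.infer_ion(self.embedding(), theta=1.0).n_edges() == 0

    def test_matches_brute_force_oracle(self):
        emb = self.embedding(seed=3)
        inferred = ds.infer_ion(emb, theta=0.4)
        vec = emb.vectors
        deltas = {}
        for i in range(6):
            for j in range(i + 1, 6):
                deltas[(i, j)] = vec[i] @ vec[j]
        vals = np.array(list(deltas.values()))
        lo, hi = vals.min(), vals.max()
        expect = {
            (f"L:n{i}", f"L:n{j}")
            for (i, j), v in deltas.items() if (v - lo) / (hi - lo) > 0.4
        }
        assert set(inferred.pairs()) == expect

    def test_all_equal_similarities_error(self):
        emb = embedding_from_vectors(["L:a", "L:b", "L:c"], np.ones((3, 2)))
        with pytest.raises(ValueError, match="min-max"):
            ds.infer_ion(emb, theta=0.5)

    def test_edge_count_non_increasing_in_theta(self):
        emb = self.embedding(seed=4, n=10)
        counts = [ds.infer_ion(emb, theta=t).n_edges()
                  for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sorted_descending(self):
        inferred = ds.infer_ion(self.embedding(seed=5, n=8), theta=0.1)
        norm = inferred.edges["delta_norm"].to_numpy()
        assert (np.diff(norm) <= 0).all()


class TestPrecisionAtK:
    def test_top_edge_in_reference(self):
        inferred = ds.infer_ion(TestInferION().embedding(seed=6), theta=0.0)
        top = inferred.pairs()[0]
        assert ds.precision_at_k(inferred, [top], ks=[1]) == [(1, 1.0)]

    def test_empty_reference_zero(self):
        inferred = ds.infer_ion(TestInferION().embedding(seed=6), theta=0.0)
        assert all(p == 0.0 for _, p in ds.precision_at_k(inferred, []))

    def test_self_reference_is_one_for_every_k(self):
        inferred = ds.infer_ion(TestInferION().embedding(seed=7, n=10), theta=0.0)
        for k in (1, 5, 10, 20):
            ref = inferred.pairs()[:k]
            (_, p), = ds.precision_at_k(inferred, ref, ks=[k])
            assert p == 1.0

    def test_matches_sort_then_count_oracle(self):
        rng = np.random.default_rng(8)
        inferred = ds.infer_ion(TestInferION().embedding(seed=8, n=12), theta=0.0)
        ranked = inferred.pairs()
        ref = [ranked[i] for i in rng.choice(len(ranked), 20, replace=False)]
        ref_set = {frozenset(e) for e in ref}
        for k in (1, 10, 25):
            (_, p), = ds.precision_at_k(inferred, ref, ks=[k])
            expect = sum(frozenset(e) in ref_set for e in ranked[:k]) / min(
                k, len(ranked))
            assert p == pytest.approx(expect)

    def test_unordered_membership(self):
        inferred = ds.infer_ion(TestInferION().embedding(seed=9), theta=0.0)
        a, b = inferred.pairs()[0]
        assert ds.precision_at_k(inferred, [(b, a)], ks=[1]) == [(1, 1.0)]


class TestMCC:
    def test_hand_formula_case(self):
        counts = ds.ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        expect = (3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6)
        assert ds.mcc(counts) == pytest.approx(expect)
        assert ds.mcc(counts) == pytest.approx(0.40824829, abs=1e-8)

    def test_perfect_and_chance(self):
        assert ds.mcc(ds.ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert ds.mcc(ds.ConfusionCounts(5, 5, 5, 5)) == 0.0

    def test_zero_denominator_maps_to_zero(self):
        assert ds.mcc(ds.ConfusionCounts(0, 0, 10, 0)) == 0.0

    def test_inverted_classifier_negates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            m = ds.mcc(ds.ConfusionCounts(tp, fp, tn, fn))
            inv = ds.mcc(ds.ConfusionCounts(fp, tp, fn, tn))
            assert -1.0 <= m <= 1.0
            assert inv == pytest.approx(-m)

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        counts = ds.ConfusionCounts(
            tp=int(((y_pred == 1) & (y_true == 1)).sum()),
            fp=int(((y_pred == 1) & (y_true == 0)).sum()),
            tn=int(((y_pred == 0) & (y_true == 0)).sum()),
            fn=int(((y_pred == 0) & (y_true == 1)).sum()),
        )
        assert ds.mcc(counts) == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_mcc_at_threshold_reference_must_be_embedded(self):
        emb = TestInferION().embedding(seed=10)
        with pytest.raises(KeyError, match="ghost"):
            ds.mcc_at_threshold(emb, [("L:ghost", "L:n0")])

    def test_threshold_sweep_shape(self):
        emb = TestInferION().embedding(seed=11, n=10)
        ref = ds.infer_ion(emb, theta=0.8).pairs()
        out = ds.mcc_at_threshold(emb, ref)
        assert [t for t, _ in out] == [round(0.1 * i, 1) for i in range(1, 10)]
        assert all(-1 <= m <= 1 for _, m in out)


class TestDetectModules:
    def inferred_from_graph(self, network):
        """Wrap a graph's edges as a top-scored inferred network."""
        import pandas as pd
        reg = network.registry
        coo = network.supra_adjacency.tocoo()
        rows = [(reg.key(i), reg.key(j), 1.0, 1.0)
                for i, j in zip(coo.row, coo.col) if i < j]
        edges = pd.DataFrame(rows, columns=["node_i", "node_j", "delta",
                                            "delta_norm"])
        return ds.InferredNetwork(edges, theta=0.7, node_keys=reg.keys())

    def test_two_cliques_give_two_modules(self):
        net = oe.make_graph_fixture("two_cliques", (12, 12), bridge=1)
        part = ds.detect_modules(self.inferred_from_graph(net), min_size=10)
        assert sorted(part.sizes.values()) == [12, 12]
        assert set(part.sizes) == {"A", "B"}

    def test_single_clique_one_module(self):
        net = oe.make_graph_fixture("clique", 12)
        part = ds.detect_modules(self.inferred_from_graph(net), min_size=10)
        assert list(part.sizes.values()) == [12]

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        net = oe.make_graph_fixture("planted_partition", (3, 20),
                                    p_in=0.3, p_out=0.02, seed=1)
        part = ds.detect_modules(self.inferred_from_graph(net), min_size=10)
        labels_true, labels_pred = [], []
        for node, module in part.assignments.items():
            labels_true.append(node.split(":")[1].split("_")[0])
            labels_pred.append(module)
        assert adjusted_rand_score(labels_true, labels_pred) >= 0.8

    def test_partition_is_disjoint_cover(self):
        net = oe.make_graph_fixture("two_cliques", (12, 14), bridge=2)
        part = ds.detect_modules(self.inferred_from_graph(net), min_size=10)
        assert sum(part.sizes.values()) == len(part.assignments)

    def test_small_modules_filtered(self, caplog):
        net = oe.make_graph_fixture("two_cliques", (5, 6), bridge=1)
        with caplog.at_level("WARNING"):
            part = ds.detect_modules(self.inferred_from_graph(net), min_size=10)
        assert part.assignments == {}

    def test_empty_network_is_error(self):
        import pandas as pd
        empty = ds.InferredNetwork(
            pd.DataFrame(columns=["node_i", "node_j", "delta", "delta_norm"]),
            theta=0.9, node_keys=[])
        with pytest.raises(ValueError, match="empty"):
            ds.detect_modules(empty)


class TestRankHubs:
    def test_star_center_ranked_first(self):
        import pandas as pd
        rows = [("L:hub", f"L:n{i}", 1.0, 1.0) for i in range(5)]
        inferred = ds.InferredNetwork(
            pd.DataFrame(rows, columns=["node_i", "node_j", "delta",
                                        "delta_norm"]),
            theta=0.7, node_keys=[])
        hubs = ds.rank_hubs(inferred)
        assert hubs[0] == ("L:hub", "", 5)

    def test_empty_network_empty_list(self):
        import pandas as pd
        inferred = ds.InferredNetwork(
            pd.DataFrame(columns=["node_i", "node_j", "delta", "delta_norm"]),
            theta=0.7, node_keys=[])
        assert ds.rank_hubs(inferred) == []

    def test_matches_incidence_recount(self):
        emb = TestInferION().embedding(seed=12, n=10)
        inferred = ds.infer_ion(emb, theta=0.5)
        deg = {}
        for a, b in inferred.pairs():
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        for node, _, d in ds.rank_hubs(inferred, top_n=100):
            assert deg[node] == d


class TestGridSearch:
    def test_subgrid_shape_and_determinism(self, default_pipeline):
        truth = default_pipeline["truth"]
        net = default_pipeline["network"]
        pairs = [(f"tf:{a}", f"gene:{b}") for a, b in truth.tf_target_edges]
        table = ds.grid_search(net, tf_target_edges=pairs, Ts=(1, 2),
                               ds=(8, 16), seed=0, n_runs=2)
        assert len(table) == 2 * 2 * len(ds.OPERATORS)
        table2 = ds.grid_search(net, tf_target_edges=pairs, Ts=(1, 2),
                                ds=(8, 16), seed=0, n_runs=2)
        assert table.equals(table2)

    def test_ion_task_shape(self, default_pipeline):
        truth = default_pipeline["truth"]
        net = default_pipeline["network"]
        ref = [(f"tf:{a}", f"gene:{b}") for a, b in truth.tf_target_edges]
        table = ds.grid_search(net, reference_edges=ref, Ts=(1,), ds=(8,),
                               task="ion")
        assert len(table) == 9  # one row per theta
        assert set(table.columns) == {"T", "d", "theta", "mcc"}

    def test_unknown_task_rejected(self, default_pipeline):
        with pytest.raises(ValueError, match="task"):
            ds.grid_search(default_pipeline["network"], task="nope")
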
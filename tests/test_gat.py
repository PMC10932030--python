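import numpy as np
import pytest

import omicsgat as og
from omicsgat.gat import (GATClassifier, GATLayerParams, _TwoLayerGAT,
                          _softmax_rows, aggregate_neighbors, attention_scores,
                          gat_forward, normalize_attention)
from omicsgat.io import OmicsValidationError
from omicsgat.similarity import PatientGraph, SimilarityMatrix, build_topk_graph


def random_graph(rng, n, k=2):
    x = rng.standard_normal((n, n))
    sim = (x + x.T) / 2
    ids = [f"S{i:02d}" for i in range(n)]
    return build_topk_graph(SimilarityMatrix(sim, "pearson", ids), k=k)


def loop_oracle(params: GATLayerParams, x, graph, activation="identity"):
    """Scalar-by-scalar evaluation of the three attention equations."""
    p, m = params.W.shape
    nbrs = graph.neighbors()
    pos = {v: i for i, v in enumerate(graph.node_ids)}
    c, alpha, h = {}, {}, np.zeros((len(x), p))
    for v in graph.node_ids:
        i = pos[v]
        hood = sorted({v, *nbrs[v]})
        for u in hood:
            j = pos[u]
            concat = np.concatenate([params.W @ x[i], params.W @ x[j]])
            s = float(params.a @ concat)
            c[(i, j)] = s if s > 0 else params.leaky_slope * s
        denom = sum(np.exp(c[(i, pos[u])]) for u in hood)
        for u in hood:
            j = pos[u]
            alpha[(i, j)] = np.exp(c[(i, j)]) / denom
        agg = sum(alpha[(i, pos[u])] * (params.W @ x[pos[u]]) for u in hood)
        h[i] = np.where(agg > 0, agg, np.expm1(np.minimum(agg, 0))) \
            if activation == "elu" else agg
    return c, alpha, h


class TestAttentionScores:
    def test_zero_attention_vector(self, rng):
        g = random_graph(rng, 4)
        params = GATLayerParams(rng.standard_normal((3, 5)), np.zeros(6))
        state = attention_scores(params, rng.standard_normal((4, 5)), g)
        np.testing.assert_array_equal(state.c, 0.0)

    def test_single_node_zero_features(self):
        g = PatientGraph(["A"], [])
        params = GATLayerParams(np.eye(2), np.ones(4))
        state = attention_scores(params, np.zeros((1, 2)), g)
        np.testing.assert_array_equal(state.c, [0.0])

    def test_matches_loop_oracle(self, rng):
        g = random_graph(rng, 4)
        params = GATLayerParams(rng.standard_normal((3, 6)),
                                rng.standard_normal(6))
        x = rng.standard_normal((4, 6))
        state = attention_scores(params, x, g)
        c_expected, _, _ = loop_oracle(params, x, g)
        for (i, j), cij in zip(state.edge_index, state.c):
            assert abs(cij - c_expected[(i, j)]) < 1e-10

    def test_dimension_mismatch_reported(self, rng):
        g = random_graph(rng, 4)
        params = GATLayerParams(rng.standard_normal((3, 6)),
                                rng.standard_normal(6))
        with pytest.raises(OmicsValidationError, match="m=6"):
            attention_scores(params, rng.standard_normal((4, 5)), g)


class TestNormalizeAttention:
    def test_single_neighbor_gets_one(self):
        g = PatientGraph(["A"], [])
        params = GATLayerParams(np.eye(2), np.ones(4))
        state = normalize_attention(attention_scores(params, np.ones((1, 2)), g))
        np.testing.assert_allclose(state.alpha, [1.0])

    def test_equal_scores_split_evenly(self, rng):
        g = PatientGraph(["A", "B", "C"], [("A", "B"), ("A", "C"), ("B", "C")])
        params = GATLayerParams(np.zeros((2, 3)), rng.standard_normal(4))
        state = normalize_attention(
            attention_scores(params, rng.standard_normal((3, 3)), g))
        np.testing.assert_allclose(state.alpha, 1 / 3)

    def test_closed_form_softmax(self):
        state = og.AttentionState(np.array([[0, 0], [0, 1]]),
                                  np.array([np.log(2.0), 0.0]))
        normalize_attention(state)
        np.testing.assert_allclose(state.alpha, [2 / 3, 1 / 3], atol=1e-12)

    def test_rows_sum_to_one_on_random_graphs(self, rng):
        for n in (4, 5, 6):
            g = random_graph(rng, n, k=2)
            params = GATLayerParams(rng.standard_normal((3, 4)),
                                    rng.standard_normal(6))
            state = normalize_attention(
                attention_scores(params, rng.standard_normal((n, 4)), g))
            sums = np.add.reduceat(state.alpha, state.offsets())
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestAggregate:
    def test_shared_feature_vector_ignores_alpha(self, rng):
        g = random_graph(rng, 5)
        params = GATLayerParams(rng.standard_normal((3, 4)),
                                rng.standard_normal(6))
        x = np.tile(rng.standard_normal(4), (5, 1))
        state = normalize_attention(attention_scores(params, x, g))
        out = aggregate_neighbors(state, params, x, activation="identity")
        np.testing.assert_allclose(out.values, np.tile(params.W @ x[0], (5, 1)),
                                   atol=1e-12)

    def test_isolated_node_self_representation(self):
        g = PatientGraph(["A"], [])
        params = GATLayerParams(np.array([[2.0, 0.0], [0.0, -1.0]]),
                                np.ones(4))
        x = np.array([[3.0, 4.0]])
        state = normalize_attention(attention_scores(params, x, g))
        out = aggregate_neighbors(state, params, x, activation="identity")
        np.testing.assert_allclose(out.values, [[6.0, -4.0]])

    def test_matches_loop_oracle(self, rng):
        g = random_graph(rng, 5)
        params = GATLayerParams(rng.standard_normal((3, 4)),
                                rng.standard_normal(6))
        x = rng.standard_normal((5, 4))
        state = normalize_attention(attention_scores(params, x, g))
        out = aggregate_neighbors(state, params, x, activation="elu")
        _, alpha_exp, h_exp = loop_oracle(params, x, g, activation="elu")
        for (i, j), a in zip(state.edge_index, state.alpha):
            assert abs(a - alpha_exp[(i, j)]) < 1e-10
        np.testing.assert_allclose(out.values, h_exp, atol=1e-10)

    def test_uniform_alpha_identity_activation_equals_mean_aggregator(self, rng):
        """With alpha forced uniform and sigma = identity the layer is a
        mean-aggregation graph convolution."""
        g = random_graph(rng, 6)
        params = GATLayerParams(rng.standard_normal((3, 4)),
                                rng.standard_normal(6))
        x = rng.standard_normal((6, 4))
        state = attention_scores(params, x, g)
        dst = state.edge_index[:, 0]
        sizes = np.bincount(dst)
        state.alpha = 1.0 / sizes[dst]
        out = aggregate_neighbors(state, params, x, activation="identity")
        nbrs = g.neighbors()
        pos = {v: i for i, v in enumerate(g.node_ids)}
        z = x @ params.W.T
        for v in g.node_ids:
            hood = sorted({v, *nbrs[v]})
            mean = np.mean([z[pos[u]] for u in hood], axis=0)
            np.testing.assert_allclose(out.values[pos[v]], mean, atol=1e-12)


class TestForward:
    def test_single_head_equals_composed_ops(self, rng):
        g = random_graph(rng, 5)
        x = rng.standard_normal((5, 4))
        model = _TwoLayerGAT(4, 3, 2, 1, 0.2, rng)
        logits, h1 = gat_forward(model, x, g)
        p1 = GATLayerParams(model.W1[0], model.a1[0])
        s1 = normalize_attention(attention_scores(p1, x, g))
        h1_ref = aggregate_neighbors(s1, p1, x, activation="elu").values
        np.testing.assert_allclose(h1, h1_ref, atol=1e-12)
        p2 = GATLayerParams(model.W2, model.a2)
        s2 = normalize_attention(attention_scores(p2, h1_ref, g))
        logits_ref = aggregate_neighbors(s2, p2, h1_ref,
                                         activation="identity").values
        np.testing.assert_allclose(logits, logits_ref, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        n = 6
        g = random_graph(rng, n)
        x = rng.standard_normal((n, 4))
        model = _TwoLayerGAT(4, 4, 3, 2, 0.2, rng)
        logits, h1 = gat_forward(model, x, g)
        perm = rng.permutation(n)
        ids_p = [g.node_ids[i] for i in perm]
        remap = {g.node_ids[i]: ids_p.index(g.node_ids[i]) for i in range(n)}
        # rebuild the same graph under the permuted node ordering
        edges_p = sorted(tuple(sorted((a, b))) for a, b in g.edges)
        g_p = PatientGraph(ids_p, edges_p)
        x_p = np.empty_like(x)
        for i, v in enumerate(g.node_ids):
            x_p[remap[v]] = x[i]
        logits_p, h1_p = gat_forward(model, x_p, g_p)
        for i, v in enumerate(g.node_ids):
            np.testing.assert_allclose(logits_p[remap[v]], logits[i], atol=1e-8)
            np.testing.assert_allclose(h1_p[remap[v]], h1[i], atol=1e-8)

    def test_zero_weights_give_uniform_scores(self, rng):
        g = random_graph(rng, 5)
        model = _TwoLayerGAT(4, 3, 2, 1, 0.2, rng)
        model.set_parameters([np.zeros_like(p) for p in model.parameters()])
        logits, _ = gat_forward(model, rng.standard_normal((5, 4)), g)
        np.testing.assert_array_equal(logits, 0.0)

    def test_heads_must_divide_hidden(self, rng):
        with pytest.raises(OmicsValidationError, match="divide"):
            _TwoLayerGAT(4, 10, 2, 3, 0.2, rng)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        n, m, hid, n_cls, heads = 6, 4, 4, 3, 2
        g = random_graph(rng, n)
        x = rng.standard_normal((n, m))
        y = rng.integers(n_cls, size=n)
        model = _TwoLayerGAT(m, hid, n_cls, heads, 0.2, rng)
        ei = g.edge_index()
        off = np.searchsorted(ei[:, 0], np.arange(n))
        onehot = np.eye(n_cls)[y]

        def loss():
            logits, _ = model.forward(x, ei, off)
            p = _softmax_rows(logits)
            return -np.mean(np.log(p[np.arange(n), y] + 1e-12))

        logits, _ = model.forward(x, ei, off)
        p = _softmax_rows(logits)
        grads = model.backward((p - onehot) / n, x, ei, off)
        eps = 1e-6
        for param, grad in zip(model.parameters(), grads):
            flat = param.reshape(-1)
            gflat = grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(6, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                assert abs((lp - lm) / (2 * eps) - gflat[idx]) < 1e-6


class TestTraining:
    def test_fixed_seed_reproducible_loss_trajectory(self, tiny_cohort, tiny_graph):
        matrices, labels, _ = tiny_cohort
        x = og.zscore_normalize(matrices[0]).values
        y = np.asarray(labels.labels)
        tr, va, te = og.stratified_split(labels, seed=0)
        kw = dict(hidden_dim=16, epochs=30, random_state=5)
        c1 = GATClassifier(**kw).fit(x, y, graph=tiny_graph, train_idx=tr, val_idx=va)
        c2 = GATClassifier(**kw).fit(x, y, graph=tiny_graph, train_idx=tr, val_idx=va)
        assert c1.history_["loss"] == c2.history_["loss"]
        np.testing.assert_array_equal(c1.embedding_, c2.embedding_)

    def test_loss_mostly_non_increasing(self, tiny_cohort, tiny_graph):
        matrices, labels, _ = tiny_cohort
        x = og.zscore_normalize(matrices[0]).values
        y = np.asarray(labels.labels)
        tr, va, _ = og.stratified_split(labels, seed=1)
        clf = GATClassifier(hidden_dim=16, epochs=100, random_state=0).fit(
            x, y, graph=tiny_graph, train_idx=tr, val_idx=va)
        loss = np.asarray(clf.history_["loss"])
        assert (np.diff(loss) <= 1e-9).mean() >= 0.95

    def test_missing_class_in_train_split_rejected(self, tiny_cohort, tiny_graph):
        matrices, labels, _ = tiny_cohort
        x = matrices[0].values
        y = np.asarray(labels.labels)
        bad_train = np.flatnonzero(y == y[0])      # a single class only
        with pytest.raises(OmicsValidationError, match="stratification"):
            GATClassifier(hidden_dim=8, epochs=2).fit(
                x, y, graph=tiny_graph, train_idx=bad_train)

    def test_strong_effect_validation_macro_f1(self, tiny_cohort, tiny_graph):
        matrices, labels, _ = tiny_cohort
        x = np.concatenate([og.zscore_normalize(matrices[0]).values,
                            og.zscore_normalize(matrices[1]).values], axis=1)
        y = np.asarray(labels.labels)
        tr, va, te = og.stratified_split(labels, seed=2)
        _, emb = og.train_gat(x, tiny_graph, labels, tr, va,
                              hidden_dim=32, epochs=100)
        from sklearn.metrics import f1_score
        clf = GATClassifier(hidden_dim=32, epochs=100, random_state=0).fit(
            x, y, graph=tiny_graph, train_idx=tr, val_idx=va)
        score = f1_score(y[va], clf.predict()[va], average="macro")
        assert score > 0.85
        assert emb.values.shape == (len(y), 32)
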
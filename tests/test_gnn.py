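"""GCN link-predictor contracts: features, propagation, gradients, graphs."""

import numpy as np
import pytest

import dyncausal as dc
from dyncausal.gnn import GcnModel, _loss_and_grads
from dyncausal.var_granger import GrangerResult, VarFit


def make_var_fit(A_list, variables=None):
    A = np.asarray(A_list, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, n, _ = A.shape
    variables = variables or [f"v{i}" for i in range(n)]
    return VarFit(
        variables=variables,
        lag_order=p,
        coef=A,
        intercept=np.zeros(n),
        sigma=np.eye(n),
        t_eff=100,
        aic=0.0,
        bic=0.0,
    )


def make_results(variables, significant_pairs, p_sig=0.001, p_null=0.8):
    out = []
    for s in variables:
        for t in variables:
            if s == t:
                continue
            sig = (s, t) in significant_pairs
            out.append(
                GrangerResult(s, t, 1, 10.0 if sig else 0.1, p_sig if sig else p_null, 1, 100, sig)
            )
    return out


class TestNodeFeatures:
    def test_outgoing_orientation(self):
        # coef[i, j] = effect of j on i's equation; outgoing of v0 = column 0
        fit = make_var_fit([[0.1, 0.2], [0.3, 0.4]])
        F = dc.build_node_features(fit)
        np.testing.assert_array_equal(F, [[0.1, 0.3], [0.2, 0.4]])

    def test_lag_blocks_ordered(self):
        fit = make_var_fit([np.full((2, 2), 1.0), np.full((2, 2), 2.0)])
        F = dc.build_node_features(fit)
        assert F.shape == (2, 4)
        np.testing.assert_array_equal(F[0], [1.0, 1.0, 2.0, 2.0])

    def test_zero_coefficients_give_zero_features(self):
        F = dc.build_node_features(make_var_fit(np.zeros((3, 3))))
        assert not F.any()


class TestEdgeTrainingSet:
    def test_balanced_counts(self):
        variables = [f"v{i}" for i in range(10)]
        sig = {("v0", "v1"), ("v2", "v3"), ("v4", "v5"), ("v6", "v7")}
        ets = dc.build_edge_training_set(make_results(variables, sig), variables, seed=0)
        assert len(ets.positives) == 4 and len(ets.negatives) == 4
        assert not set(ets.positives) & set(ets.negatives)

    def test_all_significant_takes_empty_pool_with_warning(self):
        variables = ["a", "b"]
        sig = {("a", "b"), ("b", "a")}
        with pytest.warns(UserWarning, match="smaller"):
            ets = dc.build_edge_training_set(make_results(variables, sig), variables, seed=0)
        assert ets.negatives == []

    def test_no_positives_is_error(self):
        variables = ["a", "b", "c"]
        with pytest.raises(ValueError, match="empty preliminary graph"):
            dc.build_edge_training_set(make_results(variables, set()), variables)

    def test_same_seed_same_negatives(self):
        variables = [f"v{i}" for i in range(8)]
        res = make_results(variables, {("v0", "v1"), ("v2", "v3")})
        a = dc.build_edge_training_set(res, variables, seed=5)
        b = dc.build_edge_training_set(res, variables, seed=5)
        assert a.negatives == b.negatives


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        np.testing.assert_array_equal(dc.normalize_adjacency(np.zeros((2, 2))), np.eye(2))

    def test_single_undirected_edge(self):
        out = dc.normalize_adjacency(np.array([[0, 1], [1, 0]]))
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    @pytest.mark.parametrize("seed", range(5))
    def test_spectrum_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.uniform(size=(8, 8)) < 0.3).astype(int)
        np.fill_diagonal(A, 0)
        eig = np.linalg.eigvalsh(dc.normalize_adjacency(A))
        assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10

    def test_symmetric_output(self):
        A = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        out = dc.normalize_adjacency(A)
        np.testing.assert_allclose(out, out.T)


class TestForward:
    def test_zero_features_give_zero_embeddings(self):
        model = GcnModel(W0=np.ones((4, 3)), W1=np.ones((3, 2)), R=np.eye(2), A_hat=np.eye(5))
        Z = dc.gcn_forward(np.zeros((5, 4)), model)
        assert not Z.any()

    def test_identity_propagation(self):
        F = np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        model = GcnModel(W0=np.eye(4), W1=np.eye(4), R=np.eye(4), A_hat=np.eye(4))
        np.testing.assert_allclose(dc.gcn_forward(F, model), F)

    def test_single_node_scalar_trace(self):
        f, w0, w1 = 1.7, 0.4, -2.0
        model = GcnModel(
            W0=np.array([[w0]]), W1=np.array([[w1]]), R=np.eye(1), A_hat=np.eye(1)
        )
        Z = dc.gcn_forward(np.array([[f]]), model)
        assert Z[0, 0] == pytest.approx(w1 * max(0.0, f * w0))

    def test_shape_mismatch_rejected(self):
        model = GcnModel(W0=np.ones((4, 3)), W1=np.ones((3, 2)), R=np.eye(2), A_hat=np.eye(5))
        with pytest.raises(ValueError, match="feature dim"):
            dc.gcn_forward(np.zeros((5, 3)), model)


class TestTraining:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((4, 6))
        A = np.array([[0, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 0, 0]])
        ets = dc.EdgeTrainingSet(positives=[(0, 1), (2, 3)], negatives=[(1, 2), (3, 0)], seed=seed)
        return F, A, ets

    def test_analytic_gradients_match_finite_differences(self):
        from dyncausal.gnn import normalize_adjacency

        F, A, ets = self._toy(3)
        S = normalize_adjacency(A)
        rng = np.random.default_rng(1)
        W0 = rng.standard_normal((6, 5)) * 0.5
        W1 = rng.standard_normal((5, 3)) * 0.5
        R = rng.standard_normal((3, 3)) * 0.5
        pairs, y = ets.pairs, ets.labels
        _, dW0, dW1, dR = _loss_and_grads(F, S, W0, W1, R, pairs, y)
        eps = 1e-6
        for name, W, dW in [("W0", W0, dW0), ("W1", W1, dW1), ("R", R, dR)]:
            num = np.zeros_like(W)
            for idx in np.ndindex(W.shape):
                Wp, Wm = W.copy(), W.copy()
                Wp[idx] += eps
                Wm[idx] -= eps
                args_p = {"W0": W0, "W1": W1, "R": R}
                args_m = {"W0": W0, "W1": W1, "R": R}
                args_p[name], args_m[name] = Wp, Wm
                lp = _loss_and_grads(F, S, args_p["W0"], args_p["W1"], args_p["R"], pairs, y)[0]
                lm = _loss_and_grads(F, S, args_m["W0"], args_m["W1"], args_m["R"], pairs, y)[0]
                num[idx] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(num), np.abs(dW)).max() + 1e-12
            assert np.max(np.abs(num - dW)) / denom < 1e-5, name

    def test_zero_learning_rate_is_noop(self):
        F, A, ets = self._toy()
        model = dc.train_edge_predictor(F, ets, A, learning_rate=0.0, epochs=20, seed=0)
        assert len(set(np.round(model.loss_log, 15))) == 1

    def test_separable_clusters_reach_low_bce(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            F = np.vstack([
                rng.standard_normal((3, 4)) + 4.0,  # cluster 1
                rng.standard_normal((3, 4)) - 4.0,  # cluster 2
            ])
            A = np.zeros((6, 6))
            pos = [(0, 1), (1, 2), (2, 0)]
            neg = [(3, 4), (4, 5), (5, 3)]
            ets = dc.EdgeTrainingSet(positives=pos, negatives=neg, seed=seed)
            model = dc.train_edge_predictor(F, ets, A, seed=seed)
            ok += model.loss_log[-1] < 0.1
        assert ok >= 9

    def test_training_deterministic_given_seed(self):
        F, A, ets = self._toy()
        m1 = dc.train_edge_predictor(F, ets, A, epochs=50, seed=4)
        m2 = dc.train_edge_predictor(F, ets, A, epochs=50, seed=4)
        np.testing.assert_array_equal(m1.W0, m2.W0)
        np.testing.assert_array_equal(m1.R, m2.R)
        g1 = dc.predict_causal_graph(m1, F, [f"v{i}" for i in range(4)])
        g2 = dc.predict_causal_graph(m2, F, [f"v{i}" for i in range(4)])
        assert g1.to_dict() == g2.to_dict()

    def test_loss_log_non_increasing_late(self):
        F, A, ets = self._toy(7)
        model = dc.train_edge_predictor(F, ets, A, seed=7)
        tail = np.asarray(model.loss_log[-len(model.loss_log) // 10 :])
        assert np.max(np.diff(tail)) < 1e-6


class TestPredictGraph:
    def test_uniform_half_scores_inclusive_threshold(self):
        # R = 0 makes every logit 0, every probability exactly 0.5
        model = GcnModel(W0=np.eye(3), W1=np.eye(3), R=np.zeros((3, 3)), A_hat=np.eye(3))
        F = np.abs(np.random.default_rng(0).standard_normal((3, 3)))
        g = dc.predict_causal_graph(model, F, ["a", "b", "c"], threshold=0.5, edge_policy="score_all")
        assert len(g.edges) == 6  # complete directed graph, >= is inclusive

    def test_threshold_one_empties_graph(self):
        model = GcnModel(W0=np.eye(3), W1=np.eye(3), R=np.eye(3), A_hat=np.eye(3))
        F = np.random.default_rng(0).standard_normal((3, 3))
        g = dc.predict_causal_graph(model, F, ["a", "b", "c"], threshold=1.0, edge_policy="score_all")
        assert g.edges == []

    def test_validate_policy_restricts_to_granger_edges(self):
        model = GcnModel(W0=np.eye(3), W1=np.eye(3), R=np.zeros((3, 3)), A_hat=np.eye(3))
        F = np.abs(np.random.default_rng(0).standard_normal((3, 3)))
        g = dc.predict_causal_graph(
            model, F, ["a", "b", "c"], granger_edges={("a", "b")}, threshold=0.5
        )
        assert g.edge_set() == {("a", "b")}
        assert g.edges[0].provenance == "both"

    def test_probabilities_and_embeddings_finite(self, clean_cohort):
        var = dc.PanelVAR(p=1).fit(clean_cohort["features"])
        res = dc.preliminary_edges(clean_cohort["features"], p=1)
        found = {(r.source, r.target) for r in res if r.significant}
        F = dc.build_node_features(var.result_)
        ets = dc.build_edge_training_set(res, var.variables_, seed=1)
        idx = {v: i for i, v in enumerate(var.variables_)}
        A = np.zeros((10, 10))
        for s, t in found:
            A[idx[s], idx[t]] = 1
        gcn = dc.GCNLinkPredictor(seed=1).fit(F, ets, A)
        graph = gcn.predict_graph(var.variables_, found)
        assert np.isfinite(graph.embeddings).all()
        assert all(0 <= e.probability <= 1 for e in graph.edges + graph.granger_only)
        # better than chance on its balanced training set
        assert gcn.loss_log_[-1] < np.log(2)
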
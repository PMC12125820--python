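"""GCN edge predictor over VAR-coefficient node features.

Node i's feature vector concatenates, for each lag k, variable i's
*outgoing* influence coefficients (the effect of i's lag-k value in every
variable's equation).  Two graph-convolution layers with symmetric
normalized adjacency and self-loops produce node embeddings; a bilinear
decoder sigmoid(z_i' R z_j) scores directed pairs.  A plain dot-product
decoder is necessarily symmetric in (i, j) and cannot represent edge
direction, so the bilinear form is used; message passing still runs on the
symmetrized preliminary graph while direction lives in the labels and the
decoder.

Training is full-batch gradient descent on mean binary cross-entropy over
a balanced edge training set (significant Granger edges as positives,
sampled non-significant ordered pairs as negatives).  Everything is plain
numpy with hand-derived gradients.

Because the balanced training set contains only a handful of labelled
pairs while the final graph concerns all n(n-1) ordered pairs, scoring
*every* pair against a fixed threshold is an uncontrolled extrapolation:
nothing in training pushes the ~n^2 unlabeled pairs below the threshold.
The default edge policy is therefore ``validate``: the final graph keeps
the preliminary Granger edges the GNN confirms (score >= threshold), and
novel above-threshold pairs are recorded with provenance
``gnn_predicted`` but only enter the edge set under
``edge_policy="score_all"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .var_granger import GrangerResult, VarFit


def build_node_features(var_fit: VarFit) -> np.ndarray:
    """Feature matrix F (n x p*n): row i holds variable i's outgoing
    coefficients, lag-1 block first.  With coef[k][a, b] the effect of b's
    lag on a's equation, the outgoing influence of i is column i of each
    coef[k]."""
    p, n = var_fit.lag_order, var_fit.n_vars
    return np.concatenate([var_fit.coef[k].T for k in range(p)], axis=1).reshape(n, p * n)


@dataclass
class EdgeTrainingSet:
    """Balanced labelled ordered pairs (indices into the node list)."""

    positives: list[tuple[int, int]]
    negatives: list[tuple[int, int]]
    seed: int

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative pairs overlap")
        if any(i == j for i, j in self.positives + self.negatives):
            raise ValueError("self-pairs are not allowed")

    @property
    def pairs(self) -> np.ndarray:
        return np.asarray(self.positives + self.negatives, dtype=int)

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.positives)), np.zeros(len(self.negatives))])


def build_edge_training_set(
    granger: list[GrangerResult], variables: list[str], seed: int = 0
) -> EdgeTrainingSet:
    """Positives = all significant ordered pairs; negatives = a uniform
    sample (without replacement) of non-significant ordered pairs of the
    same count.  If the pool is smaller, all of it is taken with a warning."""
    idx = {v: i for i, v in enumerate(variables)}
    positives = [(idx[r.source], idx[r.target]) for r in granger if r.significant]
    if not positives:
        raise ValueError("empty preliminary graph: no significant Granger edges")
    pool = [(idx[r.source], idx[r.target]) for r in granger if not r.significant]
    rng = np.random.default_rng(seed)
    if len(pool) < len(positives):
        warnings.warn(
            f"negative pool ({len(pool)}) smaller than positives ({len(positives)}); taking all"
        )
        negatives = list(pool)
    else:
        chosen = rng.choice(len(pool), size=len(positives), replace=False)
        negatives = [pool[c] for c in sorted(chosen)]
    return EdgeTrainingSet(positives=positives, negatives=negatives, seed=seed)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """D^(-1/2) (A_sym + I) D^(-1/2) with A_sym the symmetrized 0/1 view
    of A and D its degree matrix; self-loops guarantee positive degrees."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    A_tilde = np.maximum(A, A.T).astype(float)
    np.fill_diagonal(A_tilde, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class GcnModel:
    """Two-layer GCN weights plus bilinear edge decoder and training log."""

    W0: np.ndarray  # (f, h)
    W1: np.ndarray  # (h, d)
    R: np.ndarray  # (d, d) bilinear decoder
    A_hat: np.ndarray  # normalized adjacency used for message passing
    loss_log: list[float] = field(default_factory=list)
    hyper: dict = field(default_factory=dict)


def gcn_forward(features: np.ndarray, model: GcnModel) -> np.ndarray:
    """Z = A_hat relu(A_hat F W0) W1 (linear final layer, deterministic)."""
    F = np.asarray(features, dtype=float)
    if F.shape[1] != model.W0.shape[0]:
        raise ValueError(f"feature dim {F.shape[1]} != W0 rows {model.W0.shape[0]}")
    H1 = np.maximum(model.A_hat @ F @ model.W0, 0.0)
    return model.A_hat @ H1 @ model.W1


def _edge_logits(Z: np.ndarray, R: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return np.einsum("ad,de,ae->a", Z[pairs[:, 0]], R, Z[pairs[:, 1]])


def _loss_and_grads(
    F: np.ndarray,
    S: np.ndarray,
    W0: np.ndarray,
    W1: np.ndarray,
    R: np.ndarray,
    pairs: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mean BCE over labelled pairs and its analytic gradients."""
    P = S @ F
    U = P @ W0
    H = np.maximum(U, 0.0)
    Q = S @ H
    Z = Q @ W1
    t = _edge_logits(Z, R, pairs)
    loss = float(np.mean(np.logaddexp(0.0, t) - y * t))
    g = (1.0 / (1.0 + np.exp(-t)) - y) / len(y)
    zi, zj = Z[pairs[:, 0]], Z[pairs[:, 1]]
    dR = zi.T @ (g[:, None] * zj)
    dZ = np.zeros_like(Z)
    np.add.at(dZ, pairs[:, 0], g[:, None] * (zj @ R.T))
    np.add.at(dZ, pairs[:, 1], g[:, None] * (zi @ R))
    dW1 = Q.T @ dZ
    dH = S @ (dZ @ W1.T)  # S symmetric
    dU = dH * (U > 0)
    dW0 = P.T @ dU
    return loss, dW0, dW1, dR


def train_edge_predictor(
    features: np.ndarray,
    edges: EdgeTrainingSet,
    A_init: np.ndarray,
    hidden: int = 16,
    embed: int = 8,
    learning_rate: float = 0.2,
    epochs: int = 2000,
    seed: int = 0,
) -> GcnModel:
    """Full-batch gradient descent on mean BCE; Gaussian init scaled by
    1/sqrt(fan-in), fixed seed, loss logged per epoch."""
    F = np.asarray(features, dtype=float)
    S = normalize_adjacency(A_init)
    rng = np.random.default_rng(seed)
    f = F.shape[1]
    W0 = rng.standard_normal((f, hidden)) / np.sqrt(f)
    W1 = rng.standard_normal((hidden, embed)) / np.sqrt(hidden)
    R = rng.standard_normal((embed, embed)) / np.sqrt(embed)
    pairs, y = edges.pairs, edges.labels
    log: list[float] = []
    max_grad_norm = 5.0  # global-norm clipping keeps plain GD stable on steep losses
    for _ in range(epochs):
        loss, dW0, dW1, dR = _loss_and_grads(F, S, W0, W1, R, pairs, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; try a lower learning rate")
        log.append(loss)
        gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in (dW0, dW1, dR)))
        scale = learning_rate * min(1.0, max_grad_norm / (gnorm + 1e-12))
        W0 = W0 - scale * dW0
        W1 = W1 - scale * dW1
        R = R - scale * dR
    return GcnModel(
        W0=W0,
        W1=W1,
        R=R,
        A_hat=S,
        loss_log=log,
        hyper={
            "hidden": hidden,
            "embed": embed,
            "learning_rate": learning_rate,
            "epochs": epochs,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# final graph


@dataclass(frozen=True)
class PredictedEdge:
    source: str
    target: str
    probability: float
    provenance: str  # both | gnn_predicted | granger_only


@dataclass
class CausalGraph:
    """Final dynamic causal graph: GNN-predicted directed edges (score >=
    threshold, inclusive) with provenance against the preliminary Granger
    set, plus node embeddings.  Granger edges the GNN scored below the
    threshold are kept separately so both readings stay recoverable."""

    nodes: list[str]
    edges: list[PredictedEdge]
    granger_only: list[PredictedEdge]
    embeddings: np.ndarray
    threshold: float = 0.5

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def causal_nodes(self) -> list[str]:
        """Nodes incident to at least one edge of the final graph."""
        incident = {v for e in self.edges for v in (e.source, e.target)}
        return [v for v in self.nodes if v in incident]

    def embedding_of(self, node: str) -> np.ndarray:
        return self.embeddings[self.nodes.index(node)]

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "threshold": self.threshold,
            "edges": [e.__dict__ for e in self.edges],
            "granger_only": [e.__dict__ for e in self.granger_only],
            "embeddings": self.embeddings.tolist(),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def embeddings_frame(self) -> pd.DataFrame:
        cols = [f"emb{k}" for k in range(self.embeddings.shape[1])]
        return pd.DataFrame(self.embeddings, index=self.nodes, columns=cols)


def predict_causal_graph(
    model: GcnModel,
    features: np.ndarray,
    variables: list[str],
    granger_edges: set[tuple[str, str]] | None = None,
    threshold: float = 0.5,
    edge_policy: str = "validate",
) -> CausalGraph:
    """Score all n(n-1) ordered pairs (edge present iff score >= threshold,
    inclusive) and assemble the final graph under the chosen policy:
    ``validate`` keeps the GNN-confirmed Granger edges as the edge set,
    ``score_all`` admits every above-threshold pair."""
    if edge_policy not in ("validate", "score_all"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    n = len(variables)
    Z = gcn_forward(features, model)
    granger_edges = granger_edges or set()
    edges: list[PredictedEdge] = []
    granger_only: list[PredictedEdge] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            logit = float(Z[i] @ model.R @ Z[j])
            prob = float(1.0 / (1.0 + np.exp(-logit)))
            name = (variables[i], variables[j])
            in_granger = name in granger_edges
            if prob >= threshold:
                prov = "both" if in_granger else "gnn_predicted"
                if in_granger or edge_policy == "score_all":
                    edges.append(PredictedEdge(name[0], name[1], prob, prov))
            elif in_granger:
                granger_only.append(PredictedEdge(name[0], name[1], prob, "granger_only"))
    return CausalGraph(
        nodes=list(variables), edges=edges, granger_only=granger_only, embeddings=Z, threshold=threshold
    )


class GCNLinkPredictor(BaseEstimator):
    """Two-layer GCN + bilinear decoder for causal-edge prediction.

    Parameters mirror :func:`train_edge_predictor`; ``fit`` takes the node
    feature matrix, the balanced edge training set, and the preliminary 0/1
    adjacency used for message passing.
    """

    def __init__(
        self,
        hidden: int = 16,
        embed: int = 8,
        learning_rate: float = 0.2,
        epochs: int = 2000,
        threshold: float = 0.5,
        edge_policy: str = "validate",
        seed: int = 0,
    ):
        self.hidden = hidden
        self.embed = embed
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.threshold = threshold
        self.edge_policy = edge_policy
        self.seed = seed

    def fit(self, X: np.ndarray, edges: EdgeTrainingSet, adjacency: np.ndarray) -> "GCNLinkPredictor":
        self.model_ = train_edge_predictor(
            X,
            edges,
            adjacency,
            hidden=self.hidden,
            embed=self.embed,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed,
        )
        self.features_ = np.asarray(X, dtype=float)
        self.embeddings_ = gcn_forward(self.features_, self.model_)
        self.loss_log_ = self.model_.loss_log
        return self

    def predict_proba_pairs(self, pairs: np.ndarray) -> np.ndarray:
        pairs = np.asarray(pairs, dtype=int)
        t = _edge_logits(self.embeddings_, self.model_.R, pairs)
        return 1.0 / (1.0 + np.exp(-t))

    def predict_graph(
        self, variables: list[str], granger_edges: set[tuple[str, str]] | None = None
    ) -> CausalGraph:
        return predict_causal_graph(
            self.model_,
            self.features_,
            variables,
            granger_edges,
            threshold=self.threshold,
            edge_policy=self.edge_policy,
        )
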
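"""Classifier bank under leakage-free grouped stratified CV with SMOTE.

Two feature sets are compared: ``all`` (the base variables as observed)
and ``dynamic_causal`` (variables participating in the final causal graph,
their lag/difference transformations, and the per-variable GCN embedding
coordinates broadcast as columns).  Whole individuals are assigned to
folds so no person's rows span train and test; SMOTE rebalances the
training partition only, and metrics are computed on untouched test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .gnn import CausalGraph
from .panel import ID_COL, OUTCOME_COL, WAVE_COL
from .preprocess import FeatureMatrix

METRIC_NAMES = ("auc", "accuracy", "precision", "recall", "f1", "mcc")

MODEL_FAMILIES = (
    "random_forest",
    "logistic_regression",
    "xgboost",
    "svm",
    "knn",
    "gradient_boosting",
    "mlp",
)


@dataclass
class DesignMatrix:
    """Model-ready rows: features X, binary labels y, individual groups."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    feature_set: str
    manifest: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("design matrix has missing cells")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")


def assemble_features(
    features: FeatureMatrix, graph: CausalGraph | None = None, mode: str = "all"
) -> DesignMatrix:
    """Build the design matrix for one feature-set mode.

    ``all``: base variables only.  ``dynamic_causal``: base variables
    incident to the final causal graph, their lag/diff columns, and each
    such variable's embedding coordinates broadcast as constant columns.
    Rows lacking required lag support are dropped in causal mode.
    """
    frame = features.frame
    if OUTCOME_COL not in frame.columns:
        raise ValueError("feature matrix has no outcome column")
    if mode == "all":
        cols = features.base_columns
        rows = frame.dropna(subset=cols + [OUTCOME_COL])
        X = rows[cols].copy()
    elif mode == "dynamic_causal":
        if graph is None:
            raise ValueError("dynamic_causal mode requires a causal graph")
        causal = [v for v in graph.causal_nodes() if v in features.base_columns]
        if not causal:
            raise ValueError("causal graph has no nodes connected by edges; nothing to select")
        causal_set = set(causal)
        cols = list(causal)
        cols += [c for c, m in features.columns.items() if m.role in ("lag", "diff") and m.source in causal_set]
        rows = frame.dropna(subset=cols + [OUTCOME_COL])
        X = rows[cols].copy()
        for v in causal:
            emb = graph.embedding_of(v)
            for k, val in enumerate(emb):
                X[f"{v}_emb{k}"] = val
    else:
        raise ValueError(f"unknown feature-set mode {mode!r}")
    return DesignMatrix(
        X=X.reset_index(drop=True),
        y=rows[OUTCOME_COL].to_numpy(dtype=int),
        groups=rows[ID_COL].to_numpy(),
        feature_set=mode,
        manifest=list(X.columns),
    )


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CvPlan:
    """K-fold assignment with whole-individual grouping."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def validate(self, y: np.ndarray, groups: np.ndarray) -> None:
        n = len(y)
        all_test = np.concatenate([test for _, test in self.folds])
        if len(all_test) != n or len(np.unique(all_test)) != n:
            raise ValueError("test folds do not partition the rows")
        for train, test in self.folds:
            if set(groups[train]) & set(groups[test]):
                raise ValueError("group overlap between train and test within a fold")

    def label_proportions(self, y: np.ndarray) -> list[float]:
        return [float(np.mean(y[test])) for _, test in self.folds]


def stratified_group_kfold(y, groups, k: int = 5, seed: int = 0) -> CvPlan:
    """Greedy stratified group K-fold: groups (whole individuals) are
    assigned to folds to balance group-level positive counts first, then
    total rows, so fold sizes are as equal as possible.  With fewer
    positive-containing groups than folds this degrades to plain group
    K-fold with a warning."""
    y = np.asarray(y)
    groups = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq, inv = np.unique(groups, return_inverse=True)
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} groups, got {len(uniq)}")
    g_pos = np.bincount(inv, weights=y.astype(float))
    g_size = np.bincount(inv)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))

    stratify = int(np.sum(g_pos > 0)) >= k
    if not stratify:
        warnings.warn("fewer positive groups than folds; falling back to plain group K-fold")

    fold_pos = np.zeros(k)
    fold_rows = np.zeros(k, dtype=int)
    assignment = np.empty(len(uniq), dtype=int)
    # positive-carrying groups first (largest positive counts first within
    # the shuffled order), then the rest
    keys = [(-g_pos[g], i) for i, g in enumerate(order)]
    for _, i in sorted(keys):
        g = order[i]
        if stratify and g_pos[g] > 0:
            f = min(range(k), key=lambda f: (fold_pos[f], fold_rows[f], f))
        else:
            f = min(range(k), key=lambda f: (fold_rows[f], f))
        assignment[g] = f
        fold_pos[f] += g_pos[g]
        fold_rows[f] += g_size[g]

    row_fold = assignment[inv]
    idx = np.arange(len(y))
    folds = [(idx[row_fold != f], idx[row_fold == f]) for f in range(k)]
    plan = CvPlan(folds=folds, seed=seed)
    plan.validate(y, groups)
    return plan


# ---------------------------------------------------------------------------
# SMOTE


class SMOTEOversampler(BaseEstimator):
    """Synthetic minority oversampling to a 1:1 class balance.

    Each synthetic row is x + u (x' - x) for a minority row x, one of its
    ``k_neighbors`` nearest minority neighbours x' (Euclidean), and
    u ~ Uniform(0, 1).  Originals are preserved verbatim.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE expects exactly two classes")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        n_needed = int(n_maj - n_min)
        if n_needed == 0:
            return X.copy(), y.copy()
        if n_min < 2:
            raise ValueError("minority class needs at least 2 rows for SMOTE")
        k = self.k_neighbors
        if n_min < k + 1:
            k = n_min - 1
            warnings.warn(f"minority class too small for k={self.k_neighbors}; using k={k}")
        X_min = X[y == minority]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
        rng = np.random.default_rng(self.seed)
        base = rng.integers(0, n_min, size=n_needed)
        pick = rng.integers(1, k + 1, size=n_needed)
        u = rng.uniform(size=n_needed)
        x0 = X_min[base]
        x1 = X_min[neigh[base, pick]]
        synth = x0 + u[:, None] * (x1 - x0)
        # parent bookkeeping (minority-row indices and mixing weights) for audits
        self.parents_ = (base.copy(), neigh[base, pick].copy(), u.copy())
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    return SMOTEOversampler(k_neighbors=k_neighbors, seed=seed).fit_resample(X, y)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(y_true, scores, threshold: float = 0.5) -> dict[str, float]:
    """Six-way metric record at the given score threshold (>= inclusive).

    AUC is threshold-free (trapezoidal ROC with tie averaging); it is NaN
    with a warning when only one class is present.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    preds = (scores >= threshold).astype(int)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, scores))
    return {
        "auc": auc,
        "accuracy": float(accuracy_score(y_true, preds)),
        "precision": float(precision_score(y_true, preds, zero_division=0)),
        "recall": float(recall_score(y_true, preds, zero_division=0)),
        "f1": float(f1_score(y_true, preds, zero_division=0)),
        "mcc": float(matthews_corrcoef(y_true, preds)),
    }


# ---------------------------------------------------------------------------
# classifier bank


def build_models(models: list[str] | None = None, seed: int = 0) -> dict[str, BaseEstimator]:
    """Instantiate the requested classifier families with library defaults
    and fixed seeds; every returned estimator exposes predict_proba."""
    if models is None:
        models = list(MODEL_FAMILIES)
    registry = {
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "logistic_regression": lambda: LogisticRegression(max_iter=1000),
        "xgboost": lambda: XGBClassifier(random_state=seed, eval_metric="logloss", verbosity=0),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "mlp": lambda: MLPClassifier(random_state=seed, max_iter=500),
    }
    unknown = [m for m in models if m not in registry]
    if unknown:
        raise ValueError(f"unknown model families {unknown}; choose from {list(registry)}")
    built = {m: registry[m]() for m in models}
    for name, est in built.items():
        if not hasattr(est, "predict_proba"):
            raise ValueError(f"model {name} has no probability output configured")
    return built


@dataclass
class ModelReport:
    """Per-(model, feature_set, fold) metric table with cross-fold means."""

    table: pd.DataFrame

    def mean_table(self) -> pd.DataFrame:
        return (
            self.table.groupby(["model", "feature_set"], sort=False)[list(METRIC_NAMES)]
            .mean()
            .reset_index()
        )

    def mean_metric(self, model: str, feature_set: str, metric: str) -> float:
        sub = self.table[(self.table.model == model) & (self.table.feature_set == feature_set)]
        return float(sub[metric].mean())

    def to_csv(self, path) -> None:
        self.mean_table().to_csv(path, index=False)

    @staticmethod
    def concat(reports: list["ModelReport"]) -> "ModelReport":
        return ModelReport(pd.concat([r.table for r in reports], ignore_index=True))


def train_and_evaluate(
    design: DesignMatrix,
    plan: CvPlan,
    models: list[str] | None = None,
    seed: int = 0,
    smote_k: int = 5,
    threshold: float = 0.5,
) -> ModelReport:
    """Per fold: SMOTE the training rows only, fit each classifier, score
    the untouched test rows, compute the six metrics.  Group disjointness
    is asserted on every run."""
    plan.validate(design.y, design.groups)
    built = build_models(models, seed=seed)
    X = design.X.to_numpy(dtype=float)
    records = []
    for fold_id, (train, test) in enumerate(plan.folds):
        X_tr, y_tr = smote_oversample(X[train], design.y[train], k_neighbors=smote_k, seed=seed + fold_id)
        for name, proto in built.items():
            est = clone(proto)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X_tr, y_tr)
                scores = est.predict_proba(X[test])[:, 1]
            rec = compute_metrics(design.y[test], scores, threshold=threshold)
            rec.update({"model": name, "feature_set": design.feature_set, "fold": fold_id})
            records.append(rec)
    cols = ["model", "feature_set", "fold", *METRIC_NAMES]
    return ModelReport(pd.DataFrame.from_records(records)[cols])


def paired_bootstrap_auc(
    y_true, scores_a, scores_b, n_boot: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Optional diagnostic: paired bootstrap over test rows for the AUC
    difference of two scorers on the same labels.  Returns the observed
    difference and a two-sided bootstrap p-value."""
    y_true = np.asarray(y_true, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    rng = np.random.default_rng(seed)
    obs = roc_auc_score(y_true, a) - roc_auc_score(y_true, b)
    diffs = []
    n = len(y_true)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y_true[idx])) < 2:
            continue
        diffs.append(roc_auc_score(y_true[idx], a[idx]) - roc_auc_score(y_true[idx], b[idx]))
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1)
    z = obs / se if se > 0 else np.inf
    return {"auc_diff": float(obs), "p_value": float(2 * _stats.norm.sf(abs(z)))}
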
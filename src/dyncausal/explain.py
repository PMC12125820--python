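"""Model-agnostic Shapley attribution and smoothed main-effect curves.

Attributions are Monte-Carlo permutation Shapley values with
background-mean imputation: for each random feature ordering, features are
switched one at a time from the background mean to the instance's actual
value and the score increments are averaged.  Because absent features are
imputed by a single reference vector, the per-permutation increments
telescope and the efficiency identity base + sum(phi) = f(x) holds exactly.
This model-agnostic scheme works uniformly across all classifier families;
no tree-path-dependent variant is used.

Main-effect curves smooth the per-instance attribution of one feature
against its value with LOWESS (tricube kernel, one robustness iteration).
The "inflection" annotation is a heuristic — the grid point with the
largest curvature (second difference) of the smoothed curve — and is
labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_N_PERMUTATIONS = 200
DEFAULT_BACKGROUND_SIZE = 100
DEFAULT_LOWESS_SPAN = 0.6


@dataclass
class AttributionResult:
    """Per-instance, per-feature Shapley attributions.

    ``base_value`` is the model score at the background-mean reference
    vector; ``scores`` are the model scores of the explained instances, so
    base_value + phi.sum(axis=1) == scores row-wise.
    """

    phi: np.ndarray  # (n_instances, n_features)
    base_value: float
    scores: np.ndarray
    feature_names: list[str]
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, columns=self.feature_names)

    def efficiency_gap(self) -> np.ndarray:
        return self.base_value + self.phi.sum(axis=1) - self.scores


def sampling_shapley(
    scorer,
    background: np.ndarray,
    X_explain: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    feature_names: list[str] | None = None,
    exact: bool = False,
) -> AttributionResult:
    """Monte-Carlo permutation Shapley attribution.

    ``scorer`` maps an (m, d) array to m probabilities.  Features absent
    from a coalition take the background mean.  The same seeded
    permutations are shared across instances.  With ``exact=True`` all d!
    orderings are enumerated instead of sampled (small d only), which
    reproduces the combinatorial Shapley formula to machine precision.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be nonempty")
    X = np.atleast_2d(np.asarray(X_explain, dtype=float))
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"x{k}" for k in range(d)]
    m = background.mean(axis=0)
    rng = np.random.default_rng(seed)
    base_value = float(np.asarray(scorer(m[None, :]))[0])
    phi = np.zeros((n, d))
    if exact:
        from itertools import permutations as _perms

        perms = [np.asarray(p) for p in _perms(range(d))]
        n_permutations = len(perms)
    else:
        perms = [rng.permutation(d) for _ in range(n_permutations)]
    for perm in perms:
        # states[s] = coalition after s switches; evaluate all at once
        states = np.empty((d + 1, n, d))
        states[0] = np.tile(m, (n, 1))
        for s, feat in enumerate(perm):
            states[s + 1] = states[s]
            states[s + 1][:, feat] = X[:, feat]
        vals = np.asarray(scorer(states.reshape(-1, d))).reshape(d + 1, n)
        increments = np.diff(vals, axis=0)  # (d, n), step s is feature perm[s]
        phi[:, perm] += increments.T
    phi /= n_permutations
    scores = np.asarray(scorer(X), dtype=float)
    return AttributionResult(
        phi=phi,
        base_value=base_value,
        scores=scores,
        feature_names=list(feature_names),
        n_permutations=n_permutations,
        seed=seed,
    )


def importance_ranking(attr: AttributionResult) -> list[tuple[str, float]]:
    """Features by descending mean |phi|; ties break lexicographically."""
    if attr.phi.size == 0:
        raise ValueError("empty attribution matrix")
    means = np.abs(attr.phi).mean(axis=0)
    order = sorted(zip(attr.feature_names, means), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(v)) for name, v in order]


@dataclass
class MainEffectCurve:
    """LOWESS-smoothed attribution of one feature against its value."""

    feature: str
    grid: np.ndarray
    smoothed: np.ndarray
    inflection_value: float  # curvature-maximum heuristic, not a model quantity
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.grid, "smoothed_phi": self.smoothed})


def main_effect_curve(
    attr: AttributionResult,
    feature_values: np.ndarray,
    feature: str,
    bandwidth: float = DEFAULT_LOWESS_SPAN,
    n_grid: int = 100,
) -> MainEffectCurve:
    """Locally weighted linear regression (tricube kernel, span
    ``bandwidth``, one robustness iteration) of phi_feature on the feature
    value, evaluated on a uniform grid."""
    x = np.asarray(feature_values, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 instances for a main-effect curve")
    if np.ptp(x) == 0:
        raise ValueError(f"feature {feature!r} is constant; no curve")
    j = attr.feature_names.index(feature)
    fitted = lowess(attr.phi[:, j], x, frac=bandwidth, it=1, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), n_grid)
    smoothed = np.interp(grid, fitted[:, 0], fitted[:, 1])
    second = np.abs(np.diff(smoothed, 2))
    inflection = float(grid[int(np.argmax(second)) + 1]) if len(second) else float(grid[0])
    return MainEffectCurve(
        feature=feature, grid=grid, smoothed=smoothed, inflection_value=inflection, bandwidth=bandwidth
    )


class ShapleyExplainer(BaseEstimator):
    """Sampling-Shapley explainer for any probability-scoring model.

    Parameters
    ----------
    n_permutations : int, default 200
        Random feature orderings per explanation batch.
    background_size : int, default 100
        Rows sampled (seeded) from the supplied background data.
    seed : int, default 0
    """

    def __init__(
        self,
        n_permutations: int = DEFAULT_N_PERMUTATIONS,
        background_size: int = DEFAULT_BACKGROUND_SIZE,
        seed: int = 0,
    ):
        self.n_permutations = n_permutations
        self.background_size = background_size
        self.seed = seed

    @staticmethod
    def _as_scorer(model):
        if callable(model) and not hasattr(model, "predict_proba"):
            return model
        return lambda X: model.predict_proba(X)[:, 1]

    def explain(
        self, model, background: np.ndarray, X_explain: np.ndarray, feature_names: list[str] | None = None
    ) -> AttributionResult:
        background = np.asarray(background, dtype=float)
        rng = np.random.default_rng(self.seed)
        if len(background) > self.background_size:
            keep = rng.choice(len(background), size=self.background_size, replace=False)
            background = background[keep]
        self.attribution_ = sampling_shapley(
            self._as_scorer(model),
            background,
            X_explain,
            n_permutations=self.n_permutations,
            seed=self.seed,
            feature_names=feature_names,
        )
        return self.attribution_

    def ranking(self) -> list[tuple[str, float]]:
        return importance_ranking(self.attribution_)

    def curve(self, feature_values: np.ndarray, feature: str, bandwidth: float = DEFAULT_LOWESS_SPAN) -> MainEffectCurve:
        return main_effect_curve(self.attribution_, feature_values, feature, bandwidth=bandwidth)
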
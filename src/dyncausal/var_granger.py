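"""Pooled panel VAR and pairwise Granger causal-edge discovery.

The VAR is fitted on stacked within-individual transitions: every design
row pairs one individual-wave response with the *same individual's* p
previous waves, and coefficients are shared across individuals.  With only
a handful of waves per person a per-individual VAR is unidentifiable; the
individual-level temporal structure is honored by never letting a
transition row cross an individual boundary.

Granger tests are bivariate nested-regression F tests.  Because a graph
over n variables involves n(n-1) simultaneous tests, edge discovery
applies Benjamini-Hochberg FDR control at level alpha by default
(``correction=None`` recovers the raw per-test threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .panel import ID_COL, WAVE_COL, PanelDataset
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_CORRECTION = "fdr_bh"


@dataclass
class VarFit:
    """Fitted pooled VAR(p).

    ``coef`` has shape (p, n, n) with ``coef[k][i, j]`` the effect of
    variable j's lag-(k+1) value in the equation for variable i.
    """

    variables: list[str]
    lag_order: int
    coef: np.ndarray
    intercept: np.ndarray
    sigma: np.ndarray
    t_eff: int
    aic: float
    bic: float

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix; < 1 means the fitted
        dynamics are stable (stationary)."""
        n, p = self.n_vars, self.lag_order
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate([self.coef[k] for k in range(p)], axis=1)
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GrangerResult:
    source: str
    target: str
    lag_order: int
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    significant: bool


# ---------------------------------------------------------------------------
# transition stacking


def _base_frame(features) -> tuple[pd.DataFrame, list[str]]:
    if isinstance(features, FeatureMatrix):
        return features.frame, features.base_columns
    if isinstance(features, PanelDataset):
        return features.frame, features.variables
    raise TypeError(f"expected FeatureMatrix or PanelDataset, got {type(features)}")


def stack_transitions(
    features, variables: list[str] | None = None, p: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Stack within-individual transitions for a VAR(p).

    Returns (design, response): response rows are X_t for each usable
    individual-wave; design rows are (1, X_{t-1}, ..., X_{t-p}) drawn from
    the same individual.  No row spans two individuals.
    """
    frame, default_vars = _base_frame(features)
    variables = list(variables) if variables is not None else default_vars
    if p < 1:
        raise ValueError("lag order p must be >= 1")
    frame = frame.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    base = frame[[ID_COL, WAVE_COL] + variables]
    merged = base
    for k in range(1, p + 1):
        shifted = base.copy()
        shifted[WAVE_COL] = shifted[WAVE_COL] + k
        shifted = shifted.rename(columns={v: f"__l{k}_{v}" for v in variables})
        merged = merged.merge(shifted, on=[ID_COL, WAVE_COL], how="left")
    merged = merged.dropna()
    if len(merged) == 0:
        raise ValueError("zero usable transitions (not enough waves for the requested lag order)")
    Y = merged[variables].to_numpy(dtype=float)
    lag_cols = [f"__l{k}_{v}" for k in range(1, p + 1) for v in variables]
    X = np.column_stack([np.ones(len(merged)), merged[lag_cols].to_numpy(dtype=float)])
    return X, Y


# ---------------------------------------------------------------------------
# VAR fitting


def _ols_fit(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    return B, Y - X @ B


def fit_var(features, variables: list[str] | None = None, p: int = 1) -> VarFit:
    """Per-equation OLS on the stacked transitions.

    Information criteria use the multivariate log-determinant form:
    aic = log det(sigma) + 2 p n^2 / T,  bic = log det(sigma) + log(T) p n^2 / T.
    """
    frame, default_vars = _base_frame(features)
    variables = list(variables) if variables is not None else default_vars
    X, Y = stack_transitions(features, variables, p)
    n = len(variables)
    t_eff = X.shape[0]
    if t_eff <= n * p + 1:
        raise ValueError(f"too few transitions (T_eff={t_eff}) for n={n}, p={p}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design; try a lower lag order or fewer variables")
    B, E = _ols_fit(X, Y)
    sigma = E.T @ E / t_eff
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("degenerate residual covariance (perfect fit?)")
    k_params = p * n * n
    aic = logdet + 2.0 * k_params / t_eff
    bic = logdet + np.log(t_eff) * k_params / t_eff
    coef = np.empty((p, n, n))
    for k in range(p):
        coef[k] = B[1 + k * n : 1 + (k + 1) * n, :].T  # row i = equation for variable i
    fit = VarFit(
        variables=variables,
        lag_order=p,
        coef=coef,
        intercept=B[0].copy(),
        sigma=sigma,
        t_eff=t_eff,
        aic=float(aic),
        bic=float(bic),
    )
    rho = fit.companion_spectral_radius()
    if rho >= 1:
        logger.warning("fitted VAR is non-stationary (companion spectral radius %.3f)", rho)
    else:
        logger.info("fitted VAR stable (companion spectral radius %.3f)", rho)
    return fit


def select_lag_order(
    features, variables: list[str] | None = None, p_max: int = 2, criterion: str = "bic"
) -> int:
    """argmin over p = 1..p_max of the chosen criterion, computed on the
    common transition sample supported by the largest p; ties -> smallest p."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    frame, default_vars = _base_frame(features)
    variables = list(variables) if variables is not None else default_vars
    X_full, Y = stack_transitions(features, variables, p_max)
    n = len(variables)
    t_eff = X_full.shape[0]
    scores = []
    for p in range(1, p_max + 1):
        X = X_full[:, : 1 + p * n]
        if t_eff <= n * p + 1:
            raise ValueError(f"too few common transitions (T_eff={t_eff}) for p={p}")
        _, E = _ols_fit(X, Y)
        sign, logdet = np.linalg.slogdet(E.T @ E / t_eff)
        if sign <= 0:
            raise ValueError("degenerate residual covariance during order selection")
        k_params = p * n * n
        penalty = 2.0 if criterion == "aic" else np.log(t_eff)
        scores.append(logdet + penalty * k_params / t_eff)
    return int(np.argmin(scores)) + 1


# ---------------------------------------------------------------------------
# Granger testing


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    _, resid = _ols_fit(X, y[:, None])
    return float(resid.ravel() @ resid.ravel())


def granger_test(
    features,
    source: str,
    target: str,
    p: int = 1,
    alpha: float = DEFAULT_ALPHA,
    conditional: bool = False,
) -> GrangerResult:
    """Nested-regression Granger F test of source -> target.

    Bivariate by default: the unrestricted model regresses X_target(t) on
    an intercept plus p lags of target and p lags of source; the restricted
    model drops the source lags.  With ``conditional=True`` the lags of all
    remaining variables are kept in both models (conditional Granger).
    """
    if source == target:
        raise ValueError("source and target must differ")
    frame, all_vars = _base_frame(features)
    if conditional:
        variables = [target] + [v for v in all_vars if v != target]
    else:
        variables = [target, source]
    X, Y = stack_transitions(features, variables, p)
    y = Y[:, 0]  # target equation
    src_pos = variables.index(source)
    src_cols = [1 + k * len(variables) + src_pos for k in range(p)]
    keep = [c for c in range(X.shape[1]) if c not in src_cols]
    rss_u = _rss(X, y)
    rss_r = _rss(X[:, keep], y)
    t_eff = X.shape[0]
    df_num = p
    df_den = t_eff - X.shape[1]
    if df_den < 1:
        raise ValueError(f"not enough transitions ({t_eff}) for the Granger regression")
    scale = float(y @ y) + 1.0
    if rss_u <= 1e-12 * scale:
        raise ValueError("degenerate input: unrestricted regression fits perfectly (RSS = 0)")
    f_stat = max(rss_r - rss_u, 0.0) / df_num / (rss_u / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den)) if f_stat > 0 else 1.0
    return GrangerResult(
        source=source,
        target=target,
        lag_order=p,
        f_statistic=float(f_stat),
        p_value=p_value,
        df_num=df_num,
        df_den=df_den,
        significant=bool(p_value < alpha),
    )


def preliminary_edges(
    features,
    variables: list[str] | None = None,
    p: int = 1,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = DEFAULT_CORRECTION,
    conditional: bool = False,
) -> list[GrangerResult]:
    """Granger tests for all ordered variable pairs; the ``significant``
    flag marks the discovered preliminary causal edges.

    ``correction='fdr_bh'`` (default) applies Benjamini-Hochberg across the
    n(n-1) tests at level ``alpha``; ``correction=None`` uses the raw
    per-test threshold p < alpha.
    """
    frame, default_vars = _base_frame(features)
    variables = list(variables) if variables is not None else default_vars
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    results = [
        granger_test(features, i, j, p=p, alpha=alpha, conditional=conditional)
        for i, j in permutations(variables, 2)
    ]
    if correction == "fdr_bh":
        reject, _, _, _ = multipletests([r.p_value for r in results], alpha=alpha, method="fdr_bh")
        for r, rej in zip(results, reject):
            r.significant = bool(rej)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return results


def edges_to_frame(results: list[GrangerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [r.source for r in results],
            "target": [r.target for r in results],
            "F": [r.f_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# estimator surfaces


class PanelVAR(BaseEstimator):
    """Pooled panel VAR estimator.

    Parameters
    ----------
    p : int or "auto", default 1
        Lag order; "auto" selects it by information criterion up to p_max.
    p_max : int, default 2
        Largest candidate order for automatic selection.
    criterion : {"aic", "bic"}, default "bic"
    """

    def __init__(self, p: int | str = 1, p_max: int = 2, criterion: str = "bic"):
        self.p = p
        self.p_max = p_max
        self.criterion = criterion

    def fit(self, X, y=None, variables: list[str] | None = None) -> "PanelVAR":
        p = self.p
        if p == "auto":
            p = select_lag_order(X, variables, p_max=self.p_max, criterion=self.criterion)
        result = fit_var(X, variables, p=int(p))
        self.result_ = result
        self.variables_ = result.variables
        self.p_ = result.lag_order
        self.coef_ = result.coef
        self.intercept_ = result.intercept
        self.sigma_ = result.sigma
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.t_eff_ = result.t_eff
        self.spectral_radius_ = result.companion_spectral_radius()
        return self


class GrangerGraph(BaseEstimator):
    """Pairwise Granger edge discovery over all ordered variable pairs.

    Parameters
    ----------
    p : int, default 1
    alpha : float, default 0.05
    correction : {"fdr_bh", None}, default "fdr_bh"
        Multiple-testing handling across the n(n-1) tests.
    conditional : bool, default False
        Condition each test on the remaining variables' lags.
    """

    def __init__(
        self,
        p: int = 1,
        alpha: float = DEFAULT_ALPHA,
        correction: str | None = DEFAULT_CORRECTION,
        conditional: bool = False,
    ):
        self.p = p
        self.alpha = alpha
        self.correction = correction
        self.conditional = conditional

    def fit(self, X, y=None, variables: list[str] | None = None) -> "GrangerGraph":
        self.results_ = preliminary_edges(
            X,
            variables,
            p=self.p,
            alpha=self.alpha,
            correction=self.correction,
            conditional=self.conditional,
        )
        self.edges_ = [(r.source, r.target) for r in self.results_ if r.significant]
        return self

    def to_frame(self) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise RuntimeError("GrangerGraph is not fitted")
        return edges_to_frame(self.results_)
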
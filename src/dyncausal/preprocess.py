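"""Panel preprocessing: missingness policy, encoding, scaling, temporal features.

The pipeline order is fixed: (1) drop variables whose missing fraction
strictly exceeds the threshold, (2) impute — forward fill within individual,
then overall mean (continuous) or mode (binary/categorical) for residual
gaps, (3) label-encode categoricals and z-score continuous variables,
(4) build lag/difference temporal features strictly within individual.
``build_temporal_features`` asserts that imputation and encoding already
happened, which pins that order.

The missing-fraction denominator is all individual-wave rows.  ">10%" is a
strict inequality: a variable missing in exactly 10% of cells is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import ID_COL, OUTCOME_COL, WAVE_COL, PanelDataset

DEFAULT_DROP_THRESHOLD = 0.10
DEFAULT_LAG_ORDERS = (1, 2)


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one feature-matrix column."""

    role: str  # base | lag | diff
    source: str  # originating variable
    order: int | None = None  # lag order for lag/diff columns


@dataclass
class FeatureMatrix:
    """Wide feature table keyed by (id, wave) with column provenance.

    ``frame`` carries id, wave, the outcome column when present, and one
    column per base/lag/diff feature.  ``columns`` maps each feature column
    to its :class:`ColumnInfo`.
    """

    frame: pd.DataFrame
    columns: dict[str, ColumnInfo] = field(default_factory=dict)

    @property
    def base_columns(self) -> list[str]:
        return [c for c, m in self.columns.items() if m.role == "base"]

    @property
    def feature_columns(self) -> list[str]:
        return list(self.columns)

    def columns_for(self, role: str) -> list[str]:
        return [c for c, m in self.columns.items() if m.role == role]

    def complete_rows(self) -> pd.DataFrame:
        """Rows with every feature defined (drops rows lacking lag support)."""
        return self.frame.dropna(subset=self.feature_columns)


# ---------------------------------------------------------------------------
# missingness policy


def sample_missing_filter(panel: PanelDataset, threshold: float = DEFAULT_DROP_THRESHOLD) -> tuple[PanelDataset, list]:
    """Optional individual-level exclusion: drop individuals whose overall
    fraction of missing variable cells strictly exceeds ``threshold``.
    Returns the filtered panel and the excluded individual ids."""
    frac = (
        panel.frame[panel.variables]
        .isna()
        .groupby(panel.frame[ID_COL].to_numpy())
        .mean()
        .mean(axis=1)
    )
    excluded = frac.index[frac > threshold].tolist()
    keep = ~panel.frame[ID_COL].isin(excluded)
    return PanelDataset(panel.frame[keep].reset_index(drop=True), dict(panel.kinds)), excluded


def drop_high_missing(
    panel: PanelDataset, threshold: float = DEFAULT_DROP_THRESHOLD
) -> tuple[PanelDataset, list[str]]:
    """Remove variables whose missing fraction strictly exceeds ``threshold``."""
    if len(panel.frame) == 0:
        raise ValueError("empty panel")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = panel.missing_fraction()
    dropped = [v for v in panel.variables if frac[v] > threshold]
    if len(dropped) == len(panel.variables):
        raise ValueError("all variables exceed the missingness threshold; nothing left to model")
    frame = panel.frame.drop(columns=dropped)
    kinds = {k: v for k, v in panel.kinds.items() if k not in dropped}
    return PanelDataset(frame, kinds), dropped


def _fit_fill_values(panel: PanelDataset) -> tuple[dict[str, float], dict[str, object]]:
    """Overall mean (continuous) / mode (binary, categorical) per variable,
    computed on observed cells.  Mode ties break to the smallest value."""
    means: dict[str, float] = {}
    modes: dict[str, object] = {}
    for v in panel.variables:
        col = panel.frame[v]
        if col.isna().all():
            raise ValueError(f"variable {v!r} entirely missing; should have been dropped")
        if panel.kinds[v] == "continuous":
            means[v] = float(col.mean())
        else:
            counts = col.dropna().value_counts()
            top = counts[counts == counts.max()]
            modes[v] = sorted(top.index)[0]
    return means, modes


def impute(
    panel: PanelDataset,
    means: dict[str, float] | None = None,
    modes: dict[str, object] | None = None,
) -> PanelDataset:
    """Two-pass imputation: forward fill within each individual (waves in
    chronological order), then fill residual gaps with the overall mean
    (continuous) or mode (binary/categorical).  Output has no missing cell."""
    if means is None or modes is None:
        fit_means, fit_modes = _fit_fill_values(panel)
        means = fit_means if means is None else means
        modes = fit_modes if modes is None else modes
    out = panel.sorted()
    frame = out.frame
    vars_ = out.variables
    frame[vars_] = frame.groupby(ID_COL, sort=False)[vars_].ffill()
    for v in vars_:
        fill = means[v] if out.kinds[v] == "continuous" else modes[v]
        if frame[v].isna().any():
            frame[v] = frame[v].fillna(fill)
    return PanelDataset(frame, dict(out.kinds))


# ---------------------------------------------------------------------------
# encoding & scaling


def _fit_encodings(panel: PanelDataset) -> dict[str, dict[object, int]]:
    enc: dict[str, dict[object, int]] = {}
    for v in panel.variables:
        if panel.kinds[v] == "categorical":
            levels = sorted(panel.frame[v].dropna().unique())
            enc[v] = {lvl: i for i, lvl in enumerate(levels)}
    return enc


def _fit_scale(panel: PanelDataset) -> dict[str, tuple[float, float]]:
    scale: dict[str, tuple[float, float]] = {}
    for v in panel.variables:
        if panel.kinds[v] == "continuous":
            col = panel.frame[v].to_numpy(dtype=float)
            mu, sd = float(np.mean(col)), float(np.std(col))  # population sd
            if sd == 0:
                raise ValueError(f"continuous variable {v!r} has zero variance")
            scale[v] = (mu, sd)
    return scale


def encode_and_scale(
    panel: PanelDataset,
    encodings: dict[str, dict[object, int]] | None = None,
    scale_params: dict[str, tuple[float, float]] | None = None,
) -> PanelDataset:
    """Label-encode categoricals (levels mapped 0..K-1 in lexicographic
    order) and z-score continuous variables; binary 0/1 columns untouched.

    When ``encodings`` / ``scale_params`` are provided (e.g. fitted on a
    training fold) they are applied as-is instead of being recomputed."""
    if panel.frame[panel.variables].isna().any().any():
        raise ValueError("panel has missing cells; impute first")
    if encodings is None:
        encodings = _fit_encodings(panel)
    if scale_params is None:
        scale_params = _fit_scale(panel)
    frame = panel.frame.copy()
    for v, mapping in encodings.items():
        unseen = set(frame[v].unique()) - set(mapping)
        if unseen:
            raise ValueError(f"categorical {v!r} has unseen levels {sorted(unseen)}")
        frame[v] = frame[v].map(mapping).astype(float)
    for v, (mu, sd) in scale_params.items():
        frame[v] = (frame[v].astype(float) - mu) / sd
    return PanelDataset(frame, dict(panel.kinds))


# ---------------------------------------------------------------------------
# temporal features


def build_temporal_features(
    panel: PanelDataset, lag_orders: tuple[int, ...] = DEFAULT_LAG_ORDERS, variables: list[str] | None = None
) -> FeatureMatrix:
    """Lag and difference features per variable and lag order, strictly
    within individual (lags are wave-aware and never cross individuals).

    lag_l(t) = X(t - l); diff_l(t) = X(t) - lag_l(t).  Rows whose lag wave
    does not exist carry missing lag/diff cells.
    """
    lag_orders = tuple(sorted(set(int(l) for l in lag_orders)))
    if any(l < 1 for l in lag_orders):
        raise ValueError("lag orders must be positive")
    n_waves = panel.n_waves
    if lag_orders and max(lag_orders) >= n_waves:
        raise ValueError(f"lag order {max(lag_orders)} >= number of waves ({n_waves})")
    if variables is None:
        variables = panel.variables
    frame = panel.sorted().frame
    if frame[variables].isna().any().any():
        raise ValueError("panel has missing cells; run drop/impute before temporal features")
    for v in variables:
        if not pd.api.types.is_numeric_dtype(frame[v]):
            raise ValueError(f"variable {v!r} is not numeric; encode before temporal features")

    out = frame.copy()
    columns: dict[str, ColumnInfo] = {v: ColumnInfo("base", v) for v in variables}
    for l in lag_orders:
        shifted = frame[[ID_COL, WAVE_COL] + variables].copy()
        shifted[WAVE_COL] = shifted[WAVE_COL] + l
        shifted = shifted.rename(columns={v: f"{v}_lag{l}" for v in variables})
        out = out.merge(shifted, on=[ID_COL, WAVE_COL], how="left")
        for v in variables:
            lag_col, diff_col = f"{v}_lag{l}", f"{v}_diff{l}"
            out[diff_col] = out[v] - out[lag_col]
            columns[lag_col] = ColumnInfo("lag", v, l)
            columns[diff_col] = ColumnInfo("diff", v, l)
    return FeatureMatrix(out, columns)


# ---------------------------------------------------------------------------
# estimator surface


class PanelPreprocessor(BaseEstimator, TransformerMixin):
    """Fit-once preprocessing: variable drop by missing fraction, two-pass
    imputation statistics, categorical encodings and z-score parameters.

    Fitting on a training subset and transforming held-out rows gives the
    leakage-free per-fold variant; fitting on the full panel reproduces the
    global preprocessing-before-modeling order.

    Parameters
    ----------
    drop_threshold : float, default 0.10
        Variables with missing fraction strictly above this are removed.
    sample_filter : bool, default False
        If True, first exclude individuals whose overall missing-cell
        fraction exceeds ``drop_threshold``.
    """

    def __init__(self, drop_threshold: float = DEFAULT_DROP_THRESHOLD, sample_filter: bool = False):
        self.drop_threshold = drop_threshold
        self.sample_filter = sample_filter

    def fit(self, X: PanelDataset, y=None) -> "PanelPreprocessor":
        panel = X
        excluded: list = []
        if self.sample_filter:
            panel, excluded = sample_missing_filter(panel, self.drop_threshold)
        panel, dropped = drop_high_missing(panel, self.drop_threshold)
        self.dropped_ = dropped
        self.excluded_individuals_ = excluded
        # fill statistics come from observed cells, before any filling
        self.fill_means_, self.fill_modes_ = _fit_fill_values(panel)
        panel = impute(panel, means=self.fill_means_, modes=self.fill_modes_)
        self.encodings_ = _fit_encodings(panel)
        self.scale_params_ = _fit_scale(panel)
        return self

    def transform(self, X: PanelDataset) -> PanelDataset:
        if not hasattr(self, "dropped_"):
            raise RuntimeError("PanelPreprocessor is not fitted")
        panel = X
        if self.sample_filter:
            panel, _ = sample_missing_filter(panel, self.drop_threshold)
        keep_kinds = {k: v for k, v in panel.kinds.items() if k not in self.dropped_}
        frame = panel.frame.drop(columns=[c for c in self.dropped_ if c in panel.frame.columns])
        panel = PanelDataset(frame, keep_kinds)
        n_missing = int(panel.frame[panel.variables].isna().sum().sum())
        panel = impute(panel, means=self.fill_means_, modes=self.fill_modes_)
        self.n_imputed_ = n_missing
        return encode_and_scale(panel, encodings=self.encodings_, scale_params=self.scale_params_)

    def report(self) -> dict:
        """JSON-serializable audit of the fitted preprocessing."""
        if not hasattr(self, "dropped_"):
            raise RuntimeError("PanelPreprocessor is not fitted")
        return {
            "dropped_variables": list(self.dropped_),
            "excluded_individuals": [int(i) for i in self.excluded_individuals_],
            "fill_means": {k: float(v) for k, v in self.fill_means_.items()},
            "fill_modes": {k: (v if isinstance(v, str) else float(v)) for k, v in self.fill_modes_.items()},
            "encodings": {k: {str(lvl): i for lvl, i in m.items()} for k, m in self.encodings_.items()},
            "scale_params": {k: [float(a), float(b)] for k, (a, b) in self.scale_params_.items()},
            "n_imputed_cells": int(getattr(self, "n_imputed_", 0)),
        }


class TemporalFeatures(BaseEstimator, TransformerMixin):
    """Stateless transformer adding lag/difference columns per variable.

    Parameters
    ----------
    lag_orders : tuple of int, default (1, 2)
    variables : list of str, optional
        Subset of variables to expand; all variables when None.
    """

    def __init__(self, lag_orders: tuple[int, ...] = DEFAULT_LAG_ORDERS, variables: list[str] | None = None):
        self.lag_orders = lag_orders
        self.variables = variables

    def fit(self, X: PanelDataset, y=None) -> "TemporalFeatures":
        return self

    def transform(self, X: PanelDataset) -> FeatureMatrix:
        return build_temporal_features(X, tuple(self.lag_orders), self.variables)
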
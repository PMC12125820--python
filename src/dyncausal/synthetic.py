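"""Synthetic longitudinal cohort generator with planted causal structure.

Emulates a CHARLS-like biennial panel: ~10 health variables observed over
4 waves for each individual, a rare binary stroke outcome driven by lagged
causal parents, and MCAR missingness.  Continuous and binary variables are
both emitted from a latent Gaussian VAR(p) so that the cross-lag dynamics
are well defined; binaries are threshold indicators of their latent states
at quantiles calibrated to target marginal prevalences.

The planted cross-variable edges form vertex-disjoint pairs by default.
This keeps the ground truth well posed for *bivariate* Granger recovery:
chains (i -> j -> k) and forks (i -> j, i -> k) induce genuine bivariate
Granger dependence between variable pairs that the planted edge list does
not contain, which would make precision/recall against the planted graph
ill-defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ID_COL, OUTCOME_COL, WAVE_COL, PanelDataset

_WARMUP = 30  # latent burn-in steps so observed waves are near-stationary

# Published cohort description the generator emulates: (count, total) per
# characteristic.  Binary target prevalences in default_config derive from
# these, and the printed percentages are recomputable as 100 * count / total.
COHORT_COUNTS: dict[str, tuple[int, int]] = {
    "stroke": (1011, 11_789),
    "female": (6334, 11_789),
    "male": (5455, 11_789),
    "disability": (5228, 11_789),
    "hibpe": (5058, 11_789),
    "chronic": (10_001, 11_789),
    "smoken": (8736, 11_789),
    "dyslipe": (9028, 11_789),
    "memrye": (11_238, 11_789),
}


def cohort_prevalence(name: str) -> float:
    count, total = COHORT_COUNTS[name]
    return count / total


@dataclass(frozen=True)
class VariableSpec:
    """One observed variable and how it is emitted from its latent state."""

    name: str
    kind: str  # continuous | binary | categorical
    n_levels: int | None = None  # categorical only
    prevalence: float = 0.5  # binary only: target marginal frequency
    loc: float = 0.0  # continuous only: emitted value = loc + scale * latent
    scale: float = 1.0


@dataclass(frozen=True)
class CausalEdge:
    source: str
    target: str
    lag: int
    coefficient: float


@dataclass(frozen=True)
class OutcomeParent:
    variable: str
    lag: int
    coefficient: float  # log-odds per latent-unit


@dataclass
class TrueGraph:
    """Ground-truth planted causal structure (cross-variable edges only)."""

    nodes: list[str]
    edges: list[CausalEdge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.lag < 1:
                raise ValueError(f"edge {e.source}->{e.target}: lag must be >= 1")
            if not np.isfinite(e.coefficient):
                raise ValueError(f"edge {e.source}->{e.target}: non-finite coefficient")
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e.source}->{e.target} names undeclared variable")

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "edges": [asdict(e) for e in self.edges]}


@dataclass
class SynthConfig:
    """Full description of one synthetic cohort.

    ``autoregression`` is the common diagonal lag-1 coefficient giving each
    latent some persistence across waves; planted ``causal_edges`` add the
    cross-variable structure on top of it.
    """

    n_individuals: int
    variables: list[VariableSpec]
    n_waves: int = 4
    true_lag_order: int = 1
    autoregression: float = 0.3
    causal_edges: list[CausalEdge] = field(default_factory=list)
    outcome_parents: list[OutcomeParent] = field(default_factory=list)
    outcome_intercept: float = 0.0
    noise_sd: float = 1.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_waves < self.true_lag_order + 2:
            raise ValueError(
                f"n_waves ({self.n_waves}) must be >= true_lag_order + 2 "
                f"({self.true_lag_order + 2})"
            )
        if self.noise_sd <= 0 and self.noise_sd != 0.0:
            raise ValueError("noise_sd must be >= 0")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        for e in self.causal_edges:
            if e.source not in names or e.target not in names:
                raise ValueError(f"causal edge {e.source}->{e.target} names undeclared variable")
            if e.lag < 1 or e.lag > self.true_lag_order:
                raise ValueError(
                    f"causal edge lag {e.lag} outside 1..true_lag_order ({self.true_lag_order})"
                )
        for p in self.outcome_parents:
            if p.variable not in names:
                raise ValueError(f"outcome parent {p.variable} not declared")
        for v, r in self.missing_rates.items():
            if v not in names:
                raise ValueError(f"missing rate given for undeclared variable {v}")
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {v} outside [0, 1]")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def coefficient_matrices(self) -> np.ndarray:
        """Latent VAR matrices, shape (p, n, n); A[k][i, j] = effect of
        variable j's lag-(k+1) value in the equation for variable i."""
        names = self.variable_names
        n = len(names)
        idx = {v: i for i, v in enumerate(names)}
        A = np.zeros((self.true_lag_order, n, n))
        A[0] += np.eye(n) * self.autoregression
        for e in self.causal_edges:
            A[e.lag - 1, idx[e.target], idx[e.source]] += e.coefficient
        return A

    def true_graph(self) -> TrueGraph:
        return TrueGraph(nodes=self.variable_names, edges=list(self.causal_edges))

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(
    n_individuals: int = 11_789,
    seed: int = 0,
    calibrate: bool = True,
    target_prevalence: float | None = None,
) -> SynthConfig:
    """CHARLS-like default cohort: 4 biennial waves, 10 variables with
    marginal frequencies matching the published cohort description, five
    planted lag-1 edges with |coefficient| >= 0.5, a rare stroke outcome
    (prevalence ~8.6%) driven by lagged disability / hypertension /
    IADL / self-rated-health, and one variable ('age') with 15%
    missingness to exercise the >10% drop rule end to end."""
    if target_prevalence is None:
        target_prevalence = cohort_prevalence("stroke")
    variables = [
        VariableSpec("age", "continuous", loc=65.0, scale=9.24),
        VariableSpec("gender", "binary", prevalence=cohort_prevalence("female")),
        VariableSpec("smoken", "binary", prevalence=cohort_prevalence("smoken")),
        VariableSpec("disability", "binary", prevalence=cohort_prevalence("disability")),
        VariableSpec("hibpe", "binary", prevalence=cohort_prevalence("hibpe")),
        VariableSpec("dyslipe", "binary", prevalence=cohort_prevalence("dyslipe")),
        VariableSpec("memrye", "binary", prevalence=cohort_prevalence("memrye")),
        VariableSpec("adl", "continuous", loc=0.51, scale=1.19),
        VariableSpec("iadl", "continuous", loc=0.64, scale=1.25),
        VariableSpec("srh", "continuous", loc=2.95, scale=1.01),
    ]
    causal_edges = [
        CausalEdge("srh", "memrye", 1, 0.6),
        CausalEdge("disability", "adl", 1, 0.7),
        CausalEdge("hibpe", "dyslipe", 1, 0.6),
        CausalEdge("age", "iadl", 1, 0.5),
        CausalEdge("gender", "smoken", 1, -0.5),
    ]
    outcome_parents = [
        OutcomeParent("disability", 1, 0.9),
        OutcomeParent("hibpe", 1, 0.8),
        OutcomeParent("iadl", 1, 0.6),
        OutcomeParent("srh", 1, -0.6),
    ]
    missing_rates = {
        "age": 0.15,  # above the 10% drop threshold by design
        "smoken": 0.02,
        "disability": 0.03,
        "hibpe": 0.03,
        "dyslipe": 0.04,
        "memrye": 0.02,
        "adl": 0.05,
        "iadl": 0.05,
        "srh": 0.02,
    }
    cfg = SynthConfig(
        n_individuals=n_individuals,
        variables=variables,
        causal_edges=causal_edges,
        outcome_parents=outcome_parents,
        missing_rates=missing_rates,
        seed=seed,
    )
    if calibrate:
        cfg.outcome_intercept = calibrate_intercept(cfg, target_prevalence)
    return cfg


# ---------------------------------------------------------------------------
# latent simulation


def _simulate_latents(
    config: SynthConfig,
    n_individuals: int,
    rng: np.random.Generator,
    return_noise: bool = False,
):
    """Latent states, shape (n_individuals, _WARMUP + n_waves, n_vars);
    optionally also the innovation draws, so the VAR recursion
    L_t = sum_k A_k L_{t-k} + eps_t can be verified exactly."""
    n = len(config.variables)
    p = config.true_lag_order
    A = config.coefficient_matrices()
    T = _WARMUP + config.n_waves
    L = np.zeros((n_individuals, T, n))
    L[:, :p, :] = rng.standard_normal((n_individuals, p, n)) * config.noise_sd
    eps = rng.standard_normal((n_individuals, T, n)) * config.noise_sd
    for t in range(p, T):
        acc = eps[:, t, :]
        for k in range(p):
            acc = acc + L[:, t - k - 1, :] @ A[k].T
        L[:, t, :] = acc
    if return_noise:
        return L, eps
    return L


def _outcome_linear_predictor(config: SynthConfig, latents: np.ndarray) -> np.ndarray:
    """Per-(individual, wave) log-odds contribution of the lagged parents
    (without intercept); shape (n_individuals, n_waves).  Lags reach into
    the burn-in so every observed wave has well-defined parents."""
    names = config.variable_names
    idx = {v: i for i, v in enumerate(names)}
    n_ind = latents.shape[0]
    eta = np.zeros((n_ind, config.n_waves))
    for parent in config.outcome_parents:
        j = idx[parent.variable]
        for t in range(config.n_waves):
            eta[:, t] += parent.coefficient * latents[:, _WARMUP + t - parent.lag, j]
    return eta


def calibrate_intercept(
    config: SynthConfig,
    target_prevalence: float,
    n_sim: int = 50_000,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Intercept making the simulated per-row outcome prevalence match
    ``target_prevalence`` (bisection on one large fixed latent sample;
    deterministic given ``config.seed``)."""
    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    latents = _simulate_latents(config, n_sim, rng)
    eta = _outcome_linear_predictor(config, latents).ravel()

    def prevalence(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta)))))

    lo, hi = -30.0, 30.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = prevalence(mid)
        if abs(p_mid - target_prevalence) < tol:
            return mid
        if p_mid < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"intercept calibration did not converge to {target_prevalence} in {max_iter} bisections"
    )


# ---------------------------------------------------------------------------
# emission


def _emit_observed(config: SynthConfig, latents: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n_ind = latents.shape[0]
    obs = latents[:, _WARMUP:, :]  # (n_ind, n_waves, n_vars)
    frame = pd.DataFrame(
        {
            ID_COL: np.repeat(np.arange(n_ind), config.n_waves),
            WAVE_COL: np.tile(np.arange(config.n_waves), n_ind),
        }
    )
    for j, spec in enumerate(config.variables):
        latent = obs[:, :, j].ravel()
        if spec.kind == "continuous":
            frame[spec.name] = spec.loc + spec.scale * latent
        elif spec.kind == "binary":
            thr = np.quantile(latent, 1.0 - spec.prevalence)
            frame[spec.name] = (latent > thr).astype(float)
        elif spec.kind == "categorical":
            if not spec.n_levels or spec.n_levels < 2:
                raise ValueError(f"categorical {spec.name} needs n_levels >= 2")
            edges = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            codes = np.searchsorted(edges, latent, side="right")
            frame[spec.name] = pd.array([f"lvl{c}" for c in codes], dtype="string")
        else:
            raise ValueError(f"unknown kind {spec.kind!r} for {spec.name}")
    eta = config.outcome_intercept + _outcome_linear_predictor(config, latents)
    prob = 1.0 / (1.0 + np.exp(-eta))
    frame[OUTCOME_COL] = (rng.uniform(size=prob.shape) < prob).astype(float).ravel()
    return frame


def _apply_missingness(
    frame: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    for spec in config.variables:
        rate = config.missing_rates.get(spec.name, 0.0)
        if rate <= 0:
            continue
        mask = rng.uniform(size=len(frame)) < rate
        if spec.kind == "categorical":
            col = frame[spec.name].copy()
            col[mask] = pd.NA
            frame[spec.name] = col
        else:
            frame.loc[mask, spec.name] = np.nan
    return frame


def generate_panel(config: SynthConfig) -> tuple[PanelDataset, TrueGraph]:
    """Simulate one cohort: latent VAR dynamics, observed emissions, lagged
    Bernoulli outcome, MCAR missingness.  Byte-identical given the seed."""
    rng = np.random.default_rng(config.seed)
    latents = _simulate_latents(config, config.n_individuals, rng)
    frame = _emit_observed(config, latents, rng)
    frame = _apply_missingness(frame, config, rng)
    kinds = {v.name: v.kind for v in config.variables}
    return PanelDataset(frame, kinds), config.true_graph()


# ---------------------------------------------------------------------------
# persistence


def write_panel(panel: PanelDataset, graph: TrueGraph, config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the long-format CSV plus a JSON sidecar with the ground-truth
    graph and the generating config; returns the emitted paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "panel.csv"
    panel.frame.to_csv(csv_path, index=False)
    sidecar = out / "truth.json"
    with open(sidecar, "w") as fh:
        json.dump({"true_graph": graph.to_dict(), "config": config.to_dict()}, fh, indent=2)
    return {"panel": csv_path, "truth": sidecar}


def read_panel(csv_path: str | Path, kinds: dict[str, str] | None = None) -> PanelDataset:
    """Read a long-format panel CSV.  If ``kinds`` is not given, kinds are
    inferred: object/string columns are categorical, {0,1}-valued columns
    binary, everything else continuous."""
    frame = pd.read_csv(csv_path)
    if kinds is None:
        kinds = {}
        for c in frame.columns:
            if c in (ID_COL, WAVE_COL, OUTCOME_COL):
                continue
            col = frame[c]
            if col.dtype == object or pd.api.types.is_string_dtype(col):
                kinds[c] = "categorical"
            elif col.dropna().isin([0, 1]).all():
                kinds[c] = "binary"
            else:
                kinds[c] = "continuous"
        if not kinds:
            warnings.warn("no variable columns found in CSV")
    return PanelDataset(frame, kinds)
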
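"""End-to-end orchestration: synthesize/ingest -> preprocess -> temporal
features -> VAR/Granger -> GCN -> classifier evaluation -> explanation.

One YAML config drives the run; a single global seed is fanned out to the
stages by fixed offsets.  Every stage writes its artifacts to the output
directory and the run manifest records a config hash, stage timings and
sha256 checksums of every emitted file, so a rerun with identical config
and seed is checksum-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import explain as explain_mod
from . import gnn as gnn_mod
from . import modeling as modeling_mod
from . import preprocess as prep_mod
from . import synthetic as synth_mod
from . import var_granger as var_mod
from .panel import ID_COL, OUTCOME_COL, WAVE_COL, PanelDataset

# fixed seed offsets per stage (kept below 2**31 for any base seed the CLI accepts)
_OFFSETS = {"synth": 0, "cv": 11, "gnn": 23, "negatives": 31, "models": 41, "explain": 53}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"
    # input: synthetic by default; or a CSV path
    input_csv: str | None = None
    synth: dict = field(default_factory=dict)  # overrides for synthetic.default_config
    drop_threshold: float = 0.10
    sample_filter: bool = False
    lag_orders: tuple[int, ...] = (1, 2)
    var_p: int | str = 1
    var_p_max: int = 2
    var_criterion: str = "bic"
    granger_alpha: float = 0.05
    granger_correction: str | None = "fdr_bh"
    gnn_hidden: int = 16
    gnn_embed: int = 8
    gnn_learning_rate: float = 0.2
    gnn_epochs: int = 2000
    gnn_threshold: float = 0.5
    gnn_edge_policy: str = "validate"
    cv_folds: int = 5
    models: list[str] = field(default_factory=lambda: list(modeling_mod.MODEL_FAMILIES))
    feature_modes: list[str] = field(default_factory=lambda: ["all", "dynamic_causal"])
    smote_k: int = 5
    explain_model: str = "gradient_boosting"
    explain_permutations: int = 200
    explain_background: int = 100
    explain_rows: int = 100
    explain_curves: int = 2

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lag_orders"] = list(self.lag_orders)
        return d

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _OFFSETS[stage]


@dataclass
class RunManifest:
    config_hash: str
    timings: dict[str, float] = field(default_factory=dict)
    files: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_file(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# stages (each consumes its predecessor's in-memory product; the CLI offers
# file-based re-entry per stage)


def stage_synth(config: PipelineConfig, out: Path, manifest: RunManifest) -> PanelDataset:
    if config.input_csv:
        return synth_mod.read_panel(config.input_csv)
    overrides = dict(config.synth)
    cfg = synth_mod.default_config(seed=config.stage_seed("synth"), **overrides)
    panel, graph = synth_mod.generate_panel(cfg)
    paths = synth_mod.write_panel(panel, graph, cfg, out)
    manifest.add_file("panel", paths["panel"])
    manifest.add_file("truth", paths["truth"])
    return panel


def stage_features(
    config: PipelineConfig, panel: PanelDataset, out: Path, manifest: RunManifest
) -> prep_mod.FeatureMatrix:
    pre = prep_mod.PanelPreprocessor(
        drop_threshold=config.drop_threshold, sample_filter=config.sample_filter
    )
    clean = pre.fit(panel).transform(panel)
    fm = prep_mod.TemporalFeatures(lag_orders=tuple(config.lag_orders)).fit(clean).transform(clean)
    report_path = out / "preprocess_report.json"
    with open(report_path, "w") as fh:
        json.dump(pre.report(), fh, indent=2)
    features_path = out / "features.csv"
    fm.frame.to_csv(features_path, index=False)
    meta_path = out / "features_meta.json"
    with open(meta_path, "w") as fh:
        json.dump({c: dataclasses.asdict(m) for c, m in fm.columns.items()}, fh, indent=2)
    manifest.add_file("preprocess_report", report_path)
    manifest.add_file("features", features_path)
    manifest.add_file("features_meta", meta_path)
    return fm


def load_features(out: Path) -> prep_mod.FeatureMatrix:
    frame = pd.read_csv(out / "features.csv")
    with open(out / "features_meta.json") as fh:
        meta = {c: prep_mod.ColumnInfo(**m) for c, m in json.load(fh).items()}
    return prep_mod.FeatureMatrix(frame, meta)


def stage_granger(
    config: PipelineConfig, fm: prep_mod.FeatureMatrix, out: Path, manifest: RunManifest
) -> tuple[var_mod.VarFit, list[var_mod.GrangerResult]]:
    if config.var_p != "auto" and int(config.var_p) < 1:
        raise ValueError("var_p must be >= 1 (or 'auto')")
    if config.var_p_max < 1:
        raise ValueError("var_p_max must be >= 1")
    var = var_mod.PanelVAR(p=config.var_p, p_max=config.var_p_max, criterion=config.var_criterion)
    var.fit(fm)
    graph = var_mod.GrangerGraph(
        p=var.p_, alpha=config.granger_alpha, correction=config.granger_correction
    ).fit(fm)
    edges_path = out / "granger_edges.csv"
    graph.to_frame().to_csv(edges_path, index=False)
    var_path = out / "var_fit.json"
    with open(var_path, "w") as fh:
        json.dump(
            {
                "variables": var.variables_,
                "p": var.p_,
                "coef": var.coef_.tolist(),
                "intercept": var.intercept_.tolist(),
                "sigma": var.sigma_.tolist(),
                "t_eff": var.t_eff_,
                "aic": var.aic_,
                "bic": var.bic_,
                "spectral_radius": var.spectral_radius_,
            },
            fh,
            indent=2,
        )
    manifest.add_file("granger_edges", edges_path)
    manifest.add_file("var_fit", var_path)
    return var.result_, graph.results_


def load_var_fit(out: Path) -> var_mod.VarFit:
    with open(out / "var_fit.json") as fh:
        d = json.load(fh)
    return var_mod.VarFit(
        variables=d["variables"],
        lag_order=d["p"],
        coef=np.asarray(d["coef"]),
        intercept=np.asarray(d["intercept"]),
        sigma=np.asarray(d["sigma"]),
        t_eff=d["t_eff"],
        aic=d["aic"],
        bic=d["bic"],
    )


def load_granger_results(out: Path, p: int) -> list[var_mod.GrangerResult]:
    frame = pd.read_csv(out / "granger_edges.csv")
    return [
        var_mod.GrangerResult(
            source=r.source,
            target=r.target,
            lag_order=p,
            f_statistic=r.F,
            p_value=r.p_value,
            df_num=p,
            df_den=0,
            significant=bool(r.significant),
        )
        for r in frame.itertuples()
    ]


def stage_gnn(
    config: PipelineConfig,
    var_fit: var_mod.VarFit,
    granger: list[var_mod.GrangerResult],
    out: Path,
    manifest: RunManifest,
) -> gnn_mod.CausalGraph:
    variables = var_fit.variables
    features = gnn_mod.build_node_features(var_fit)
    edges = gnn_mod.build_edge_training_set(granger, variables, seed=config.stage_seed("negatives"))
    n = len(variables)
    A = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(variables)}
    for r in granger:
        if r.significant:
            A[idx[r.source], idx[r.target]] = 1
    predictor = gnn_mod.GCNLinkPredictor(
        hidden=config.gnn_hidden,
        embed=config.gnn_embed,
        learning_rate=config.gnn_learning_rate,
        epochs=config.gnn_epochs,
        threshold=config.gnn_threshold,
        edge_policy=config.gnn_edge_policy,
        seed=config.stage_seed("gnn"),
    ).fit(features, edges, A)
    granger_set = {(r.source, r.target) for r in granger if r.significant}
    graph = predictor.predict_graph(variables, granger_set)
    graph_path = out / "causal_graph.json"
    graph.write_json(graph_path)
    emb_path = out / "embeddings.csv"
    graph.embeddings_frame().to_csv(emb_path, index_label="variable")
    manifest.add_file("causal_graph", graph_path)
    manifest.add_file("embeddings", emb_path)
    return graph


def load_causal_graph(out: Path) -> gnn_mod.CausalGraph:
    with open(out / "causal_graph.json") as fh:
        d = json.load(fh)
    return gnn_mod.CausalGraph(
        nodes=d["nodes"],
        edges=[gnn_mod.PredictedEdge(**e) for e in d["edges"]],
        granger_only=[gnn_mod.PredictedEdge(**e) for e in d["granger_only"]],
        embeddings=np.asarray(d["embeddings"]),
        threshold=d["threshold"],
    )


def stage_modeling(
    config: PipelineConfig,
    fm: prep_mod.FeatureMatrix,
    graph: gnn_mod.CausalGraph,
    out: Path,
    manifest: RunManifest,
) -> modeling_mod.ModelReport:
    reports = []
    for mode in config.feature_modes:
        design = modeling_mod.assemble_features(fm, graph, mode=mode)
        plan = modeling_mod.stratified_group_kfold(
            design.y, design.groups, k=config.cv_folds, seed=config.stage_seed("cv")
        )
        reports.append(
            modeling_mod.train_and_evaluate(
                design,
                plan,
                models=config.models,
                seed=config.stage_seed("models"),
                smote_k=config.smote_k,
            )
        )
    report = modeling_mod.ModelReport.concat(reports)
    csv_path = out / "model_report.csv"
    report.to_csv(csv_path)
    folds_path = out / "model_report_folds.json"
    with open(folds_path, "w") as fh:
        json.dump(report.table.to_dict(orient="records"), fh, indent=2)
    manifest.add_file("model_report", csv_path)
    manifest.add_file("model_report_folds", folds_path)
    return report


def stage_explain(
    config: PipelineConfig,
    fm: prep_mod.FeatureMatrix,
    graph: gnn_mod.CausalGraph,
    out: Path,
    manifest: RunManifest,
) -> explain_mod.AttributionResult:
    mode = "dynamic_causal" if "dynamic_causal" in config.feature_modes else config.feature_modes[0]
    design = modeling_mod.assemble_features(fm, graph, mode=mode)
    X = design.X.to_numpy(dtype=float)
    X_bal, y_bal = modeling_mod.smote_oversample(
        X, design.y, k_neighbors=config.smote_k, seed=config.stage_seed("models")
    )
    model = modeling_mod.build_models([config.explain_model], seed=config.stage_seed("models"))[
        config.explain_model
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_bal, y_bal)
    rng = np.random.default_rng(config.stage_seed("explain"))
    n_explain = min(config.explain_rows, len(X))
    rows = rng.choice(len(X), size=n_explain, replace=False)
    explainer = explain_mod.ShapleyExplainer(
        n_permutations=config.explain_permutations,
        background_size=config.explain_background,
        seed=config.stage_seed("explain"),
    )
    attr = explainer.explain(model, X, X[rows], feature_names=design.manifest)
    attr_path = out / "attribution.csv"
    attr.to_frame().to_csv(attr_path, index=False)
    ranking = explainer.ranking()
    rank_path = out / "importance.csv"
    pd.DataFrame(ranking, columns=["feature", "mean_abs_shap"]).to_csv(rank_path, index=False)
    manifest.add_file("attribution", attr_path)
    manifest.add_file("importance", rank_path)
    n_curves = 0
    for name, _ in ranking:
        if n_curves >= config.explain_curves:
            break
        vals = X[rows, design.manifest.index(name)]
        if np.ptp(vals) == 0 or len(vals) < 20:
            continue
        curve = explainer.curve(vals, name)
        curve_path = out / f"curve_{name}.csv"
        curve.to_frame().to_csv(curve_path, index=False)
        manifest.add_file(f"curve_{name}", curve_path)
        n_curves += 1
    return attr


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing every artifact plus a manifest.

    Any stage error aborts with the stage name attached and the partial
    manifest written to the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config))

    state: dict = {}
    stages = [
        ("synthetic_data", lambda: state.update(panel=stage_synth(config, out, manifest))),
        (
            "preprocessing",
            lambda: state.update(fm=stage_features(config, state["panel"], out, manifest)),
        ),
        (
            "var_granger",
            lambda: state.update(
                var_granger=stage_granger(config, state["fm"], out, manifest)
            ),
        ),
        (
            "causal_gnn",
            lambda: state.update(
                graph=stage_gnn(config, *state["var_granger"], out, manifest)
            ),
        ),
        (
            "modeling",
            lambda: state.update(
                report=stage_modeling(config, state["fm"], state["graph"], out, manifest)
            ),
        ),
        (
            "explain",
            lambda: state.update(
                attr=stage_explain(config, state["fm"], state["graph"], out, manifest)
            ),
        ),
    ]
    for name, run in stages:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                run()
            manifest.warnings.extend(f"{name}: {w.message}" for w in caught)
        except Exception as exc:
            manifest.write(out / "manifest.json")
            raise PipelineError(name, manifest, exc) from exc
        manifest.timings[name] = round(time.perf_counter() - t0, 4)
    manifest.write(out / "manifest.json")
    return manifest
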
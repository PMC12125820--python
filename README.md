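# dyncausal

Dynamic causal inference for longitudinal risk prediction.  `dyncausal`
implements, as composable scikit-learn-style estimators, a pipeline for
predicting a rare binary health outcome (stroke) from panel survey data
while exploiting the *temporal causal structure* among health variables:

1. **Temporal features** — lag and difference columns per variable,
   `x_lag_l(t) = x(t−l)` and `x_diff_l(t) = x(t) − x(t−l)`, computed
   strictly within individual.
2. **Panel VAR** — `X_t = A_1 X_{t−1} + … + A_p X_{t−p} + ε_t` fitted by
   per-equation OLS on stacked within-individual transitions, with
   AIC/BIC lag-order selection.
3. **Granger edge discovery** — bivariate nested-regression F tests for
   all ordered variable pairs, Benjamini–Hochberg-controlled at q = 0.05,
   producing a preliminary directed causal graph.
4. **GCN link prediction** — a two-layer graph convolutional network
   `H^(l+1) = σ(D̃^{−1/2} Ã D̃^{−1/2} H^(l) W^(l))` over VAR-coefficient
   node features, trained with binary cross-entropy on a balanced edge
   set, scoring directed pairs with a bilinear decoder
   `σ(zᵢᵀ R z_j)`; the final dynamic causal graph and node embeddings.
5. **Classifier bank** — seven families (random forest, logistic
   regression, XGBoost, SVM, KNN, gradient boosting, MLP) compared on
   "all features" vs "dynamic causal" feature sets under SMOTE
   rebalancing and leakage-free stratified *group* K-fold CV (whole
   individuals per fold), reporting AUC, accuracy, precision, recall,
   F1 and MCC.
6. **Explanation** — Monte-Carlo permutation Shapley attributions,
   mean-|SHAP| importance ranking, and LOWESS main-effect curves with a
   curvature-based inflection annotation.

Because the cohort it targets (CHARLS, 2011–2018, 11,789 adults) is
access-restricted, the package ships a first-class **synthetic cohort
generator**: a latent Gaussian VAR with planted lagged causal edges,
threshold-emitted binary variables matching the published prevalences,
a calibrated rare outcome (≈8.6% per row), and MCAR missingness —
giving every stage a ground truth to be tested against.  See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import dyncausal as dc
import numpy as np

# a 2,000-person, fully observed synthetic cohort with 5 planted edges
cfg = dc.default_config(n_individuals=2000, seed=1, calibrate=False)
cfg.missing_rates = {}
panel, truth = dc.generate_panel(cfg)

clean = dc.PanelPreprocessor().fit(panel).transform(panel)
features = dc.TemporalFeatures(lag_orders=(1, 2)).fit(clean).transform(clean)

var = dc.PanelVAR(p=1).fit(features)
results = dc.preliminary_edges(features, p=1)
found = {(r.source, r.target) for r in results if r.significant}
print(sorted(found))
print(sorted(truth.edge_set()))
```

prints

```
[('age', 'iadl'), ('disability', 'adl'), ('gender', 'smoken'), ('hibpe', 'dyslipe'), ('srh', 'memrye')]
[('age', 'iadl'), ('disability', 'adl'), ('gender', 'smoken'), ('hibpe', 'dyslipe'), ('srh', 'memrye')]
```

— all five planted lag-1 edges recovered with no false positives at
this sample size.  Continuing through the GCN and the classifier bank:

```python
ets = dc.build_edge_training_set(results, var.variables_, seed=1)
F = dc.build_node_features(var.result_)
idx = {v: i for i, v in enumerate(var.variables_)}
A = np.zeros((10, 10))
for s, t in found:
    A[idx[s], idx[t]] = 1
gcn = dc.GCNLinkPredictor(seed=1).fit(F, ets, A)
graph = gcn.predict_graph(var.variables_, found)

for mode in ("all", "dynamic_causal"):
    design = dc.assemble_features(features, graph, mode=mode)
    plan = dc.stratified_group_kfold(design.y, design.groups, k=3, seed=1)
    report = dc.train_and_evaluate(design, plan, models=["gradient_boosting"], seed=1)
    print(mode, round(report.mean_metric("gradient_boosting", mode, "auc"), 3))
```

prints

```
all 0.632
dynamic_causal 0.782
```

— the dynamic-causal feature set (causal variables, their lag/diff
transforms and GCN embeddings) lifts gradient-boosting AUC by ~0.15
over the raw per-wave variables, because the planted outcome depends on
*lagged* parents that only the temporal features expose.

A full run (synthesis → preprocessing → VAR/Granger → GCN → evaluation
→ SHAP) from one YAML config:

```bash
dyncausal run --config cfg.yaml --seed 1 --out run/
dyncausal synth --out cohort/        # or stage by stage
dyncausal granger --out run/
```

Every run writes a manifest with per-file sha256 checksums; identical
config + seed reproduces identical artifacts.

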
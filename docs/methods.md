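# Methods

`dyncausal` implements a dynamic-causal risk-prediction pipeline for
longitudinal panel cohorts: temporal feature construction, pooled panel
VAR with Granger causal-edge discovery, a GCN link predictor over
VAR-coefficient node features, fusion of the resulting dynamic-causal
features into a classifier bank evaluated under SMOTE and grouped
stratified cross-validation, and sampling-Shapley explanation.  This note
records the model assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic cohort generator

The generator emulates a CHARLS-like biennial panel: `n` individuals
observed over 4 waves (coded 0–3), ~10 health variables, and a rare
binary stroke outcome.  All variables — continuous and binary — are
emitted from a latent Gaussian VAR(p):

    L_t = A_1 L_{t-1} + … + A_p L_{t-p} + ε_t,   ε_t ~ N(0, σ² I)

with `A_1 = ρ I + planted cross edges` (persistence ρ = 0.3 by default,
innovation σ = 1).  Thirty burn-in steps precede wave 0 so observed waves
are near-stationary and lagged outcome parents are defined at every wave.

* **Continuous variables** are affine transforms of their latents, with
  location/scale matching the published cohort means/SDs (age 65.00 ± 9.24,
  ADL 0.51 ± 1.19, IADL 0.64 ± 1.25, Srh 2.95 ± 1.01).
* **Binary variables** are threshold indicators of their latents at the
  empirical quantile matching the published prevalence (hypertension
  42.90%, disability 44.35%, dyslipidemia 76.58%, memory disease 95.33%,
  smoking 74.10%, female 53.73%).  Thresholding on latents keeps the VAR
  dynamics well defined while emitting realistic binaries.
* **Outcome**: stroke at wave t is Bernoulli(sigmoid(c + Σ_k β_k
  L_parent_k(t − lag_k))) with parents lagged disability (β = 0.9),
  hypertension (0.8), IADL (0.6) and self-rated health (−0.6).  The
  intercept c is calibrated by bisection on a fixed 50,000-individual
  latent sample so the per-row prevalence matches the published
  1,011/11,789 ≈ 8.58%.
* **Missingness** is MCAR per variable (the source cohort's mechanism is
  not documented).  `age` carries a 15% rate by default so the >10%
  variable-drop rule is exercised end to end; the remaining rates are
  2–5%.

The five planted cross-variable edges (coefficients |0.5–0.7|) form
**vertex-disjoint pairs** (srh→memrye, disability→adl, hibpe→dyslipe,
age→iadl, gender→smoken).  This is deliberate: bivariate Granger analysis
genuinely detects chain- and fork-induced dependence (i→j→k makes i
predictive of k), so a ground truth containing chains would make edge
precision/recall ill-posed.  Disjoint pairs give exactly-null
non-edges and a well-defined recovery target.

What the generator does **not** emulate: survey weights, MNAR
missingness, unequal calendar spacing between waves (the lag operator is
wave-based), time-invariance of demographic variables (the "gender"
latent evolves like the others; only its marginal frequency is matched),
and the skewness of real ADL/IADL score distributions.  Passing tests
therefore demonstrate correctness of the machinery on a cohort whose
dynamics are exactly the model's own assumptions — not performance on
real survey data.

## Preprocessing

Fixed order: (1) drop variables with missing fraction **strictly** above
10% ("exceeding" read literally; denominator = all individual-wave
rows); (2) forward-fill within individual by wave, then overall mean
(continuous) or mode (binary/categorical, ties to the smallest level)
for residual gaps; (3) lexicographic label encoding and population
z-scoring (binary columns untouched); (4) lag/difference features

    x_lag_l(t) = x(t − l),   x_diff_l(t) = x(t) − x(t − l),   l ∈ {1, 2}

computed strictly within individual and wave-aware (a lag never crosses
an individual boundary or a wave gap).  `build_temporal_features`
rejects unimputed or unencoded input, which pins the pipeline order.
Rows lacking lag support keep missing lag/diff cells and are excluded
from VAR and causal-mode classifier fitting rather than zero-filled — no
pre-baseline history is fabricated.

`PanelPreprocessor` is a fit/transform estimator: fitting on the full
panel reproduces the global preprocessing-before-modeling order of the
original workflow; fitting on a training fold and transforming held-out
rows gives the leakage-free variant.  The global default is kept because
it mirrors the source workflow; the per-fold option exists and is
documented rather than silently substituted.  An optional
individual-level filter (excluding individuals with >10% of their cells
missing) implements the alternative sample-wise reading of the exclusion
rule; it is off by default and no claim is made about which reading
produced the published cohort size.

## Panel VAR and Granger discovery

A pooled panel VAR is fitted by per-equation OLS on stacked
within-individual transitions: response X_t paired with (1, X_{t−1}, …,
X_{t−p}) from the same individual, coefficients shared across
individuals.  With 4 waves per person an individual-level VAR is
unidentifiable; pooling honors the within-individual temporal structure
by never letting a transition row span individuals.  Intercepts are
included (near-zero on standardized data, harmless otherwise).
Information criteria use the multivariate form `log det Σ̂ + penalty ·
p·n²/T`, compared across orders on the common transition sample
supported by the largest candidate order; ties go to the smaller order.
Stability (companion spectral radius < 1) is logged, not enforced.

Granger tests are bivariate nested-regression F tests (unrestricted:
own lags + source lags; restricted: own lags), with a conditional
variant behind a flag.  **Multiple testing:** a graph over n variables
runs n(n−1) simultaneous tests; at n = 10 and raw α = 0.05 the null
pairs alone contribute ≈ 4 false edges in expectation, which would
swamp a 5-edge graph.  Edge discovery therefore applies
Benjamini–Hochberg FDR control at level α by default;
`correction=None` restores the raw per-test threshold.  Per-test
calibration (size 0.05 under the null, uniform p-values) is unaffected
and covered by the acceptance suite.

## GCN link predictor

Node features follow the outgoing-influence convention: row i
concatenates, for each lag k, the coefficients of variable i's lag-k
value in every equation (column i of each A_k under this package's
equation-row storage).  Two graph-convolution layers

    H^(1) = relu(Â F W^(0)),   Z = Â H^(1) W^(1),   Â = D̃^{-1/2}(A_sym + I)D̃^{-1/2}

run on the symmetrized preliminary Granger graph (the symmetric
normalization presumes an undirected adjacency); edge direction lives in
the labels and the decoder.  A plain dot-product decoder is symmetric in
(i, j) and cannot represent direction at all, so edges are scored with a
bilinear form sigmoid(z_i' R z_j) with R trained jointly — the minimal
standard directed link-prediction decoder.

Training: balanced edge set (all significant Granger edges as
positives, an equal-size seeded uniform sample of non-significant
ordered pairs as negatives), full-batch gradient descent on mean binary
cross-entropy with global-norm gradient clipping (threshold 5),
Gaussian 1/√fan-in initialization, hidden width 16, embedding dimension
8, learning rate 0.2, 2,000 epochs, fixed seed.  None of these is
prescribed by the source method; they were chosen so the loss descends
monotonically late in training on the default problem sizes.  Gradients
are hand-derived and verified against central finite differences.

**Final-graph policy.**  The training set contains only ~2·|edges|
labelled pairs, while the final graph concerns all n(n−1) ordered pairs;
thresholding every pair's score is an uncontrolled extrapolation
(nothing in training pushes the unlabeled pairs below threshold, and
reverse pairs of true edges are rarely sampled as negatives).  The
default policy is therefore **validate**: the final graph keeps the
Granger edges the GNN scores ≥ 0.5 (inclusive), records Granger edges
scored below threshold with provenance `granger_only`, and records novel
above-threshold pairs as `gnn_predicted` without admitting them to the
edge set.  `edge_policy="score_all"` gives the literal all-pairs
reading; both are recoverable from the output.

## Classifier evaluation

Two feature sets: **all** (base variables as observed) and
**dynamic_causal** (variables incident to the final causal graph, their
lag/diff columns, plus each such variable's 8 embedding coordinates
broadcast as constant columns — the desk-scale reading of fusing node
embeddings with tabular features).  Labels are the per-wave stroke
indicator; grouping whole individuals into folds makes per-wave rows
safe against identity leakage.

Cross-validation is a greedy stratified group K-fold (K = 5, implied by
the published 80/20 split): groups are assigned to the fold with the
fewest positives, then the fewest rows, so fold sizes are as equal as
possible — on 11,789 single-row individuals this reproduces test folds
of {2,358 × 4, 2,357} and the printed 9,431/2,358 split.  SMOTE
(k = 5 neighbours, u ~ U(0,1) interpolation, originals preserved) is
applied to training partitions only; metrics (AUC, accuracy, precision,
recall, F1, MCC at threshold 0.5) are computed on untouched test rows.
The seven classifier families (random forest, logistic regression,
XGBoost, SVM, KNN, gradient boosting, MLP) use library defaults with
fixed seeds; no hyperparameter search.  A paired-bootstrap AUC
comparison is available as an optional diagnostic; it is not claimed to
reproduce any particular published significance procedure.

## Shapley explanation

Model-agnostic Monte-Carlo permutation Shapley with background-mean
imputation: for each random feature ordering, features switch one at a
time from the background mean to the instance value and score increments
are averaged (200 permutations, 100 background rows by default; an exact
enumeration mode covers small feature counts).  Because the reference is
a single mean vector, increments telescope and efficiency
(base + Σφ = f(x)) holds exactly, not just in expectation.  Main-effect
curves are LOWESS (tricube, span 0.6, one robustness iteration) of φ
against the feature value on a 100-point grid; the annotated
"inflection" is the grid point of maximum curvature (absolute second
difference) — a heuristic, labelled as such, since no formal definition
exists for the reference point.

## Problem sizes and numerical choices

Default verification sizes: structure recovery at 2,000 individuals
(10 seeds), Granger calibration on 1,000 replicate null panels of 500
individuals, order selection at 2,000 individuals, uplift at 1,200
individuals with 3 folds over 5 seeds, full-cohort runs at 11,789 for
split arithmetic and prevalence.  Structure recovery is measured on
fully observed panels (missingness off) so the recovery target includes
all five planted edges; the end-to-end pipeline keeps the default 15%
missing variable and consequently drops it, which is exercised
separately.  Degenerate inputs fail loudly: zero-variance continuous
variables, all-variables-dropped, perfect-fit Granger regressions,
rank-deficient VAR designs, empty preliminary graphs.

## Known limitations

* Pooled VAR assumes coefficient homogeneity across individuals; no
  mixed-effects extension.
* Bivariate Granger cannot distinguish direct edges from chains/forks;
  the conditional variant mitigates but is not the default.
* No stationarity testing or cointegration handling; 4 waves would not
  support them.
* The GCN adds no edges under the default policy; with richer label sets
  (larger graphs) `score_all` becomes meaningful.
* Constant-per-variable embedding columns are uninformative for
  tree-based learners; they are retained for fidelity to the fusion
  design, not for predictive value.
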
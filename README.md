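# omicsgat

Multi-omics integration for cancer subtype prediction with **graph attention
networks over patient similarity graphs**, plus a survival pipeline that asks
whether the learned embeddings stratify patient risk better than the raw
features they were trained on.

The package is aimed at computational biologists working with cohorts that
carry several molecular layers per patient — mRNA / miRNA / lncRNA
expression, DNA methylation, copy number alteration, somatic mutation,
co-expression module eigengenes and clinical covariates (codes `EXP`, `MIR`,
`LNC`, `MET`, `CNA`, `MUT`, `COE`, `CLI`). Because real cohorts of this kind
sit behind portals and access controls, the package ships a first-class
synthetic cohort generator that emulates subtype-structured omics and
subtype-dependent censored survival, so every stage is runnable and testable
out of the box.

## The model

For each omics layer a **patient similarity graph** links every patient to
its k = 3 most similar peers (Pearson correlation for continuous layers,
Jaccard for binary mutation profiles, Gower for mixed clinical tables). A
two-layer **graph attention network (GAT)** is trained per layer as a
transductive node classifier on subtype labels. For node *i* with
neighborhood *N(i)* (graph neighbors plus a self-loop):

```
c_ij     = LeakyReLU( aᵀ [W x_i ‖ W x_j] )            attention score
α_ij     = exp(c_ij) / Σ_{k∈N(i)} exp(c_ik)           softmax over N(i)
h_i      = σ( Σ_{j∈N(i)} α_ij W x_j )                 neighbor aggregation
```

with `W ∈ R^{p×m}` and `a ∈ R^{2p}` learned, LeakyReLU slope 0.2, ELU after
layer 1 and a softmax cross-entropy head at layer 2. Layer 1 may run H
attention heads whose outputs are concatenated. The forward and reverse
passes are plain numpy; gradients are hand-derived and verified against
finite differences in the test suite.

Per-omics hidden embeddings `h_i` are **concatenated across layers** and fed
to an MLP subtype classifier, evaluated by accuracy, weighted-F1 and
macro-F1 over repeated stratified splits — including the full sweep of all
2^T − 1 omics combinations and the leave-one-omics-out ablation.

Embeddings are evaluated a second way through a **risk pipeline**: LASSO
selection (grid-searched α) → multivariate Cox proportional hazards
(Breslow ties) → risk score `Σ X_i·Coef_i` over predictors with p < 0.05 →
median split → Kaplan–Meier curves, log-rank test and hazard ratio.

## Worked example

```python
import numpy as np
import omicsgat as og

spec = og.SyntheticSpec(n_samples=400, seed=0)          # 5 subtypes
matrices, labels, clinical = og.generate_multiomics_cohort(spec)
survival = og.generate_survival_outcomes(labels, spec)

exp = og.zscore_normalize(matrices[0])                  # EXP layer
graph = og.build_topk_graph(og.pearson_similarity(exp), k=3)

y = np.asarray(labels.labels)
train, val, test = og.stratified_split(labels, seed=0)
clf = og.GATClassifier(hidden_dim=64, epochs=200, random_state=0)
clf.fit(exp.values, y, graph=graph, train_idx=train, val_idx=val)
report = og.evaluate_metrics(clf.predict()[test], y[test])

res = og.risk_stratify(clf.embedding_, survival, seed=0)
```

Output:

```
cohort: 400 samples, {'EXP': 200, 'MET': 150, 'MUT': 100}
EXP graph: 400 nodes, 816 edges
EXP-only GAT test metrics: accuracy=1.000 weighted_f1=1.000 macro_f1=1.000
embedding shape: (400, 64)
risk split: 200 low / 200 high, log-rank chi2=18.1, p=2.08e-05, HR=1.65
```

The edge count (816 for n = 400, k = 3) falls in the union-symmetrization
band [⌈3n/2⌉, 3n] = [600, 1200]. At the generator's default effect size
(3 SD mean shifts on 20% of features) the subtypes are cleanly separable, so
the per-layer GAT reaches perfect test metrics; the embedding-based risk
split separates survival because the synthetic hazard depends on subtype.

An end-to-end run — cohort synthesis, preprocessing, all graphs, all GATs,
combination sweep and survival comparison, with a manifest of every
parameter and seed — is one call (or `omicsgat run --outdir out`):

```python
from omicsgat import demo_config, run_pipeline
result = run_pipeline(demo_config(seed=0), "out")
```

The CLI exposes each stage separately: `omicsgat synth | preprocess | graph
| train | classify | survival | run`.

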
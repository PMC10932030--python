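"""End-to-end orchestration: synthesize-or-load -> preprocess -> graphs ->
per-omics GATs -> fusion/classification sweep -> survival comparison.

Every random draw derives from the config seed; a manifest records all
parameters so a rerun reproduces every number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, preprocess, similarity, survival as surv
from .gat import EmbeddingMatrix, train_gat
from .io import (CONTINUOUS_CODES, OmicsMatrix, PipelineConfig, logger,
                 write_labels, write_matrix, write_survival)
from .synthetic import SyntheticSpec, generate_multiomics_cohort, generate_survival_outcomes


def demo_config(seed: int = 0, **overrides) -> PipelineConfig:
    """CI-scale synthetic demo: 4 omics layers, 64-d embeddings."""
    params = {"omics_codes": ["CLI", "EXP", "MET", "MUT"], "gat_hidden_dim": 64,
              "seed": seed}
    params.update(overrides)
    return PipelineConfig(**params)


def prepare_cohort(config: PipelineConfig, spec: SyntheticSpec | None = None):
    """Synthesize (or accept) a cohort and apply the cleaning rules.

    Returns ``(processed matrices dict, clinical, labels, survival,
    node_features, graphs dict)``: continuous layers are feature-selected and
    z-scored, the clinical table is one-hot encoded, one top-k similarity
    graph is built per omics code, and the node feature matrix is the
    concatenation of all processed layers (shared by every per-omics GAT).
    """
    if spec is None:
        spec = SyntheticSpec(seed=config.seed,
                             omics_codes=tuple(config.omics_codes))
    matrices, labels, clinical = generate_multiomics_cohort(spec)
    survival_table = generate_survival_outcomes(labels, spec)
    matrices, labels, survival_table, clinical = preprocess.intersect_common_samples(
        matrices, labels, survival_table, clinical)

    processed: dict[str, OmicsMatrix] = {}
    graphs: dict[str, similarity.PatientGraph] = {}
    for mat in matrices:
        code = mat.omics_code
        m = preprocess.select_features(mat, labels)
        if code in CONTINUOUS_CODES:
            m = preprocess.zscore_normalize(m)
        processed[code] = m
        graphs[code] = similarity.build_topk_graph(similarity.similarity_for(m),
                                                   k=config.k)
    if "CLI" in config.omics_codes:
        processed["CLI"] = preprocess.one_hot_encode_clinical(clinical)
        graphs["CLI"] = similarity.build_topk_graph(
            similarity.gower_similarity(clinical), k=config.k)
    codes = [c for c in fusion.CANONICAL_ORDER if c in processed]
    node_features = np.concatenate([processed[c].values for c in codes], axis=1)
    return processed, clinical, labels, survival_table, node_features, graphs


def train_embeddings(node_features, graphs, labels, train_idx, val_idx,
                     config: PipelineConfig, seed: int) -> dict[str, EmbeddingMatrix]:
    """One GAT per omics graph, all on the shared node feature matrix."""
    out = {}
    for code, graph in graphs.items():
        _, emb = train_gat(node_features, graph, labels, train_idx, val_idx,
                           sample_ids=labels.sample_ids, omics_code=code,
                           random_state=seed,
                           hidden_dim=config.gat_hidden_dim,
                           learning_rate=config.gat_learning_rate,
                           epochs=config.gat_epochs, heads=config.gat_heads)
        out[code] = emb
    return out


def sweep_with_training(node_features, graphs, labels, config: PipelineConfig,
                        subsets=None, runs: int | None = None):
    """Combination sweep with per-run GAT retraining on fresh splits."""
    runs = config.n_runs if runs is None else runs
    subsets = subsets if subsets is not None else \
        fusion.enumerate_omics_subsets(graphs)
    rows = []
    embeddings_first_run = None
    for run in range(runs):
        seed = config.seed + run
        train, val, test = fusion.stratified_split(labels, config.split_fractions,
                                                   seed=seed)
        embeddings = train_embeddings(node_features, graphs, labels, train, val,
                                      config, seed)
        if embeddings_first_run is None:
            embeddings_first_run = embeddings
        y = np.asarray(labels.labels)
        for combo in subsets:
            fused = fusion.concatenate_embeddings(embeddings, subset=combo)
            clf = fusion.train_mlp(fused, y, train, val, seed=seed,
                                   hidden_layers=config.mlp_hidden_layers,
                                   learning_rate=config.mlp_learning_rate,
                                   epochs=config.mlp_epochs)
            rep = fusion.evaluate_metrics(clf.predict(fused.values[test]), y[test])
            rows.append({"combination": "+".join(combo), "run": run,
                         "accuracy": rep.accuracy,
                         "weighted_f1": rep.weighted_f1,
                         "macro_f1": rep.macro_f1})
        logger.info("pipeline: run %d/%d complete", run + 1, runs)
    return pd.DataFrame(rows), embeddings_first_run


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 spec: SyntheticSpec | None = None, subsets=None,
                 with_survival: bool = True) -> dict:
    """Execute the full framework and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    processed, clinical, labels, survival_table, node_features, graphs = \
        prepare_cohort(config, spec)

    (outdir / "graphs").mkdir(exist_ok=True)
    for code, g in graphs.items():
        similarity.write_edge_list(g, outdir / "graphs" / f"{code}_edges.tsv")
    write_labels(labels, outdir / "labels.tsv")
    write_survival(survival_table, outdir / "survival.tsv")

    sweep, embeddings = sweep_with_training(node_features, graphs, labels,
                                            config, subsets=subsets)
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    fusion.summarize_sweep(sweep).to_csv(outdir / "sweep_summary.tsv",
                                         sep="\t", index=False)
    fusion.ablation_view(sweep, graphs).to_csv(outdir / "ablation.tsv",
                                               sep="\t", index=False)
    (outdir / "embeddings").mkdir(exist_ok=True)
    for code, emb in embeddings.items():
        write_matrix(pd.DataFrame(emb.values, index=emb.sample_ids,
                                  columns=[f"e{j}" for j in range(emb.values.shape[1])]),
                     outdir / "embeddings" / f"{code}.tsv")

    result = {"sweep": sweep, "outdir": str(outdir)}
    if with_survival:
        fused = fusion.concatenate_embeddings(embeddings)
        codes = [c for c in fusion.CANONICAL_ORDER if c in processed]
        raw = np.concatenate([processed[c].values for c in codes], axis=1)
        comparison = surv.compare_feature_sets(raw, fused.values, survival_table,
                                               alpha_grid=config.lasso_alpha_grid,
                                               seed=config.seed)
        summary = {side: {k: v for k, v in res.items()
                          if k not in ("risk", "km_low", "km_high")}
                   for side, res in comparison.items()}
        (outdir / "survival_summary.json").write_text(json.dumps(summary, indent=2))
        for side, res in comparison.items():
            if res["risk"] is not None:
                res["risk"].to_frame().to_csv(outdir / f"risk_{side}.tsv", sep="\t",
                                              index_label="sample_id")
        result["survival"] = comparison
    else:
        logger.warning("pipeline: survival table absent — survival stage skipped")

    manifest = {"config": config.to_dict(),
                "synthetic_spec": None if spec is None else
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items() if not k.startswith("_")},
                "n_samples": len(labels.sample_ids),
                "omics": sorted(graphs),
                "edge_counts": {c: len(g.edges) for c, g in graphs.items()}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
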
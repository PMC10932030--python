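"""Embedding fusion, MLP subtype classification, metrics and the
combination sweep / leave-one-omics-out ablation."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .gat import EmbeddingMatrix
from .io import OMICS_CODES, OmicsValidationError, logger

#: Canonical block order for concatenation (alphabetical omics codes).
CANONICAL_ORDER = OMICS_CODES


def stratified_split(labels, fractions=(0.7, 0.1, 0.2), seed: int = 0):
    """Stratified train/validation/test indices.

    Classes too small to stratify the val/test subdivision (fewer than two
    members remaining) fall back to a random subdivision there; the first
    (train vs rest) split stays stratified so every class reaches training.
    """
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    idx = np.arange(len(y))
    f_train, f_val, f_test = fractions
    train, rest = train_test_split(idx, test_size=f_val + f_test,
                                   stratify=y, random_state=seed)
    try:
        val, test = train_test_split(rest, test_size=f_test / (f_val + f_test),
                                     stratify=y[rest], random_state=seed)
    except ValueError:
        val, test = train_test_split(rest, test_size=f_test / (f_val + f_test),
                                     random_state=seed)
    return np.sort(train), np.sort(val), np.sort(test)


@dataclass
class FusedEmbedding:
    """Column-wise concatenation of per-omics embedding blocks."""

    values: np.ndarray
    sample_ids: list[str]
    blocks: list[tuple[str, int]]          # (omics code, width) in canonical order

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(code for code, _ in self.blocks)


def concatenate_embeddings(embeddings: dict[str, EmbeddingMatrix] | list[EmbeddingMatrix],
                           subset=None) -> FusedEmbedding:
    """Fuse the selected omics blocks in canonical code order.

    Input list/dict order is irrelevant; blocks are always reordered
    canonically so fused layouts are comparable across calls.
    """
    if not isinstance(embeddings, dict):
        embeddings = {e.omics_code: e for e in embeddings}
    if None in embeddings:
        raise OmicsValidationError("every embedding must carry an omics_code")
    codes = [c for c in CANONICAL_ORDER
             if c in embeddings and (subset is None or c in subset)]
    if subset is not None:
        unknown = set(subset) - set(embeddings)
        if unknown:
            raise OmicsValidationError(f"no embedding for requested codes {sorted(unknown)}")
    if not codes:
        raise OmicsValidationError("no omics blocks to concatenate")
    ref_ids = embeddings[codes[0]].sample_ids
    for c in codes[1:]:
        if embeddings[c].sample_ids != ref_ids:
            raise OmicsValidationError(
                f"sample mismatch between {codes[0]} and {c} embeddings")
    values = np.concatenate([embeddings[c].values for c in codes], axis=1)
    blocks = [(c, embeddings[c].values.shape[1]) for c in codes]
    return FusedEmbedding(values, list(ref_ids), blocks)


@dataclass
class MetricsReport:
    accuracy: float
    weighted_f1: float
    macro_f1: float


def evaluate_metrics(predictions, labels) -> MetricsReport:
    """Accuracy plus macro/weighted F1; classes absent from both truth and
    prediction are excluded, a class never predicted and never true gets F1=0."""
    pred = np.asarray(predictions)
    truth = np.asarray(labels)
    if len(pred) != len(truth):
        raise OmicsValidationError("predictions and labels differ in length")
    observed = sorted(set(truth) | set(pred))
    return MetricsReport(
        accuracy=float(accuracy_score(truth, pred)),
        weighted_f1=float(f1_score(truth, pred, labels=observed,
                                   average="weighted", zero_division=0)),
        macro_f1=float(f1_score(truth, pred, labels=observed,
                                average="macro", zero_division=0)),
    )


def _mlp(hidden_layers=(64, 32), learning_rate=0.001, epochs=1000, seed=0):
    return MLPClassifier(hidden_layer_sizes=tuple(hidden_layers),
                         learning_rate_init=learning_rate, max_iter=epochs,
                         random_state=seed)


def train_mlp(fused: FusedEmbedding, labels, train_idx, val_idx,
              grid: dict | None = None, n_candidates: int = 20,
              seed: int = 0, **config):
    """Fit the fusion MLP; with ``grid`` given, a randomized search over
    ``n_candidates`` sampled configurations keeps the best validation
    macro-F1.  Default configuration: layers (64, 32), lr 0.001, 1000 epochs.
    """
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    if len(set(y[train_idx])) < 2:
        raise OmicsValidationError("training split contains a single class")
    X = fused.values
    rng = np.random.default_rng(seed)
    if grid:
        keys = sorted(grid)
        all_cands = [dict(zip(keys, v))
                     for v in itertools.product(*(grid[k] for k in keys))]
        pick = rng.choice(len(all_cands), size=min(n_candidates, len(all_cands)),
                          replace=False)
        candidates = [all_cands[i] for i in pick]
    else:
        candidates = [{}]
    best, best_score = None, -np.inf
    for cand in candidates:
        params = {"hidden_layers": (64, 32), "learning_rate": 0.001,
                  "epochs": 1000, "seed": seed, **config, **cand}
        clf = _mlp(**params)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # convergence warnings at small epoch budgets
            clf.fit(X[train_idx], y[train_idx])
        score = f1_score(y[val_idx], clf.predict(X[val_idx]),
                         average="macro", zero_division=0)
        if score > best_score:
            best, best_score = clf, score
    return best


def enumerate_omics_subsets(codes) -> list[tuple[str, ...]]:
    """All 2^T − 1 non-empty omics combinations, canonical order."""
    codes = [c for c in CANONICAL_ORDER if c in set(codes)]
    if not codes:
        raise OmicsValidationError("at least one omics code required")
    out = []
    for r in range(1, len(codes) + 1):
        out.extend(itertools.combinations(codes, r))
    return out


def run_combination_sweep(embeddings: dict[str, EmbeddingMatrix], labels,
                          runs: int = 10, fractions=(0.7, 0.1, 0.2),
                          seed: int = 0, subsets=None,
                          mlp_grid: dict | None = None) -> pd.DataFrame:
    """Evaluate every non-empty omics combination over repeated runs.

    Each run draws a fresh stratified split; the MLP is trained on the fused
    blocks of that combination and scored on the test nodes.  Returns one row
    per (combination, run) with accuracy / weighted-F1 / macro-F1.
    """
    if not embeddings:
        raise OmicsValidationError("no embeddings supplied")
    y = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    subsets = subsets if subsets is not None else enumerate_omics_subsets(embeddings)
    rows = []
    for run in range(runs):
        train, val, test = stratified_split(y, fractions, seed=seed + run)
        for combo in subsets:
            fused = concatenate_embeddings(embeddings, subset=combo)
            clf = train_mlp(fused, y, train, val, grid=mlp_grid, seed=seed + run)
            rep = evaluate_metrics(clf.predict(fused.values[test]), y[test])
            rows.append({"combination": "+".join(combo), "run": run,
                         "accuracy": rep.accuracy, "weighted_f1": rep.weighted_f1,
                         "macro_f1": rep.macro_f1})
        logger.info("sweep: run %d/%d done (%d combinations)",
                    run + 1, runs, len(subsets))
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per combination over runs."""
    g = sweep.groupby("combination")[["accuracy", "weighted_f1", "macro_f1"]]
    out = g.agg(["mean", "std"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def ablation_view(sweep: pd.DataFrame, codes) -> pd.DataFrame:
    """Leave-one-omics-out table: 'All except X' rows plus 'All Datatypes'."""
    codes = [c for c in CANONICAL_ORDER if c in set(codes)]
    summary = summarize_sweep(sweep).set_index("combination")
    rows = []
    for left_out in codes:
        combo = "+".join(c for c in codes if c != left_out)
        if combo in summary.index:
            rows.append({"row": f"All except {left_out}",
                         **summary.loc[combo].to_dict()})
    full = "+".join(codes)
    if full in summary.index:
        rows.append({"row": "All Datatypes", **summary.loc[full].to_dict()})
    return pd.DataFrame(rows)
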
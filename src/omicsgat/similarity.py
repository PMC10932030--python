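"""Patient similarity matrices and top-k similarity graphs.

Metric dispatch follows the data type: Pearson correlation for continuous
layers, Jaccard for binary mutation profiles, Gower for mixed clinical
tables.  The graph links every patient to its k most similar peers (k=3 by
default); the directed top-k lists are symmetrized by union into an
undirected graph, so node degree is >= k and the edge count lies in
[ceil(n*k/2), n*k].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ClinicalTable, OmicsMatrix, OmicsValidationError, logger


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    metric: str                 # pearson | jaccard | gower
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise OmicsValidationError("similarity matrix must be n x n")


@dataclass
class PatientGraph:
    """Undirected patient similarity network (no self-edges)."""

    node_ids: list[str]
    edges: list[tuple[str, str]]            # each sorted (a < b), unique
    weights: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.node_ids)
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise OmicsValidationError(f"self-edge on {a!r}")
            if a > b:
                raise OmicsValidationError("edges must be stored sorted (a < b)")
            if a not in node_set or b not in node_set:
                raise OmicsValidationError(f"edge ({a!r}, {b!r}) references unknown node")
            if (a, b) in seen:
                raise OmicsValidationError(f"duplicate edge ({a!r}, {b!r})")
            seen.add((a, b))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def neighbors(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {v: [] for v in self.node_ids}
        for a, b in self.edges:
            out[a].append(b)
            out[b].append(a)
        return {v: sorted(ns) for v, ns in out.items()}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for a, b in self.edges:
            w = self.weights.get((a, b)) if self.weights else None
            g.add_edge(a, b, **({"weight": w} if w is not None else {}))
        return g

    def edge_index(self) -> np.ndarray:
        """Directed edge list with self-loops, as integer index pairs (i, j)
        meaning "neighbor j contributes to node i"; grouped by i, j ascending."""
        pos = {v: i for i, v in enumerate(self.node_ids)}
        nbrs = self.neighbors()
        pairs = []
        for v in self.node_ids:
            js = sorted({v, *nbrs[v]})
            pairs.extend((pos[v], pos[j]) for j in js)
        return np.asarray(pairs, dtype=int)


def pearson_similarity(matrix: OmicsMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation between sample feature vectors."""
    if matrix.n_features < 2:
        raise OmicsValidationError("Pearson similarity needs >= 2 features")
    x = matrix.values
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("similarity: %d zero-variance sample row(s); their "
                       "correlations are set to 0", int(degenerate.sum()))
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (xc @ xc.T) / denom
    s[degenerate, :] = 0.0
    s[:, degenerate] = 0.0
    np.fill_diagonal(s, np.where(degenerate, 0.0, 1.0))
    s = np.clip((s + s.T) / 2.0, -1.0, 1.0)    # enforce exact symmetry
    return SimilarityMatrix(s, "pearson", list(matrix.sample_ids))


def jaccard_similarity(matrix: OmicsMatrix) -> SimilarityMatrix:
    """|intersection| / |union| of mutated-gene sets; all-zero pairs -> 0."""
    x = matrix.values
    if not np.isin(x, (0.0, 1.0)).all():
        raise OmicsValidationError("Jaccard similarity requires a binary matrix")
    inter = x @ x.T
    ones = x.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    if (ones == 0).any():
        logger.warning("similarity: %d all-zero mutation profile(s); their "
                       "Jaccard similarity is 0 by convention", int((ones == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(union > 0, inter / np.where(union == 0, 1.0, union), 0.0)
    np.fill_diagonal(s, np.where(ones > 0, 1.0, 0.0))
    return SimilarityMatrix((s + s.T) / 2.0, "jaccard", list(matrix.sample_ids))


def gower_similarity(table: ClinicalTable) -> SimilarityMatrix:
    """Gower similarity on the raw mixed clinical table.

    Per attribute: ``1 - |x_i - x_j| / range`` (continuous) or exact-match
    (categorical); per pair, the average over attributes observed in both
    records.  Zero-range continuous attributes are excluded pairwise.
    """
    n = len(table.sample_ids)
    score = np.zeros((n, n))
    count = np.zeros((n, n))
    for col in table.frame.columns:
        series = table.frame[col]
        if table.kinds[col] == "continuous":
            x = series.astype(float).to_numpy()
            valid = ~np.isnan(x)
            rng = (np.nanmax(x) - np.nanmin(x)) if valid.any() else 0.0
            if rng == 0:
                logger.warning("similarity: zero-range attribute %r excluded "
                               "from Gower", col)
                continue
            d = 1.0 - np.abs(x[:, None] - x[None, :]) / rng
        else:
            vals = series.astype(object).to_numpy()
            valid = ~series.isna().to_numpy()
            d = (vals[:, None] == vals[None, :]).astype(float)
        both = np.outer(valid, valid)
        score += np.where(both, np.nan_to_num(d), 0.0)
        count += both
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(count > 0, score / np.where(count == 0, 1.0, count), 0.0)
    if (count == 0).any():
        logger.warning("similarity: some record pairs share no observed "
                       "attribute; their Gower similarity is 0")
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix((s + s.T) / 2.0, "gower", list(table.sample_ids))


def similarity_for(matrix: OmicsMatrix | ClinicalTable) -> SimilarityMatrix:
    """Metric dispatch by data type."""
    if isinstance(matrix, ClinicalTable):
        return gower_similarity(matrix)
    if matrix.omics_code == "MUT":
        return jaccard_similarity(matrix)
    return pearson_similarity(matrix)


def build_topk_graph(sim: SimilarityMatrix, k: int = 3) -> PatientGraph:
    """Link each node to its k most similar others (union symmetrization).

    Ties are broken by ascending sample ID for reproducibility.
    """
    if k <= 0:
        raise OmicsValidationError("k must be positive")
    n = len(sim.sample_ids)
    if k >= n:
        raise OmicsValidationError(f"k={k} must be smaller than n={n}")
    ids = sim.sample_ids
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    for i, v in enumerate(ids):
        others = [(j, ids[j]) for j in range(n) if j != i]
        others.sort(key=lambda t: (-sim.values[i, t[0]], t[1]))
        for j, u in others[:k]:
            e = (v, u) if v < u else (u, v)
            edges.add(e)
            weights[e] = float(sim.values[i, j])
    return PatientGraph(list(ids), sorted(edges), weights)


def write_edge_list(graph: PatientGraph, path, with_weights: bool = True) -> None:
    import pandas as pd

    rows = [(a, b, graph.weights.get((a, b)) if graph.weights else None)
            for a, b in graph.edges]
    df = pd.DataFrame(rows, columns=["sample_id_a", "sample_id_b", "weight"])
    if not with_weights or graph.weights is None:
        df = df.drop(columns="weight")
    df.to_csv(path, sep="\t", index=False)
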
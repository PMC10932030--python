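"""Cleaning rules: expression filtering, duplicate merging, clinical one-hot
encoding, common-sample intersection, feature selection and normalization.

Expression filters operate on the raw (FPKM/RPM-like) scale and keep a
feature only if its value reaches the threshold in at least the required
fraction of samples (defaults: 1.0 in >=15% of samples for mRNA/lncRNA, 1.0
in >=30% for miRNA).  Feature selection is a label-aware univariate ranking
(one-way ANOVA F across subtypes) behind a pluggable scorer interface; the
default number of kept features per modality mirrors the dimensionality
profile of a real cohort.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .io import (CONTINUOUS_CODES, ClinicalTable, LabelVector, OmicsMatrix,
                 OmicsValidationError, SurvivalTable, logger)

#: (threshold, min_fraction) defaults for the low-expression filter.
FILTER_DEFAULTS = {"EXP": (1.0, 0.15), "LNC": (1.0, 0.15), "MIR": (1.0, 0.30)}

#: Default kept-feature counts for the selection stage (None = keep all).
SELECT_DEFAULTS = {"EXP": 1000, "LNC": 500, "MET": 1000, "CNA": 500, "MUT": 200,
                   "MIR": None, "COE": None, "CLI": None}


def filter_low_expression(matrix: OmicsMatrix, threshold: float | None = None,
                          min_fraction: float | None = None) -> OmicsMatrix:
    """Drop features whose value is below ``threshold`` in too many samples."""
    if threshold is None or min_fraction is None:
        t, f = FILTER_DEFAULTS.get(matrix.omics_code, (1.0, 0.15))
        threshold = t if threshold is None else threshold
        min_fraction = f if min_fraction is None else min_fraction
    if (matrix.values < 0).any():
        raise OmicsValidationError(
            "low-expression filter expects a raw nonnegative-scale matrix")
    frac = (matrix.values >= threshold).mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        logger.warning("preprocess: low-expression filter removed every feature "
                       "of %s", matrix.omics_code)
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return OmicsMatrix(matrix.values[:, keep], matrix.sample_ids, kept_ids,
                       matrix.omics_code)


def merge_duplicate_samples(matrix: OmicsMatrix,
                            patient_of: Mapping[str, str]) -> OmicsMatrix:
    """Collapse multiple samples per patient: mean for continuous, OR for MUT.

    Output rows are ordered by first appearance of each patient.
    """
    if matrix.omics_code == "CLI":
        raise OmicsValidationError(
            "clinical duplicates must be resolved upstream (first record wins)")
    missing = [s for s in matrix.sample_ids if s not in patient_of]
    if missing:
        raise OmicsValidationError(f"patient_of missing sample IDs: {missing[:5]}")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(matrix.sample_ids):
        p = str(patient_of[s])
        if p not in groups:
            groups[p] = []
            order.append(p)
        groups[p].append(i)
    rows = []
    for p in order:
        block = matrix.values[groups[p]]
        rows.append(block.max(axis=0) if matrix.omics_code == "MUT"
                    else block.mean(axis=0))
    return OmicsMatrix(np.vstack(rows), order, list(matrix.feature_ids),
                       matrix.omics_code)


def one_hot_encode_clinical(table: ClinicalTable) -> OmicsMatrix:
    """Expand categoricals to indicators (NaN gets its own indicator column);
    continuous attributes pass through unscaled."""
    blocks: list[pd.DataFrame] = []
    for col in table.frame.columns:
        series = table.frame[col]
        if table.kinds[col] == "continuous":
            blocks.append(series.astype(float).to_frame(col))
            continue
        if series.isna().all():
            logger.warning("preprocess: dropping all-missing clinical attribute %r", col)
            continue
        vals = series.astype(object).where(~series.isna(), "missing").astype(str)
        dummies = pd.get_dummies(vals, prefix=col, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        blocks.append(dummies)
    if not blocks:
        raise OmicsValidationError("clinical table encoded to zero columns")
    frame = pd.concat(blocks, axis=1)
    return OmicsMatrix.from_frame(frame, "CLI")


def intersect_common_samples(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector | None = None,
    survival: SurvivalTable | None = None,
    clinical: ClinicalTable | None = None,
):
    """Restrict every input to the samples present in all of them.

    Returns ``(matrices, labels, survival, clinical)`` with the optional
    entries ``None`` when not supplied; all outputs share one sorted sample
    order.
    """
    if not matrices:
        raise OmicsValidationError("at least one matrix required")
    common: set[str] = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if labels is not None:
        common &= set(labels.sample_ids)
    if survival is not None:
        common &= set(survival.sample_ids)
    if clinical is not None:
        common &= set(clinical.sample_ids)
    if not common:
        raise OmicsValidationError("no samples are common to all inputs")
    ordered = sorted(common)
    out_m = [m.subset_samples(ordered) for m in matrices]
    out_l = labels.subset_samples(ordered) if labels is not None else None
    out_s = survival.subset_samples(ordered) if survival is not None else None
    out_c = clinical.subset_samples(ordered) if clinical is not None else None
    return out_m, out_l, out_s, out_c


def anova_f_scores(values: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """One-way ANOVA F per feature across label groups (default scorer)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield F = 0/0
        f, _ = f_classif(values, np.asarray(labels))
    return np.nan_to_num(f, nan=0.0, posinf=np.finfo(float).max)


def select_features(matrix: OmicsMatrix, labels: LabelVector,
                    n_keep: int | None = None,
                    scorer: Callable[[np.ndarray, Sequence[str]], np.ndarray]
                    = anova_f_scores) -> OmicsMatrix:
    """Keep the ``n_keep`` highest-scoring features (ties: feature_id asc).

    ``scorer`` maps ``(values, labels) -> score per feature``; any ranking
    function with that signature can replace the ANOVA-F default.
    """
    if n_keep is None:
        n_keep = SELECT_DEFAULTS.get(matrix.omics_code)
    if n_keep is None or n_keep >= matrix.n_features:
        if n_keep is not None and n_keep > matrix.n_features:
            logger.warning("preprocess: n_keep=%d exceeds %d features; keeping all",
                           n_keep, matrix.n_features)
        return matrix
    if n_keep < 1:
        raise OmicsValidationError("n_keep must be >= 1")
    lab = labels.to_series().loc[matrix.sample_ids]
    scores = scorer(matrix.values, list(lab.values))
    order = sorted(range(matrix.n_features),
                   key=lambda j: (-scores[j], matrix.feature_ids[j]))
    keep = sorted(order[:n_keep])   # preserve original column order
    return OmicsMatrix(matrix.values[:, keep], matrix.sample_ids,
                       [matrix.feature_ids[j] for j in keep], matrix.omics_code)


# backwards-compatible alias used in pipeline configs
select_features_standin = select_features


def zscore_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Per-feature z-score (population SD); constant columns map to zeros."""
    if matrix.omics_code not in CONTINUOUS_CODES:
        raise OmicsValidationError(
            f"{matrix.omics_code} features do not require normalization "
            f"(z-score applies to {CONTINUOUS_CODES})")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning("preprocess: %d zero-variance feature(s) set to 0 during "
                       "z-scoring", int(zero.sum()))
    sd_safe = np.where(zero, 1.0, sd)
    out = (matrix.values - mean) / sd_safe
    out[:, zero] = 0.0
    return OmicsMatrix(out, matrix.sample_ids, list(matrix.feature_ids),
                       matrix.omics_code)
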
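"""Core data types, TSV readers/writers, configuration and logging.

All matrices travel as :class:`OmicsMatrix`: a sample × feature value matrix
with string IDs and an omics code identifying the modality.  Files are
tab-separated UTF-8 text with '.' decimals; the first column is ``sample_id``
and the header row carries feature IDs.  Sample alignment everywhere in the
package is by ID string, never by row position.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("omicsgat")
if not logger.handlers:  # stage-tagged lines to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[omicsgat:%(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: The eight supported omics codes, in canonical (alphabetical) order.
OMICS_CODES = ("CLI", "CNA", "COE", "EXP", "LNC", "MET", "MIR", "MUT")

#: Continuous modalities that are z-score normalized before modelling.
CONTINUOUS_CODES = ("CNA", "EXP", "LNC", "MET", "MIR")


class OmicsValidationError(ValueError):
    """Raised when a matrix or table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique().tolist())
        raise OmicsValidationError(
            f"duplicate {what}: {dups[:5]}"
            + (" — merge with preprocess.merge_duplicate_samples first"
               if what == "sample IDs" else "")
        )


@dataclass
class OmicsMatrix:
    """One omics layer: an ``n_samples × m_features`` real matrix with IDs.

    MUT matrices must be binary {0,1}; continuous modalities must be finite
    (missing values are only tolerated in CLI tables before encoding).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_code: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.omics_code not in OMICS_CODES:
            raise OmicsValidationError(
                f"unknown omics code {self.omics_code!r}; valid codes: {OMICS_CODES}"
            )
        if self.values.ndim != 2:
            raise OmicsValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != m:
            raise OmicsValidationError(
                f"ID lengths ({len(self.sample_ids)}, {len(self.feature_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.sample_ids, "sample IDs")
        _check_unique(self.feature_ids, "feature IDs")
        if self.omics_code == "MUT":
            vals = self.values
            if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0)).all() or np.isnan(vals).any():
                raise OmicsValidationError("MUT matrix must contain only 0/1 values")
        elif self.omics_code != "CLI" and np.isnan(self.values).any():
            raise OmicsValidationError(
                f"{self.omics_code} matrix contains missing values; "
                "only CLI tables may carry missing entries"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omics_code: str) -> "OmicsMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index.astype(str)),
                   list(frame.columns.astype(str)), omics_code)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Row-subset (and reorder) by sample ID."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(self.values[idx], list(sample_ids), list(self.feature_ids),
                           self.omics_code)


@dataclass
class LabelVector:
    """Categorical subtype label per sample."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise OmicsValidationError("one label per sample required")
        _check_unique(self.sample_ids, "sample IDs")
        if len(set(self.labels)) < 2:
            raise OmicsValidationError("label set must contain at least 2 classes")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="subtype")

    def subset_samples(self, sample_ids: Sequence[str]) -> "LabelVector":
        s = self.to_series().loc[list(sample_ids)]
        return LabelVector(list(s.index), list(s.values))


@dataclass
class ClinicalTable:
    """Per-sample clinical attributes, each declared continuous or categorical.

    Missing values are explicit NaN; downstream encoders and the Gower metric
    handle them, other stages reject them.
    """

    frame: pd.DataFrame          # index = sample IDs
    kinds: dict[str, str]        # attribute -> "continuous" | "categorical"

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = self.frame.index.astype(str)
        _check_unique(list(self.frame.index), "sample IDs")
        for col in self.frame.columns:
            kind = self.kinds.get(col)
            if kind not in ("continuous", "categorical"):
                raise OmicsValidationError(
                    f"attribute {col!r} must be declared continuous or categorical"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)], dict(self.kinds))


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: positive time and a 0/1 event flag."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise OmicsValidationError("survival columns must align with sample IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if (self.time <= 0).any():
            raise OmicsValidationError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise OmicsValidationError("event indicator must be 0 (censored) or 1 (death)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event},
                            index=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        df = self.to_frame().loc[list(sample_ids)]
        return SurvivalTable(list(df.index), df["time"].to_numpy(),
                             df["event"].to_numpy())


# ---------------------------------------------------------------------------
# configuration

#: Grid-search ranges for the GAT, MLP and LASSO stages.
DEFAULT_GRIDS = {
    "gat_hidden_dim": [128, 256, 512, 1024],
    "gat_learning_rate": [0.01, 0.001, 0.0001],
    "gat_epochs": [100, 200, 500],
    "gat_heads": [1, 2, 4, 8],
    "mlp_learning_rate": [0.1, 0.01, 0.001, 0.0001, 0.00001],
    "mlp_hidden_layers": [[32], [64], [128], [256], [512],
                          [32, 32], [64, 32], [128, 32], [256, 32]],
    "mlp_epochs": [200, 500, 1000, 1500],
    "lasso_alpha": [0.001, 0.002, 0.005, 0.01, 0.05, 1.0],
}


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the tuned values of the grids above."""

    omics_codes: list[str] = field(default_factory=lambda: list(OMICS_CODES))
    k: int = 3                               # neighbors per node in the similarity graph
    gat_hidden_dim: int = 512
    gat_learning_rate: float = 0.001
    gat_epochs: int = 200
    gat_heads: int = 1
    leaky_slope: float = 0.2
    mlp_hidden_layers: tuple[int, ...] = (64, 32)
    mlp_learning_rate: float = 0.001
    mlp_epochs: int = 1000
    lasso_alpha_grid: list[float] = field(
        default_factory=lambda: list(DEFAULT_GRIDS["lasso_alpha"]))
    n_runs: int = 10
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    grids: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRIDS.items()})

    def __post_init__(self) -> None:
        for code in self.omics_codes:
            if code not in OMICS_CODES:
                raise OmicsValidationError(
                    f"unknown omics code {code!r}; valid codes: {OMICS_CODES}")
        if self.k < 1:
            raise OmicsValidationError("similarity k must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise OmicsValidationError("split fractions must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mlp_hidden_layers"] = list(self.mlp_hidden_layers)
        d["split_fractions"] = list(self.split_fractions)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config; absent fields fall back to tuned defaults."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise OmicsValidationError(f"unknown config fields: {sorted(unknown)}")
    if "mlp_hidden_layers" in data:
        data["mlp_hidden_layers"] = tuple(data["mlp_hidden_layers"])
    if "split_fractions" in data:
        data["split_fractions"] = tuple(data["split_fractions"])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# TSV matrix I/O

def read_feature_matrix(path: str | Path, omics_code: str) -> OmicsMatrix:
    """Read a TSV matrix (first column ``sample_id``, header = feature IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=["", "NA"])
    _check_unique(list(df.index.astype(str)), "sample IDs")
    try:
        values = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise OmicsValidationError(
                        f"non-numeric cell {cell!r} at row {df.index[i]!r}, "
                        f"column {col!r} in {path}"
                    ) from None
        raise
    return OmicsMatrix.from_frame(values, omics_code)


def write_matrix(matrix: OmicsMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV readable by :func:`read_feature_matrix`."""
    frame = matrix.to_frame() if isinstance(matrix, OmicsMatrix) else matrix
    if frame.size == 0:
        raise OmicsValidationError("refusing to write an empty matrix")
    frame.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LabelVector(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "subtype": labels.labels}
                 ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalTable(list(df.index.astype(str)), df["time"].to_numpy(),
                         df["event"].to_numpy())


def write_survival(survival: SurvivalTable, path: str | Path) -> None:
    survival.to_frame().to_csv(path, sep="\t", index_label="sample_id")
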
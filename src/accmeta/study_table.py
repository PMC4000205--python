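"""Clustered study-factor table: loading, validation, derived counts, design encoding.

The analysis table has one row per published classification model, rows
clustered by the study that reported them.  Each row carries the model's
reported accuracy, the number of samples that accuracy was computed over,
and eight study factors (disease category, medical question, microarray
colour system, training-set size, cross-validation technique, gene-selection
class, classifier class, number of genes in the final model) plus the
class-imbalance level of the training set, which acts as a forced
correction covariate in every model.

Accuracy is converted to a grouped-binomial outcome (n_correct, n_incorrect)
so a binomial likelihood applies row-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "FactorSet",
    "DesignMatrix",
    "SchemaError",
    "ValidationError",
    "DegenerateDesignError",
    "STUDY_FACTORS",
    "CATEGORICAL_LEVELS",
    "NUMERIC_FACTORS",
    "load_study_table",
    "write_study_table",
    "records_to_frame",
    "frame_to_records",
    "derive_counts",
    "compute_imbalance",
    "encode_design",
    "default_reference_levels",
]


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ValidationError(ValueError):
    """A row violates the controlled vocabulary or a numeric bound."""


class DegenerateDesignError(ValueError):
    """Design matrix would be rank deficient (e.g. single-level factor)."""


#: Controlled vocabularies for the categorical study factors.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "disease_category": (
        "inflammatory disorder",
        "immune disease",
        "degenerative disease",
        "infection",
        "mental disorder",
        "other",
    ),
    "medical_question": ("diagnostic", "prognostic", "response-to-treatment"),
    "platform_color": ("one-color", "two-color"),
    "cv_technique": ("single", "nested"),
    "gene_selection": ("filter", "wrapper", "embedded"),
    "classifier_class": ("interaction", "non-interaction"),
}

#: Numeric study factors, passed into the design untransformed by default.
NUMERIC_FACTORS: tuple[str, ...] = ("n_train", "n_genes_final", "imbalance")

#: The eight study factors, in the order the univariable scan reports them.
STUDY_FACTORS: tuple[str, ...] = (
    "n_train",
    "platform_color",
    "medical_question",
    "disease_category",
    "cv_technique",
    "gene_selection",
    "classifier_class",
    "n_genes_final",
)

_REQUIRED_COLUMNS: tuple[str, ...] = (
    "study_id",
    "model_id",
    "disease_category",
    "medical_question",
    "platform_color",
    "n_train",
    "imbalance",
    "cv_technique",
    "gene_selection",
    "classifier_class",
    "n_genes_final",
    "accuracy",
    "n_eval",
)


@dataclass(frozen=True)
class StudyRecord:
    """One classification model's factors and grouped-binomial outcome."""

    study_id: str
    model_id: str
    disease_category: str
    medical_question: str
    platform_color: str
    n_train: int
    imbalance: float
    cv_technique: str
    gene_selection: str
    classifier_class: str
    n_genes_final: int
    accuracy: float
    n_eval: int
    n_correct: int
    n_incorrect: int

    def __post_init__(self) -> None:
        if self.n_eval <= 0:
            raise ValidationError(f"n_eval must be positive, got {self.n_eval}")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValidationError(f"accuracy outside [0, 1]: {self.accuracy}")
        if not 0.0 <= self.imbalance <= 1.0:
            raise ValidationError(f"imbalance outside [0, 1]: {self.imbalance}")
        if self.n_correct + self.n_incorrect != self.n_eval:
            raise ValidationError(
                f"n_correct + n_incorrect != n_eval "
                f"({self.n_correct} + {self.n_incorrect} != {self.n_eval})"
            )
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValidationError(
                    f"{name}={value!r} not in controlled vocabulary {levels}"
                )


@dataclass(frozen=True)
class FactorSet:
    """An ordered set of study factors plus the always-included covariate."""

    included_factors: tuple[str, ...]
    forced: str = "imbalance"

    def __post_init__(self) -> None:
        if len(set(self.included_factors)) != len(self.included_factors):
            raise ValueError("duplicate factors in FactorSet")
        unknown = set(self.included_factors) - set(STUDY_FACTORS)
        if unknown:
            raise ValueError(f"unknown study factors: {sorted(unknown)}")

    def without(self, factor: str) -> "FactorSet":
        if factor not in self.included_factors:
            raise ValueError(f"{factor!r} not in factor set")
        return FactorSet(
            tuple(f for f in self.included_factors if f != factor), self.forced
        )

    @classmethod
    def full(cls, forced: str = "imbalance") -> "FactorSet":
        return cls(STUDY_FACTORS, forced)

    @classmethod
    def empty(cls, forced: str = "imbalance") -> "FactorSet":
        return cls((), forced)


@dataclass
class DesignMatrix:
    """Reference-coded fixed-effect design with a cluster index per row."""

    X: np.ndarray
    columns: list[str]
    column_map: dict[str, list[int]]
    cluster_index: np.ndarray
    cluster_labels: list[str]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def drop_factor(self, factor: str) -> "DesignMatrix":
        """Design with one factor's columns removed (for deletion refits)."""
        drop = set(self.column_map[factor])
        keep = [j for j in range(self.X.shape[1]) if j not in drop]
        remap: dict[str, list[int]] = {}
        old_to_new = {j: i for i, j in enumerate(keep)}
        for name, cols in self.column_map.items():
            if name == factor:
                continue
            remap[name] = [old_to_new[j] for j in cols]
        return DesignMatrix(
            X=self.X[:, keep],
            columns=[self.columns[j] for j in keep],
            column_map=remap,
            cluster_index=self.cluster_index,
            cluster_labels=self.cluster_labels,
        )


def derive_counts(accuracy: float, n_eval: int) -> tuple[int, int]:
    """Convert a reported accuracy into integer (correct, incorrect) counts.

    The product accuracy * n_eval is rounded to the nearest integer with
    halves rounding up, so reported accuracies that are not exact multiples
    of 1/n_eval still yield a consistent grouped-binomial outcome.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValidationError(f"accuracy outside [0, 1]: {accuracy}")
    if n_eval < 1:
        raise ValidationError(f"n_eval must be >= 1, got {n_eval}")
    n_correct = int(math.floor(accuracy * n_eval + 0.5))
    return n_correct, n_eval - n_correct


def compute_imbalance(group_sizes: Sequence[int]) -> float:
    """Majority-class share: max(group sizes) / total."""
    if len(group_sizes) < 2:
        raise ValidationError("need at least two class groups")
    if any(g < 0 for g in group_sizes):
        raise ValidationError("negative group size")
    total = sum(group_sizes)
    if total <= 0:
        raise ValidationError("total sample size must be positive")
    return max(group_sizes) / total


def _coerce_row(row: pd.Series, index: int) -> StudyRecord:
    try:
        accuracy = float(row["accuracy"])
        n_eval = int(row["n_eval"])
        if "n_correct" in row and not pd.isna(row.get("n_correct")):
            n_correct = int(row["n_correct"])
            n_incorrect = int(row.get("n_incorrect", n_eval - n_correct))
        else:
            n_correct, n_incorrect = derive_counts(accuracy, n_eval)
        return StudyRecord(
            study_id=str(row["study_id"]),
            model_id=str(row["model_id"]),
            disease_category=str(row["disease_category"]),
            medical_question=str(row["medical_question"]),
            platform_color=str(row["platform_color"]),
            n_train=int(row["n_train"]),
            imbalance=float(row["imbalance"]),
            cv_technique=str(row["cv_technique"]),
            gene_selection=str(row["gene_selection"]),
            classifier_class=str(row["classifier_class"]),
            n_genes_final=int(row["n_genes_final"]),
            accuracy=accuracy,
            n_eval=n_eval,
            n_correct=n_correct,
            n_incorrect=n_incorrect,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {index}: {exc}") from exc


def load_study_table(path, dialect: str = ",") -> list[StudyRecord]:
    """Read a delimited study-factor table into validated records.

    Lines starting with ``#`` are treated as comments (run reports prepend a
    provenance header).  Missing n_correct/n_incorrect columns are derived
    from accuracy and n_eval.
    """
    df = pd.read_csv(path, sep=dialect, comment="#", float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return frame_to_records(df)


def load_study_table_xlsx(path, sheet: int | str = 0) -> list[StudyRecord]:
    """Read a spreadsheet version of the study table (first sheet by default).

    Convenience for supplements distributed as XLSX; the result is identical
    to converting the sheet to CSV and calling :func:`load_study_table`.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[StudyRecord]:
    # rows cited 1-based in error messages
    return [_coerce_row(row, i + 1) for i, (_, row) in enumerate(df.iterrows())]


def records_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(StudyRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def write_study_table(records: Sequence[StudyRecord], path, dialect: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=dialect, index=False)


def default_reference_levels(records: Sequence[StudyRecord]) -> dict[str, str]:
    """Most frequent observed level per categorical factor (ties: vocabulary order)."""
    refs: dict[str, str] = {}
    for factor, levels in CATEGORICAL_LEVELS.items():
        counts = {lv: 0 for lv in levels}
        for r in records:
            counts[getattr(r, factor)] += 1
        refs[factor] = max(levels, key=lambda lv: counts[lv])
    return refs


def encode_design(
    records: Sequence[StudyRecord],
    factors: FactorSet,
    reference_levels: Mapping[str, str] | None = None,
    log10_numeric: bool = False,
    include_forced: bool = True,
) -> DesignMatrix:
    """Build the reference-coded fixed-effect design matrix.

    Columns: intercept, the forced covariate, then per included factor either
    a single numeric column or (levels - 1) reference-coded dummies.  The
    reference level maps to the all-zero dummy pattern.  ``log10_numeric``
    applies log10 to n_train and n_genes_final for sensitivity analyses.
    """
    if not records:
        raise ValidationError("cannot encode an empty record list")
    refs = dict(reference_levels) if reference_levels is not None else (
        default_reference_levels(records)
    )

    cluster_labels: list[str] = []
    cluster_pos: dict[str, int] = {}
    for r in records:
        if r.study_id not in cluster_pos:
            cluster_pos[r.study_id] = len(cluster_labels)
            cluster_labels.append(r.study_id)
    cluster_index = np.array([cluster_pos[r.study_id] for r in records], dtype=np.intp)

    columns: list[str] = ["intercept"]
    col_data: list[np.ndarray] = [np.ones(len(records))]
    column_map: dict[str, list[int]] = {}

    def add_numeric(name: str) -> None:
        vals = np.array([float(getattr(r, name)) for r in records])
        if name in ("n_train", "n_genes_final") and log10_numeric:
            vals = np.log10(vals)
        if np.ptp(vals) == 0.0:
            raise DegenerateDesignError(f"factor {name!r} is constant")
        column_map[name] = [len(columns)]
        columns.append(name)
        col_data.append(vals)

    def add_categorical(name: str) -> None:
        observed = [getattr(r, name) for r in records]
        observed_levels = [lv for lv in CATEGORICAL_LEVELS[name] if lv in set(observed)]
        if len(observed_levels) < 2:
            raise DegenerateDesignError(f"factor {name!r} has a single observed level")
        ref = refs.get(name)
        if ref not in observed_levels:
            raise ValidationError(
                f"reference level {ref!r} for {name!r} not among observed levels"
            )
        idxs: list[int] = []
        for lv in observed_levels:
            if lv == ref:
                continue
            idxs.append(len(columns))
            columns.append(f"{name}[{lv}]")
            col_data.append(np.array([1.0 if v == lv else 0.0 for v in observed]))
        column_map[name] = idxs

    names = (factors.forced, *factors.included_factors) if include_forced else (
        factors.included_factors
    )
    for name in names:
        if name in NUMERIC_FACTORS:
            add_numeric(name)
        else:
            add_categorical(name)

    X = np.column_stack(col_data)
    return DesignMatrix(
        X=X,
        columns=columns,
        column_map=column_map,
        cluster_index=cluster_index,
        cluster_labels=cluster_labels,
    )


def outcomes_array(records: Sequence[StudyRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(n_correct, n_eval) arrays in record order."""
    y = np.array([r.n_correct for r in records], dtype=float)
    n = np.array([r.n_eval for r in records], dtype=float)
    return y, n
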
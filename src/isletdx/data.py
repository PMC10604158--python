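"""Data model, file I/O and the preprocessing chain.

An :class:`ExpressionMatrix` holds a genes x samples block of microarray
intensities together with its identifiers.  Preprocessing mirrors the
standard microarray regime for this kind of study: keep the genes with the
largest peak intensity, take log10, then standardize every sample column to
mean 0 / variance 1 (population variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LABEL_DIABETIC = "diabetic"
LABEL_NON_DIABETIC = "non_diabetic"
VALID_LABELS = (LABEL_DIABETIC, LABEL_NON_DIABETIC)


class ValidationError(ValueError):
    """Raised when inputs violate a structural contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with gene/sample identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains missing or non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))


@dataclass
class LabelVector:
    """Per-sample binary class aligned with an expression matrix's columns."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels differ in length")
        bad = [l for l in self.labels if l not in VALID_LABELS]
        if bad:
            raise ValidationError(f"unknown label string(s): {sorted(set(bad))!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in labels")

    def __len__(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def binary(self, positive: str = LABEL_DIABETIC) -> np.ndarray:
        """0/1 vector with the requested positive class mapped to 1."""
        return np.asarray([1 if l == positive else 0 for l in self.labels])

    def class_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in VALID_LABELS}
        for l in self.labels:
            out[l] += 1
        return out

    def reorder(self, sample_ids: Sequence[str]) -> "LabelVector":
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"no label for sample(s): {missing}")
        return LabelVector(list(sample_ids), [lookup[s] for s in sample_ids])

    def subset(self, idx: Sequence[int]) -> "LabelVector":
        return LabelVector([self.sample_ids[i] for i in idx],
                           [self.labels[i] for i in idx])


def _read_table(path, dialect: str) -> pd.DataFrame:
    if dialect not in ("csv", "tsv"):
        raise ValidationError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         header=0, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return df


def load_dataset(expr_path, label_path, dialect: str = "csv"
                 ) -> tuple[ExpressionMatrix, LabelVector]:
    """Read an expression matrix and its label file.

    The expression file has ``gene_id`` in the first column and one column
    per sample; the label file has two columns ``sample_id,label`` with
    label in {diabetic, non_diabetic}.  Labels are re-ordered to the matrix's
    column order, which defines sample order everywhere downstream.
    """
    df = _read_table(expr_path, dialect)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric entry in {expr_path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValidationError(f"{expr_path} has missing entries (ragged rows?)")
    x = ExpressionMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)

    ldf = _read_table(label_path, dialect)
    if ldf.shape[1] != 1:
        raise ValidationError("label file must have exactly two columns: sample_id,label")
    raw = {str(k): str(v) for k, v in ldf.iloc[:, 0].items()}
    extra = sorted(set(raw) - set(x.sample_ids))
    if extra:
        raise ValidationError(f"label file names unknown sample(s): {extra}")
    missing = [s for s in x.sample_ids if s not in raw]
    if missing:
        raise ValidationError(f"unlabeled sample(s): {missing}")
    y = LabelVector(list(x.sample_ids), [raw[s] for s in x.sample_ids])
    return x, y


def save_dataset(x: ExpressionMatrix, y: LabelVector, expr_path, label_path,
                 dialect: str = "csv") -> None:
    sep = "," if dialect == "csv" else "\t"
    x.to_frame().to_csv(expr_path, sep=sep)
    pd.DataFrame({"sample_id": y.sample_ids, "label": y.labels}).to_csv(
        label_path, sep=sep, index=False)


def preprocess(x: ExpressionMatrix, n_top_genes: int = 22_960,
               log_base: float = 10.0) -> ExpressionMatrix:
    """Peak-intensity gene filter, log transform, per-sample standardization.

    Keeps the ``n_top_genes`` genes with the largest maximum intensity
    across samples (a single shared gene set so the matrix stays
    rectangular), applies a base-``log_base`` logarithm, then standardizes
    every sample column to mean 0 and *population* variance 1.
    """
    if n_top_genes <= 0:
        raise ValidationError("n_top_genes must be positive")
    if np.any(x.values <= 0):
        raise ValidationError("intensities must be strictly positive before log")
    n_keep = min(n_top_genes, x.n_genes)
    peaks = x.values.max(axis=1)
    # stable sort keeps the original gene order among ties
    order = np.argsort(-peaks, kind="stable")[:n_keep]
    order.sort()
    vals = np.log(x.values[order]) / np.log(log_base)
    mean = vals.mean(axis=0)
    var = vals.var(axis=0)  # population variance (divisor n)
    if np.any(var <= 0):
        bad = [x.sample_ids[j] for j in np.flatnonzero(var <= 0)]
        raise ValidationError(f"zero-variance sample column(s), cannot standardize: {bad}")
    vals = (vals - mean) / np.sqrt(var)
    return ExpressionMatrix([x.gene_ids[i] for i in order], list(x.sample_ids), vals)
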
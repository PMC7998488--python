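"""Reading, cleaning, normalizing and class-balancing labeled expression tables.

The central container is :class:`LabeledExpressionMatrix`: a samples x genes
numeric matrix together with sample identifiers, gene identifiers and an
integer-coded class label per sample.  Tables are plain delimited text (CSV or
TSV) with one sample per row, a sample-ID column, gene columns and a label
column; this mirrors how cohort-level expression matrices are distributed
after transposition to sample-major order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BalanceError,
    ConfigError,
    EmptyFeatureError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "drop_zero_mean_genes",
    "normalize",
    "oversample_minority",
]


@dataclass
class LabeledExpressionMatrix:
    """Samples x genes expression matrix with per-sample class labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    gene_ids : list of str
        Unique gene identifiers, one per column of ``values``.
    values : ndarray of shape (n_samples, n_genes)
        Expression values in whatever units the source provides.
    labels : ndarray of int, shape (n_samples,)
        Class labels coded ``0..C-1``.
    label_map : dict
        Mapping from original label value to integer code.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    label_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x genes matrix")
        n, g = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"row mismatch: {n} rows, {len(self.sample_ids)} sample IDs, "
                f"{len(self.labels)} labels"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"column mismatch: {g} columns, {len(self.gene_ids)} gene IDs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene IDs")
        if not self.label_map:
            self.label_map = {int(c): int(c) for c in np.unique(self.labels)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def class_counts(self) -> dict[int, int]:
        classes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(k) for c, k in zip(classes, counts)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledExpressionMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.allclose(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression_table(
    path: str | Path,
    schema: dict | None = None,
    sep: str | None = None,
) -> LabeledExpressionMatrix:
    """Read a delimited expression table into a :class:`LabeledExpressionMatrix`.

    Parameters
    ----------
    path : path-like
        CSV or TSV file with a header row.  The delimiter is inferred from the
        extension unless ``sep`` is given.
    schema : dict, optional
        Column-role mapping with keys ``"sample_id"`` and ``"label"`` naming
        those columns (defaults ``"id"`` and ``"label"``).  All remaining
        columns are treated as genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    schema = {"sample_id": "id", "label": "label", **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path, sep))

    for role in ("sample_id", "label"):
        col = schema[role]
        if col not in df.columns:
            raise SchemaError(
                f"declared {role} column {col!r} not found in {path.name} "
                f"(columns: {list(df.columns)[:8]}...)"
            )
    id_col, label_col = schema["sample_id"], schema["label"]
    gene_cols = [c for c in df.columns if c not in (id_col, label_col)]
    if not gene_cols:
        raise SchemaError(f"{path.name} has no gene columns")

    sample_ids = df[id_col].astype(str).tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = df[id_col][df[id_col].duplicated()].unique()
        raise ValidationError(f"duplicate sample IDs in {path.name}: {list(dupes)[:5]}")

    raw = df[gene_cols]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) & ~raw.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"non-numeric value {raw.iat[r, c]!r} at sample {sample_ids[r]!r}, "
            f"gene {gene_cols[c]!r}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"missing value at sample {sample_ids[r]!r}, gene {gene_cols[c]!r}"
        )

    raw_labels = df[label_col].tolist()
    classes = sorted(set(raw_labels), key=lambda v: str(v))
    label_map = {c: i for i, c in enumerate(classes)}
    labels = np.array([label_map[v] for v in raw_labels], dtype=int)
    return LabeledExpressionMatrix(sample_ids, gene_cols, values, labels, label_map)


def write_expression_table(
    X: LabeledExpressionMatrix,
    path: str | Path,
    schema: dict | None = None,
    sep: str | None = None,
) -> Path:
    """Write a delimited table plus a ``<path>.labels.json`` sidecar with the
    label-encoding map.  Inverse of :func:`read_expression_table`."""
    path = Path(path)
    schema = {"sample_id": "id", "label": "label", **(schema or {})}
    inverse = {v: k for k, v in X.label_map.items()}
    df = pd.DataFrame(X.values, columns=X.gene_ids)
    df.insert(0, schema["sample_id"], X.sample_ids)
    df[schema["label"]] = [inverse[int(c)] for c in X.labels]
    df.to_csv(path, sep=_sep_for(path, sep), index=False)
    sidecar = path.with_name(path.name + ".labels.json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in X.label_map.items()}, indent=1) + "\n"
    )
    return path


def drop_zero_mean_genes(X: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """Remove genes whose mean across samples is exactly zero.

    For non-negative expression data this deletes all-zero genes, i.e.
    features that carry no signal for any sample; gene order is otherwise
    preserved.
    """
    means = X.values.mean(axis=0)
    keep = means != 0.0
    removed = int((~keep).sum())
    if not keep.any():
        raise EmptyFeatureError("every gene has zero mean; nothing left to analyse")
    if removed:
        logger.info("drop_zero_mean_genes: removed %d of %d genes", removed, X.n_genes)
        return replace(
            X,
            gene_ids=[g for g, k in zip(X.gene_ids, keep) if k],
            values=X.values[:, keep],
        )
    return X


def normalize(
    X: LabeledExpressionMatrix, method: str = "zscore"
) -> LabeledExpressionMatrix:
    """Per-gene normalization.

    ``zscore`` centres each gene column to mean 0 and scales to population
    standard deviation 1 (constant columns map to all-zero); ``none`` is the
    identity, useful when downstream stages expect count-like values.
    """
    if method == "none":
        return X
    if method != "zscore":
        raise ConfigError(f"unknown normalization method {method!r}")
    mu = X.values.mean(axis=0)
    sd = X.values.std(axis=0)  # population sd
    centred = X.values - mu
    out = np.divide(centred, sd, out=np.zeros_like(centred), where=sd > 0)
    return replace(X, values=out)


def oversample_minority(X: LabeledExpressionMatrix, seed: int) -> LabeledExpressionMatrix:
    """Balance class counts by sampling minority-class rows with replacement.

    Every class is brought up to the majority-class count; duplicated rows get
    suffixed sample IDs so identifiers stay unique.  The original rows are a
    prefix of the output.
    """
    counts = X.class_counts()
    if len(counts) < 2:
        raise BalanceError("oversampling needs at least two classes")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    extra_rows: list[int] = []
    for c, k in sorted(counts.items()):
        if k < target:
            pool = np.flatnonzero(X.labels == c)
            extra_rows.extend(rng.choice(pool, size=target - k, replace=True).tolist())
    if not extra_rows:
        return X
    logger.info("oversample_minority: appended %d duplicated rows", len(extra_rows))
    new_ids = list(X.sample_ids)
    seen: dict[int, int] = {}
    for i in extra_rows:
        seen[i] = seen.get(i, 0) + 1
        new_ids.append(f"{X.sample_ids[i]}_dup{seen[i]}")
    return replace(
        X,
        sample_ids=new_ids,
        values=np.vstack([X.values, X.values[extra_rows]]),
        labels=np.concatenate([X.labels, X.labels[extra_rows]]),
    )
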
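"""Count-matrix input, sample labels, and DESeq-style normalization.

The factorization core consumes a nonnegative matrix ``V`` of
log2-transformed, depth-normalized expression values (genes in rows,
samples in columns).  This module reads raw count tables, pairs them with
a two-class sample labelling, estimates per-sample size factors by the
median-of-ratios method, and applies the ``log2(count / sf + pseudocount)``
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ClassLabels",
    "read_counts",
    "write_counts",
    "read_labels",
    "size_factors",
    "normalize_log",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifier(s): {dups}")


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, with row and column identifiers.

    Invariants: all values are nonnegative integers; gene and sample
    identifiers are unique; at least two genes and two samples.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if not np.issubdtype(self.values.dtype, np.number):
            raise ValueError("count matrix must be numeric")
        if np.any(self.values < 0):
            raise ValueError("count matrix contains negative values")
        if not np.all(np.equal(np.mod(self.values, 1), 0)):
            raise ValueError("count matrix contains non-integral values")
        self.values = self.values.astype(np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, L = self.values.shape
        if n != len(self.gene_ids) or L != len(self.sample_ids):
            raise ValueError("identifier lengths do not match matrix shape")
        if n < 2 or L < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


@dataclass
class ExpressionMatrix:
    """Normalized, log2-transformed expression: the nonnegative ``V``."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError(
                "expression matrix contains negative values; the factorization "
                "requires a nonnegative input (use pseudocount >= 1)"
            )
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("identifier lengths do not match matrix shape")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClassLabels:
    """Two-(or more-)class assignment of samples.

    ``class_order`` lists the distinct labels in order of first appearance;
    the first entry is taken as the control group.
    """

    assignment: dict[str, str]
    class_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty label assignment")
        if self.class_order is None:
            order: list[str] = []
            for lab in self.assignment.values():
                if lab not in order:
                    order.append(lab)
            self.class_order = order
        if set(self.class_order) != set(self.assignment.values()):
            raise ValueError("class_order does not match the labels present")
        sizes = self.class_sizes
        if any(s == 0 for s in sizes):
            raise ValueError("every class must be nonempty")

    @property
    def R(self) -> int:
        """Number of classes."""
        return len(self.class_order)

    @property
    def class_sizes(self) -> list[int]:
        vals = list(self.assignment.values())
        return [vals.count(c) for c in self.class_order]

    @property
    def control(self) -> str:
        return self.class_order[0]

    def indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Class index (0-based, control = 0) for each sample in order.

        Raises if a sample has no label.
        """
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"sample(s) without class label: {missing}")
        lut = {c: r for r, c in enumerate(self.class_order)}
        return np.array([lut[self.assignment[s]] for s in sample_ids], dtype=np.intp)

    @classmethod
    def from_sequence(
        cls, labels: Sequence[str], sample_ids: Sequence[str]
    ) -> "ClassLabels":
        if len(labels) != len(sample_ids):
            raise ValueError("one label per sample is required")
        return cls({str(s): str(c) for s, c in zip(sample_ids, labels)})


def read_counts(path: Union[str, Path], delimiter: str | None = None) -> CountMatrix:
    """Read a count table: header of sample ids, first column gene ids.

    ``delimiter`` defaults to tab for ``.tsv``/``.txt`` and comma for
    ``.csv``.  Row and column order are preserved.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except ValueError as exc:
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"malformed numeric cell at gene {row!r}, sample {col!r} in {path}"
            )
    if df.isna().any().any():
        raise ValueError(f"missing value(s) in count table {path}")
    return CountMatrix.from_dataframe(df)


def write_counts(counts: CountMatrix, path: Union[str, Path], delimiter: str = "\t") -> None:
    counts.to_dataframe().to_csv(path, sep=delimiter, index_label="gene_id")


def read_labels(
    path_or_spec: Union[str, Path, Mapping[str, str]],
    sample_ids: Sequence[str] | None = None,
) -> ClassLabels:
    """Read sample labels from a two-column TSV, a mapping, or a CSV string.

    A plain comma-separated string such as ``"A,A,B,B"`` is positional and
    requires ``sample_ids``.  Classes are ordered by first appearance; the
    first class is the control.
    """
    if isinstance(path_or_spec, Mapping):
        return ClassLabels(dict(path_or_spec))
    spec = str(path_or_spec)
    if not Path(spec).exists() and "," in spec:
        if sample_ids is None:
            raise ValueError("positional class list requires sample identifiers")
        return ClassLabels.from_sequence(spec.split(","), sample_ids)
    df = pd.read_csv(spec, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {spec} must have two columns: sample, class")
    assignment: dict[str, str] = {}
    for sample, label in zip(df[0], df[1]):
        if sample in assignment and assignment[sample] != label:
            raise ValueError(f"sample {sample!r} labelled with conflicting classes")
        assignment[sample] = label
    return ClassLabels(assignment)


def size_factors(counts: Union[CountMatrix, np.ndarray, pd.DataFrame]) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq convention).

    For sample ``j``: the median over genes with positive geometric mean of
    ``count_ij / geomean_i``.  Genes containing any zero are excluded since
    their geometric mean is zero.
    """
    if isinstance(counts, CountMatrix):
        values = counts.values
    else:
        values = np.asarray(counts)
    if values.size == 0:
        raise ValueError("empty count matrix")
    values = values.astype(float)
    usable = np.all(values > 0, axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "filter low-coverage genes or add a pseudo-count before "
            "estimating size factors"
        )
    rows = values[usable]
    geomean = np.exp(np.log(rows).mean(axis=1, keepdims=True))
    sf = np.median(rows / geomean, axis=0)
    return sf


def normalize_log(
    counts: Union[CountMatrix, np.ndarray],
    sf: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> Union[ExpressionMatrix, np.ndarray]:
    """Depth-normalize and log2-transform: ``V = log2(count/sf + pseudocount)``.

    With the default pseudocount of 1 the output is guaranteed nonnegative,
    as the factorization requires.  A smaller pseudocount is accepted only
    if no entry becomes negative.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    is_cm = isinstance(counts, CountMatrix)
    values = counts.values if is_cm else np.asarray(counts, dtype=float)
    if sf is None:
        sf = size_factors(values)
    sf = np.asarray(sf, dtype=float)
    if sf.ndim != 1 or sf.shape[0] != values.shape[1]:
        raise ValueError("one size factor per sample is required")
    if np.any(sf <= 0):
        raise ValueError("size factors must be strictly positive")
    V = np.log2(values / sf + pseudocount)
    if np.any(V < 0):
        raise ValueError(
            f"pseudocount {pseudocount} yields negative log-expression; "
            "use pseudocount >= 1"
        )
    if is_cm:
        return ExpressionMatrix(V, counts.gene_ids, counts.sample_ids)
    return V
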
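"""Tabular readers/writers and gene-universe harmonization.

Expression matrices are genes x samples TSV files: a header row of sample
identifiers, first column gene symbols. Clinical tables are one row per
sample with ``sample_id``, ``time`` (follow-up, any consistent unit),
``event`` (1 = event observed, 0 = censored) plus optional categorical
covariate columns used for subgroup filtering.

Gene identity is by exact (case-sensitive) symbol string: probe-to-gene
mapping and cross-platform symbol resolution are upstream concerns, so
callers must supply pre-harmonized, one-row-per-gene matrices. Missing
values are rejected rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "load_expression",
    "write_expression",
    "load_clinical",
    "write_clinical",
    "intersect_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a platform tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with sample identifiers as
        columns. Values may be on a linear or log scale; downstream
        ROC statistics are rank-based and indifferent to monotone
        transforms, while metagene averaging optionally log-transforms.
    platform_tag
        Free-text provenance tag, e.g. ``"rnaseq"`` or ``"chip"``.
    """

    data: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving the given order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.platform_tag)


class ClinicalTable:
    """Per-sample follow-up time, event flag and optional covariates.

    ``data`` is indexed by sample_id with ``time`` and ``event`` columns;
    any further columns are treated as categorical subgroup covariates.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        if data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        for col in ("time", "event"):
            if col not in data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        time = pd.to_numeric(data["time"], errors="raise")
        if not np.all(np.isfinite(time)) or (time <= 0).any():
            raise ValueError("follow-up time must be finite and > 0 for every sample")
        event = pd.to_numeric(data["event"], errors="raise")
        if not set(np.unique(event)).issubset({0, 1}):
            raise ValueError("event flag must be 0 (censored) or 1 (event)")
        data = data.copy()
        data["time"] = time.astype(float)
        data["event"] = event.astype(int)
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset(self, sample_ids) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def filter_subgroup(self, column: str, value) -> "ClinicalTable":
        """Keep samples whose covariate ``column`` equals ``value``."""
        if column not in self.data.columns:
            raise KeyError(f"no clinical column {column!r}")
        kept = self.data[self.data[column].astype(str) == str(value)]
        if kept.empty:
            raise ValueError(f"subgroup {column}={value!r} selects no samples")
        return ClinicalTable(kept)


# TSV dialect: tab-separated, UTF-8, "." decimal, no quoting.
_TSV = dict(sep="\t", encoding="utf-8")


def _read_header(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.readline().rstrip("\n").split("\t")


def load_expression(path, platform_tag: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by keeping the first occurrence
    (with a warning); duplicate sample columns are an error. Non-numeric
    cells raise a parse error naming the offending gene and sample.
    """
    header = _read_header(path)
    samples = header[1:]
    seen = pd.Index(samples)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers in header: {dupes[:5]}")
    raw = pd.read_csv(path, index_col=0, dtype=str, **_TSV)
    raw.columns = samples
    if raw.index.has_duplicates:
        n_dup = int(raw.index.duplicated().sum())
        warnings.warn(
            f"{path}: {n_dup} duplicated gene row(s) collapsed (first kept)",
            stacklevel=2,
        )
        raw = raw[~raw.index.duplicated(keep="first")]
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric value {raw.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    return ExpressionMatrix(numeric, platform_tag)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, **_TSV)


def load_clinical(path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, time, event, covariates...)."""
    df = pd.read_csv(path, index_col=0, **_TSV)
    if df.index.name is None:
        df.index.name = "sample_id"
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, **_TSV)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the sorted intersection of their genes.

    Mirrors cross-platform harmonization where only genes measured on
    both platforms enter the analysis. Raises if no genes are shared.
    """
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("gene sets have empty intersection")
    return (
        ExpressionMatrix(a.data.loc[shared], a.platform_tag),
        ExpressionMatrix(b.data.loc[shared], b.platform_tag),
    )
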
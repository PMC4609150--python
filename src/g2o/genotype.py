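"""Somatic-call and CNV-segment filtering and the binary mutation pattern.

The mutation pattern is the class label of the downstream ROC analysis:
one bit per sample, set when the sample carries a qualifying alteration
in the selected gene (or any/all of up to three genes).

Somatic calls are MAF-like rows (sample_id, gene, judgment, alt_reads,
coverage, function_class[, position]); CNV segments are SEG-like rows
(sample_id, chrom, start, end, n_probes, segment_mean) in log-ratio
units; gene intervals are 4-column (gene, chrom, start, end) tables with
1-based inclusive coordinates.

Threshold conventions follow the wording they derive from: "at least"
thresholds (reads, coverage, probes) are inclusive, "above"/"under"
thresholds (segment means) are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CALL_COLUMNS",
    "SEGMENT_COLUMNS",
    "ALTERED_MRNA_CLASSES",
    "SILENT_CLASSES",
    "KNOWN_CLASSES",
    "MutationPattern",
    "load_mutation_calls",
    "load_cnv_segments",
    "load_gene_intervals",
    "filter_somatic_calls",
    "classify_cnv_segments",
    "map_segments_to_genes",
    "build_mutation_pattern",
]

CALL_COLUMNS = ["sample_id", "gene", "judgment", "alt_reads", "coverage", "function_class"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "segment_mean"]

# Function-class vocabulary (SNPeff-style annotation strings). The two
# named presets contrast alterations that change the mRNA sequence with
# silent ones; "locus region of gene" is its own vocabulary string.
ALTERED_MRNA_CLASSES = frozenset(
    {"start gain", "exon", "splice site", "non-synonymous coding", "stop gain", "stop loss"}
)
SILENT_CLASSES = frozenset({"intron", "synonymous coding"})
KNOWN_CLASSES = ALTERED_MRNA_CLASSES | SILENT_CLASSES | frozenset(
    {"coding non-synonymous", "coding synonymous", "locus region of gene"}
)

_CLASS_PRESETS = {"altered": ALTERED_MRNA_CLASSES, "silent": SILENT_CLASSES}


@dataclass
class MutationPattern:
    """Binary genotype vector aligned to an expression matrix.

    ``labels[i] == 1`` means ``sample_ids[i]`` carries a qualifying
    alteration in the source gene(s).
    """

    sample_ids: list[str]
    labels: np.ndarray
    genes: tuple[str, ...]
    class_filter: str = "all"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be a vector with one entry per sample")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ValueError("labels must be binary")

    @property
    def n_mutated(self) -> int:
        return int(self.labels.sum())

    @property
    def n_wildtype(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def flipped(self) -> "MutationPattern":
        return MutationPattern(self.sample_ids, 1 - self.labels, self.genes, self.class_filter)


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def load_mutation_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", encoding="utf-8")
    _require_columns(calls, CALL_COLUMNS, "mutation call table")
    validate_calls(calls)
    return calls


def validate_calls(calls: pd.DataFrame) -> None:
    _require_columns(calls, CALL_COLUMNS, "mutation call table")
    if (calls["alt_reads"] < 0).any() or (calls["coverage"] < 0).any():
        raise ValueError("alt_reads and coverage must be non-negative")
    if (calls["alt_reads"] > calls["coverage"]).any():
        raise ValueError("alt_reads exceeds coverage in some row(s)")


def load_cnv_segments(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", encoding="utf-8")
    _require_columns(seg, SEGMENT_COLUMNS, "CNV segment table")
    if (seg["start"] > seg["end"]).any():
        raise ValueError("segment start exceeds end in some row(s)")
    if (seg["n_probes"] < 1).any():
        raise ValueError("segments must span at least one probe")
    return seg


def load_gene_intervals(path) -> pd.DataFrame:
    iv = pd.read_csv(path, sep="\t", encoding="utf-8")
    _require_columns(iv, ["gene", "chrom", "start", "end"], "gene interval table")
    return iv


def filter_somatic_calls(
    calls: pd.DataFrame,
    min_alt: int = 4,
    min_cov: int = 20,
    required_judgment: str = "KEEP",
) -> pd.DataFrame:
    """Apply the somatic acceptance filter to a call table.

    Retains exactly the rows whose caller judgment equals
    ``required_judgment`` and whose variant is supported by at least
    ``min_alt`` reads at ``min_cov``-fold coverage or more (both
    inclusive). Row order is preserved; the operation is idempotent.
    """
    if min_alt < 0 or min_cov < 0:
        raise ValueError("thresholds must be non-negative")
    validate_calls(calls)
    keep = (
        (calls["judgment"] == required_judgment)
        & (calls["alt_reads"] >= min_alt)
        & (calls["coverage"] >= min_cov)
    )
    return calls.loc[keep].copy()


def classify_cnv_segments(
    segments: pd.DataFrame,
    min_probes: int = 10,
    amp_thresh: float = 0.2,
    del_thresh: float = -0.2,
) -> pd.DataFrame:
    """Classify CNV segments as amplified or deleted; drop the rest.

    A segment qualifies when it carries at least ``min_probes`` probes
    (inclusive) and its segment mean lies strictly above ``amp_thresh``
    (amplified) or strictly below ``del_thresh`` (deleted). The output
    gains a ``call`` column; the two classes are mutually exclusive.
    """
    if amp_thresh <= del_thresh:
        raise ValueError("amplification threshold must exceed deletion threshold")
    _require_columns(segments, SEGMENT_COLUMNS, "CNV segment table")
    enough = segments["n_probes"] >= min_probes
    amp = enough & (segments["segment_mean"] > amp_thresh)
    dele = enough & (segments["segment_mean"] < del_thresh)
    out = segments.loc[amp | dele].copy()
    out["call"] = np.where(out["segment_mean"] > amp_thresh, "amplified", "deleted")
    return out


def map_segments_to_genes(
    segments: pd.DataFrame, gene_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Annotate classified segments with overlapping genes.

    Coordinates are 1-based inclusive on both sides; any overlap of at
    least one base assigns the segment's call to the gene. A gene hit by
    both an amplified and a deleted segment in the same sample receives
    both calls (logged as a warning). Returns unique
    (sample_id, gene, call) rows. Segments on chromosomes absent from
    the interval table are skipped with a warning.
    """
    _require_columns(segments, SEGMENT_COLUMNS + ["call"], "classified segment table")
    _require_columns(gene_intervals, ["gene", "chrom", "start", "end"], "gene interval table")
    known_chroms = set(gene_intervals["chrom"])
    unknown = sorted(set(segments["chrom"]) - known_chroms)
    if unknown:
        warnings.warn(f"skipping segments on unannotated chromosome(s): {unknown}", stacklevel=2)
        segments = segments[segments["chrom"].isin(known_chroms)]
    merged = segments.merge(gene_intervals, on="chrom", suffixes=("_seg", "_gene"))
    overlap = (merged["start_seg"] <= merged["end_gene"]) & (
        merged["end_seg"] >= merged["start_gene"]
    )
    calls = (
        merged.loc[overlap, ["sample_id", "gene", "call"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    both = calls.groupby(["sample_id", "gene"])["call"].nunique()
    conflicted = both[both > 1]
    if len(conflicted):
        pairs = list(conflicted.index[:5])
        warnings.warn(
            f"gene(s) with both amplified and deleted calls in one sample: {pairs}",
            stacklevel=2,
        )
    return calls


def _resolve_class_filter(class_filter) -> frozenset | None:
    """Return the set of accepted classes, or None for 'all'."""
    if class_filter is None or class_filter == "all":
        return None
    if isinstance(class_filter, str):
        if class_filter in _CLASS_PRESETS:
            return _CLASS_PRESETS[class_filter]
        return frozenset(part.strip() for part in class_filter.split(","))
    return frozenset(class_filter)


def build_mutation_pattern(
    calls: pd.DataFrame,
    samples,
    genes,
    class_filter="all",
    combine: str = "any",
    gene_universe=None,
    cnv_calls: pd.DataFrame | None = None,
) -> MutationPattern:
    """Build the binary mutation pattern for one to three genes.

    Parameters
    ----------
    calls
        Filtered somatic call table (see :func:`filter_somatic_calls`;
        no further QC filtering is applied here).
    samples
        Ordered sample identifiers, typically the columns of the
        training expression matrix. Samples with no retained call are
        labelled 0.
    genes
        One to three gene symbols.
    class_filter
        ``"all"`` (default, any function class), the presets
        ``"altered"`` / ``"silent"``, or an explicit set of class
        strings. With an explicit filter, calls whose class is outside
        the known vocabulary are rejected with a warning.
    combine
        Multi-gene semantics: ``"any"`` labels a sample 1 when at least
        one listed gene is altered (elementwise OR), ``"all"`` requires
        every listed gene (AND).
    gene_universe
        Optional collection of valid gene symbols; when given, each
        requested gene must be a member.
    cnv_calls
        Optional (sample_id, gene, call) table from
        :func:`map_segments_to_genes`; a gene then also counts as
        altered in samples where it is amplified or deleted.
    """
    genes = tuple(genes)
    if not 1 <= len(genes) <= 3:
        raise ValueError("select between one and three genes")
    if combine not in ("any", "all"):
        raise ValueError("combine must be 'any' or 'all'")
    if gene_universe is not None:
        universe = set(gene_universe)
        for gene in genes:
            if gene not in universe:
                raise KeyError(f"gene {gene!r} is not in the gene universe")
    validate_calls(calls)
    samples = list(samples)
    accepted = _resolve_class_filter(class_filter)
    if accepted is not None:
        unknown = set(calls["function_class"]) - KNOWN_CLASSES
        if unknown:
            warnings.warn(
                f"rejecting calls with unknown function class(es): {sorted(unknown)[:5]}",
                stacklevel=2,
            )
        calls = calls[calls["function_class"].isin(accepted)]

    sample_index = {s: i for i, s in enumerate(samples)}
    per_gene = np.zeros((len(genes), len(samples)), dtype=bool)
    for g, gene in enumerate(genes):
        hit_samples = set(calls.loc[calls["gene"] == gene, "sample_id"])
        if cnv_calls is not None and len(cnv_calls):
            hit_samples |= set(cnv_calls.loc[cnv_calls["gene"] == gene, "sample_id"])
        for s in hit_samples:
            if s in sample_index:
                per_gene[g, sample_index[s]] = True
    labels = per_gene.any(axis=0) if combine == "any" else per_gene.all(axis=0)
    filter_desc = class_filter if isinstance(class_filter, str) else ",".join(sorted(class_filter))
    return MutationPattern(samples, labels.astype(int), genes, filter_desc)
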
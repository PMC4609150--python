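"""Genome-wide ROC analysis: from mutation pattern to fingerprint gene sets.

For every gene the expression vector is scored against the binary
mutation pattern with the rank-based AUC

    AUC = P(expression in a mutated sample > expression in a wild-type
          sample) + 0.5 * P(tie),

identical to the Mann-Whitney U statistic divided by n1*n0 (midrank tie
credit). Under exchangeable labels and no ties the AUC has mean 1/2 and
standard deviation

    se0 = sqrt((n1 + n0 + 1) / (12 * n1 * n0)),

the exact permutation SD (equivalently the Hanley-McNeil standard error
evaluated at AUC = 1/2). The z-score (AUC - 1/2)/se0 is referred to the
normal distribution for a two-sided p-value; two-sided because the
screen classifies both up- and downregulation symmetrically.

Genes pass into the upregulated fingerprint when AUC >= auc_min and
p <= p_max, and into the downregulated fingerprint when
AUC <= 1 - auc_min and p <= p_max. No multiple-testing correction is
applied: the raw-p gate is paired with the AUC effect-size floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import MutationPattern
from .io import ExpressionMatrix

__all__ = [
    "RocResult",
    "RocThresholds",
    "FingerprintSets",
    "compute_auc",
    "auc_null_se",
    "auc_p_value",
    "derive_fingerprint",
]

DEFAULT_MIN_MUTATED = 7  # fewer mutated samples -> analysis reported as NA


@dataclass(frozen=True)
class RocResult:
    """Per-gene ROC outcome."""

    gene: str
    auc: float
    se0: float
    z: float
    p: float


@dataclass(frozen=True)
class RocThresholds:
    """Significance gates of the ROC screen.

    ``auc_min`` is the minimal AUC for the up set (mirrored as
    ``1 - auc_min`` for the down set); the supported range is
    0.6-0.75. ``p_max`` is the raw p-value gate, supported range
    0.05 down to 0.0001.
    """

    auc_min: float = 0.65
    p_max: float = 0.01

    def __post_init__(self) -> None:
        if not 0.5 < self.auc_min < 1:
            raise ValueError("auc_min must lie in (0.5, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")


@dataclass
class FingerprintSets:
    """Up/down fingerprint gene lists with their ROC statistics.

    ``na`` is set when fewer than ``min_mutated`` samples carry the
    alteration, in which case both lists are empty and the verdict of
    any downstream analysis is "NA" rather than negative.
    """

    up: list[RocResult]
    down: list[RocResult]
    thresholds: RocThresholds
    n_mutated: int
    n_wildtype: int
    na: bool = False
    table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def up_genes(self) -> list[str]:
        return [r.gene for r in self.up]

    @property
    def down_genes(self) -> list[str]:
        return [r.gene for r in self.down]


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    n1 = int(labels.sum())
    n0 = int(len(labels) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("mutation pattern must contain both classes")
    return n1, n0


def compute_auc(expr, pattern) -> float:
    """Rank-based AUC of one expression vector against the pattern.

    ``pattern`` may be a :class:`~g2o.genotype.MutationPattern` or a
    plain binary vector. Ties receive midrank (0.5) credit, so the
    statistic is invariant under any strictly increasing transform of
    the expression values.
    """
    labels = pattern.labels if isinstance(pattern, MutationPattern) else np.asarray(pattern)
    expr = np.asarray(expr, dtype=float)
    if expr.shape != labels.shape:
        raise ValueError("expression vector and pattern differ in length")
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression values must be finite")
    n1, n0 = _check_labels(labels)
    ranks = stats.rankdata(expr)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_null_se(n1: int, n0: int) -> float:
    """Exact null (label-permutation) standard deviation of the AUC.

    For tie-free data, permuting n1 positive labels among n1 + n0
    samples gives Var(AUC) = (n1 + n0 + 1) / (12 n1 n0); this
    coincides with the Hanley-McNeil standard error at AUC = 1/2.
    Symmetric in its arguments.
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("both group sizes must be at least 1")
    return math.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))


def auc_p_value(auc: float, n1: int, n0: int) -> float:
    """Two-sided normal p-value for H0: AUC = 1/2.

    z = (AUC - 1/2)/se0; p = 2 * Phi(-|z|), clamped into (0, 1]. The
    p-value is symmetric under AUC <-> 1 - AUC.
    """
    z = (auc - 0.5) / auc_null_se(n1, n0)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _roc_table(values: np.ndarray, labels: np.ndarray, genes) -> pd.DataFrame:
    """Vectorized per-gene AUC/z/p for a genes x samples matrix."""
    n1, n0 = _check_labels(labels)
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, labels == 1].sum(axis=1)
    auc = (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)
    se0 = auc_null_se(n1, n0)
    z = (auc - 0.5) / se0
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return pd.DataFrame({"gene": list(genes), "auc": auc, "se0": se0, "z": z, "p": p})


def derive_fingerprint(
    expr: ExpressionMatrix,
    pattern: MutationPattern,
    thresholds: RocThresholds | None = None,
    min_mutated: int = DEFAULT_MIN_MUTATED,
) -> FingerprintSets:
    """Screen every gene of the training matrix against the pattern.

    Returns the up- and downregulated fingerprint sets together with the
    full per-gene ROC table (``set`` column in {up, down, none}). When
    fewer than ``min_mutated`` samples are mutated the screen is not
    attempted and an NA-flagged empty result is returned.
    """
    thresholds = thresholds or RocThresholds()
    if list(expr.sample_ids) != list(pattern.sample_ids):
        raise ValueError("expression matrix and mutation pattern sample ids differ")
    n1 = pattern.n_mutated
    n0 = pattern.n_wildtype
    if n1 < min_mutated:
        return FingerprintSets(
            up=[], down=[], thresholds=thresholds, n_mutated=n1, n_wildtype=n0, na=True
        )
    table = _roc_table(expr.data.to_numpy(), pattern.labels, expr.gene_ids)
    sig = table["p"] <= thresholds.p_max
    up_mask = sig & (table["auc"] >= thresholds.auc_min)
    down_mask = sig & (table["auc"] <= 1.0 - thresholds.auc_min)
    table["set"] = np.select([up_mask, down_mask], ["up", "down"], default="none")

    def _results(mask) -> list[RocResult]:
        rows = table.loc[mask]
        return [
            RocResult(r.gene, float(r.auc), float(r.se0), float(r.z), float(r.p))
            for r in rows.itertuples(index=False)
        ]

    return FingerprintSets(
        up=_results(up_mask),
        down=_results(down_mask),
        thresholds=thresholds,
        n_mutated=n1,
        n_wildtype=n0,
        na=False,
        table=table,
    )
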
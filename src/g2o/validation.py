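"""Robustness machinery: permutation FPR, random holdout, platform concordance.

Three studies probe the pipeline's reliability:

* ``permutation_study`` reruns the full analysis on batches of randomly
  drawn genes and counts significant verdicts per batch; paired with
  ``estimate_fpr`` this turns the counts into a false-positive rate,
  treating the expected density of genuinely cancer-linked genes
  (e.g. the COSMIC consensus fraction, 571 per 10,000) as the true
  positives: FP = max(0, observed - expected TP),
  TN = genes_per_run - expected TP - FP, FPR = FP / (FP + TN).
* ``holdout_study`` drops a random fraction (default 20%) of the
  training-cohort samples and reruns the analysis repeatedly,
  summarizing the stability of each signature's HR and p.
* ``platform_concordance`` computes the per-sample Spearman rank
  correlation between two expression matrices of the same samples
  (e.g. RNA-seq vs microarray).

All stochastic procedures take an explicit seed; gene and sample draws
use independent substreams per run index so each run is individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix
from .survival import G2OConfig, run_g2o

__all__ = [
    "PermutationSummary",
    "FprEstimate",
    "HoldoutSignatureSummary",
    "HoldoutSummary",
    "ConcordanceResult",
    "permutation_study",
    "estimate_fpr",
    "holdout_study",
    "platform_concordance",
]

COSMIC_CONSENSUS_DENSITY = 571 / 10_000  # known cancer genes per screened gene


@dataclass
class PermutationSummary:
    """Significant-gene counts across random-gene permutation runs."""

    counts: np.ndarray  # one significant-verdict count per run
    genes_per_run: int

    @property
    def k_runs(self) -> int:
        return len(self.counts)

    @property
    def mean_count(self) -> float:
        return float(self.counts.mean())

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    @property
    def min_count(self) -> int:
        return int(self.counts.min())

    @property
    def histogram(self) -> dict[int, int]:
        values, freq = np.unique(self.counts, return_counts=True)
        return {int(v): int(f) for v, f in zip(values, freq)}


@dataclass(frozen=True)
class FprEstimate:
    """FPR bookkeeping for one run's significant-gene count."""

    sig_count: float
    expected_positives: float
    fp: float
    tn: float
    fpr: float


@dataclass
class HoldoutSignatureSummary:
    direction: str
    n_reps_with_signature: int
    mean_p: float
    sd_p: float
    mean_hr: float
    hr_min: float
    hr_max: float


@dataclass
class HoldoutSummary:
    """Stability of one gene set's analysis under repeated 20% holdout."""

    genes: tuple[str, ...]
    n_reps: int
    n_significant: int
    n_na: int
    up: HoldoutSignatureSummary | None
    down: HoldoutSignatureSummary | None
    records: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ConcordanceResult:
    """Per-sample cross-platform Spearman correlations."""

    per_sample: pd.Series
    median: float
    minimum: float
    n_genes: int


def permutation_study(
    ngs_expr: ExpressionMatrix,
    chip_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    calls: pd.DataFrame,
    k_runs: int = 100,
    genes_per_run: int = 100,
    cfg: G2OConfig | None = None,
    seed: int = 0,
    candidate_genes=None,
) -> PermutationSummary:
    """Rerun the whole analysis on random gene batches and count hits.

    Each run draws ``genes_per_run`` genes without replacement from the
    shared gene universe (or ``candidate_genes``), executes the full
    pipeline per gene, and counts significant verdicts (NA results
    count as not significant). Deterministic given ``seed``.
    """
    if k_runs < 1:
        raise ValueError("k_runs must be at least 1")
    cfg = cfg or G2OConfig()
    universe = list(
        candidate_genes
        if candidate_genes is not None
        else sorted(set(ngs_expr.gene_ids) & set(chip_expr.gene_ids))
    )
    if genes_per_run > len(universe):
        raise ValueError(
            f"genes_per_run={genes_per_run} exceeds the gene universe ({len(universe)})"
        )
    streams = np.random.SeedSequence(seed).spawn(k_runs)
    counts = np.zeros(k_runs, dtype=int)
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        drawn = rng.choice(universe, size=genes_per_run, replace=False)
        n_sig = 0
        for gene in drawn:
            result = run_g2o(ngs_expr, chip_expr, clinical, calls, [gene], cfg)
            n_sig += int(result.significant)
        counts[i] = n_sig
    return PermutationSummary(counts=counts, genes_per_run=genes_per_run)


def estimate_fpr(
    sig_count: float,
    genes_per_run: int = 100,
    known_positive_density: float = COSMIC_CONSENSUS_DENSITY,
) -> FprEstimate:
    """False-positive rate of one run given the expected hit density.

    Significant genes up to the expected number of genuine positives
    (density x genes per run) are credited as true positives; only the
    excess counts as false positives, so the estimate clamps to 0 when
    the run finds no more hits than expected.
    """
    if not 0 <= known_positive_density <= 1:
        raise ValueError("known_positive_density must lie in [0, 1]")
    if sig_count < 0 or sig_count > genes_per_run:
        raise ValueError("sig_count must lie in [0, genes_per_run]")
    expected = known_positive_density * genes_per_run
    fp = max(0.0, sig_count - expected)
    tn = genes_per_run - expected - fp
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    return FprEstimate(
        sig_count=float(sig_count),
        expected_positives=float(expected),
        fp=float(fp),
        tn=float(tn),
        fpr=float(fpr),
    )


def _summarize_signature(records: pd.DataFrame, direction: str):
    rows = records[(records["direction"] == direction) & records["hr"].notna()]
    if rows.empty:
        return None
    return HoldoutSignatureSummary(
        direction=direction,
        n_reps_with_signature=len(rows),
        mean_p=float(rows["p"].mean()),
        sd_p=float(rows["p"].std(ddof=1)) if len(rows) > 1 else 0.0,
        mean_hr=float(rows["hr"].mean()),
        hr_min=float(rows["hr"].min()),
        hr_max=float(rows["hr"].max()),
    )


def holdout_study(
    ngs_expr: ExpressionMatrix,
    chip_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    calls: pd.DataFrame,
    genes,
    holdout_fraction: float = 0.2,
    n_reps: int = 10,
    cfg: G2OConfig | None = None,
    seed: int = 0,
) -> HoldoutSummary:
    """Repeatedly drop a random sample fraction and rerun the analysis.

    The holdout is applied to the training cohort — the side where
    sample loss can change the fingerprint; the validation cohort stays
    fixed. Each rep keeps round((1 - fraction) * n) training samples.
    Up- and down-signature HR/p are summarized separately.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    cfg = cfg or G2OConfig()
    samples = np.array(ngs_expr.sample_ids)
    n_keep = int(round((1.0 - holdout_fraction) * len(samples)))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        kept = rng.choice(samples, size=n_keep, replace=False)
        kept = [s for s in samples if s in set(kept)]  # preserve cohort order
        sub_expr = ngs_expr.subset_samples(kept)
        sub_calls = calls[calls["sample_id"].isin(set(kept))]
        result = run_g2o(sub_expr, chip_expr, clinical, sub_calls, genes, cfg)
        for direction, sig in (("up", result.up), ("down", result.down)):
            rows.append(
                {
                    "rep": rep,
                    "direction": direction,
                    "hr": sig.cox.hr if sig else np.nan,
                    "p": sig.cox.p if sig else np.nan,
                    "n_genes": len(sig.genes) if sig else 0,
                    "significant": result.significant,
                    "na": result.na_flag,
                }
            )
    records = pd.DataFrame(rows)
    per_rep = records.drop_duplicates("rep")
    return HoldoutSummary(
        genes=tuple(genes),
        n_reps=n_reps,
        n_significant=int(per_rep["significant"].sum()),
        n_na=int(per_rep["na"].sum()),
        up=_summarize_signature(records, "up"),
        down=_summarize_signature(records, "down"),
        records=records,
    )


def platform_concordance(a: ExpressionMatrix, b: ExpressionMatrix) -> ConcordanceResult:
    """Per-sample Spearman correlation between two platforms.

    Matrices are restricted to shared genes and shared samples; for
    each shared sample the rank correlation across genes is computed.
    Rank correlation makes the comparison invariant to monotone
    per-platform transforms (e.g. log scaling).
    """
    shared_genes = sorted(set(a.gene_ids) & set(b.gene_ids))
    if len(shared_genes) < 3:
        raise ValueError("need at least 3 shared genes for rank correlation")
    shared_samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared_samples:
        raise ValueError("no shared samples between the matrices")
    av = a.data.loc[shared_genes, shared_samples].to_numpy()
    bv = b.data.loc[shared_genes, shared_samples].to_numpy()
    rhos = [
        float(stats.spearmanr(av[:, j], bv[:, j]).statistic)
        for j in range(len(shared_samples))
    ]
    per_sample = pd.Series(rhos, index=shared_samples, name="spearman_rho")
    return ConcordanceResult(
        per_sample=per_sample,
        median=float(per_sample.median()),
        minimum=float(per_sample.min()),
        n_genes=len(shared_genes),
    )
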
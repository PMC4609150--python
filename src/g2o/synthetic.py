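"""Paired synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a training ("NGS-like") cohort in which a driver gene is mutated with
  Bernoulli prevalence and a planted set of fingerprint genes is
  mean-shifted (up or down) in mutated samples;
* a validation ("chip-like") cohort of independent samples with a
  latent genotype drawn from the same law and the same expression
  model, plus survival follow-up whose hazard is proportional to
  exp(hazard_coef * standardized true up-metagene) — i.e. outcome is
  linked to the transcriptomic surrogate, not to the genotype bit
  itself, matching the causal chain mutation -> fingerprint -> outcome.

Expression is Gaussian on a log2-like scale (per-gene baselines ~
N(8, 2), unit noise); the upstream screen is rank-based and the
downstream metagene is an average, so the distributional family matters
little beyond averaging behaviour. Survival times are exponential with
independent exponential censoring whose rate is solved numerically so
the expected censored fraction equals ``censor_rate``.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ClinicalTable, ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticData", "generate_paired_cohorts"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_ngs: int = 200
    n_chip: int = 600
    n_genes: int = 1000
    prevalence: float = 0.2
    n_up: int = 50
    n_down: int = 50
    effect_size: float = 1.0  # mean shift in units of noise_sd
    noise_sd: float = 1.0
    hazard_coef: float = 0.7  # log-hazard per SD of the true up-metagene
    censor_rate: float = 0.3
    baseline_hazard: float = 0.05
    seed: int = 0
    # Optional realism knobs (off by default):
    background_prevalence: float = 0.0  # independent null mutations in non-driver genes
    hazard_on_genotype: bool = False  # link hazard to the genotype bit instead
    include_rejected_calls: bool = True  # add QC-failing rows the filter must drop

    def __post_init__(self) -> None:
        if self.n_up + self.n_down + 1 > self.n_genes:
            raise ValueError("n_up + n_down (+ driver) must fit into n_genes")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_hazard and noise_sd must be positive")
        if not 0 <= self.background_prevalence < 1:
            raise ValueError("background_prevalence must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted parameters, for recovery tests."""

    driver_gene: str
    mutated_ngs_samples: list[str]
    chip_latent_genotype: np.ndarray
    up_genes: list[str]
    down_genes: list[str]
    effect_size: float
    hazard_coef: float


@dataclass
class SyntheticData:
    calls: pd.DataFrame
    ngs_expr: ExpressionMatrix
    chip_expr: ExpressionMatrix
    clinical: ClinicalTable
    truth: SyntheticTruth


def _expression(rng, baselines, shifts, genotype, noise_sd) -> np.ndarray:
    """genes x samples Gaussian expression with genotype-linked shifts."""
    n_genes, n_samples = len(baselines), len(genotype)
    mean = baselines[:, None] + shifts[:, None] * genotype[None, :]
    return mean + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))


def _censoring_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with E[P(censor)] == censor_rate.

    With event time ~ Exp(lambda_i) and independent censoring ~ Exp(c),
    P(censored_i) = c / (c + lambda_i); solve the cohort average for c.
    """
    if censor_rate == 0:
        return 0.0

    def gap(c: float) -> float:
        return float(np.mean(c / (c + hazards)) - censor_rate)

    lo, hi = hazards.min() * 1e-9, hazards.max() * 1e9
    return float(optimize.brentq(gap, lo, hi))


def _call_rows(rng, samples, gene, judgment, function_class):
    rows = []
    for s in samples:
        coverage = int(rng.integers(20, 200))
        alt = int(rng.integers(4, max(5, coverage // 2)))
        rows.append(
            {
                "sample_id": s,
                "gene": gene,
                "judgment": judgment,
                "alt_reads": min(alt, coverage),
                "coverage": coverage,
                "function_class": function_class,
            }
        )
    return rows


def generate_paired_cohorts(cfg: SyntheticConfig | None = None) -> SyntheticData:
    """Generate the paired training/validation cohorts plus ground truth.

    Gene symbols are G0001..G{n_genes}; the driver is the first symbol,
    followed by the planted up and down fingerprint genes. Each mutated
    training sample yields one passing somatic call (judgment KEEP,
    >=4 alt reads, >=20x coverage, class "non-synonymous coding"); with
    ``include_rejected_calls`` a handful of wild-type samples carry
    QC-failing rows so the acceptance filter has work to do.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    driver = gene_ids[0]
    up_genes = gene_ids[1 : 1 + cfg.n_up]
    down_genes = gene_ids[1 + cfg.n_up : 1 + cfg.n_up + cfg.n_down]
    shifts = np.zeros(cfg.n_genes)
    shift = cfg.effect_size * cfg.noise_sd
    shifts[1 : 1 + cfg.n_up] = shift
    shifts[1 + cfg.n_up : 1 + cfg.n_up + cfg.n_down] = -shift
    baselines = rng.normal(8.0, 2.0, size=cfg.n_genes)

    ngs_samples = [f"NGS{i + 1:04d}" for i in range(cfg.n_ngs)]
    chip_samples = [f"CHIP{i + 1:04d}" for i in range(cfg.n_chip)]

    geno_ngs = rng.binomial(1, cfg.prevalence, size=cfg.n_ngs)
    geno_chip = rng.binomial(1, cfg.prevalence, size=cfg.n_chip)

    ngs_values = _expression(rng, baselines, shifts, geno_ngs, cfg.noise_sd)
    # Chip intensities are emitted on a linear (MAS5-like) scale so the
    # pipeline's default log2(x+1) metagene averaging applies; the
    # underlying log2-scale values carry the Gaussian shift model.
    chip_log = _expression(rng, baselines, shifts, geno_chip, cfg.noise_sd)
    chip_values = np.exp2(chip_log)
    ngs_expr = ExpressionMatrix(
        pd.DataFrame(ngs_values, index=gene_ids, columns=ngs_samples), "rnaseq"
    )
    chip_expr = ExpressionMatrix(
        pd.DataFrame(chip_values, index=gene_ids, columns=chip_samples), "chip"
    )

    mutated = [s for s, g in zip(ngs_samples, geno_ngs) if g == 1]
    rows = _call_rows(rng, mutated, driver, "KEEP", "non-synonymous coding")
    if cfg.include_rejected_calls:
        wild = [s for s, g in zip(ngs_samples, geno_ngs) if g == 0]
        n_noise = min(len(wild), max(1, cfg.n_ngs // 20))
        noisy = list(rng.choice(wild, size=n_noise, replace=False))
        for row in _call_rows(rng, noisy, driver, "REJECT", "non-synonymous coding"):
            row["alt_reads"], row["coverage"] = 2, 15
            rows.append(row)
    if cfg.background_prevalence > 0:
        # Independent null mutation patterns for every non-driver gene
        # (null regardless of planting: no expression link).
        bg = rng.binomial(
            1, cfg.background_prevalence, size=(cfg.n_genes - 1, cfg.n_ngs)
        )
        for gi, gene in enumerate(gene_ids[1:]):
            carriers = [ngs_samples[si] for si in np.flatnonzero(bg[gi])]
            rows.extend(_call_rows(rng, carriers, gene, "KEEP", "non-synonymous coding"))
    calls = pd.DataFrame(rows, columns=[
        "sample_id", "gene", "judgment", "alt_reads", "coverage", "function_class",
    ])

    # Survival: hazard tied to the standardized true up-metagene (or to
    # the genotype bit when hazard_on_genotype is set).
    if cfg.hazard_on_genotype:
        link = geno_chip.astype(float)
    elif cfg.n_up > 0:
        link = chip_log[1 : 1 + cfg.n_up].mean(axis=0)  # true up-metagene, log scale
    else:
        link = np.zeros(cfg.n_chip)  # no planted fingerprint: flat hazard
    sd = link.std()
    z = (link - link.mean()) / sd if sd > 0 else np.zeros_like(link)
    hazards = cfg.baseline_hazard * np.exp(cfg.hazard_coef * z)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _censoring_rate(hazards, cfg.censor_rate)
    if c_rate > 0:
        censor_times = rng.exponential(1.0 / c_rate, size=cfg.n_chip)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        events = np.ones(cfg.n_chip, dtype=int)
    observed = np.maximum(observed, 1e-9)
    clinical = ClinicalTable(
        pd.DataFrame({"time": observed, "event": events}, index=pd.Index(chip_samples, name="sample_id"))
    )

    truth = SyntheticTruth(
        driver_gene=driver,
        mutated_ngs_samples=mutated,
        chip_latent_genotype=geno_chip,
        up_genes=list(up_genes),
        down_genes=list(down_genes),
        effect_size=cfg.effect_size,
        hazard_coef=cfg.hazard_coef,
    )
    return SyntheticData(calls, ngs_expr, chip_expr, clinical, truth)
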
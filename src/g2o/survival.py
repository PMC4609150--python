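"""Metagene scoring and survival analysis in the validation cohort.

Each fingerprint gene set is collapsed to a per-sample "metagene" (the
mean expression of its genes, by default on a log2(x+1) scale so that a
handful of very highly expressed genes cannot dominate a linear-scale
average). The cohort is split at the median metagene score, and the
high-vs-low contrast is quantified with a single-covariate Cox
proportional-hazards model (Efron tie handling, Wald CI and p) and
Kaplan-Meier curves.

The up- and downregulated signatures are analysed separately; the two
hazard ratios are folded into a single "average HR" defined as the mean
of the larger HR and the reciprocal of the smaller one (>= 1 by
construction). The default significance verdict requires average
HR > 1.4 and every available signature p-value <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from . import genotype
from .fingerprint import (
    DEFAULT_MIN_MUTATED,
    FingerprintSets,
    RocThresholds,
    derive_fingerprint,
)
from .io import ClinicalTable, ExpressionMatrix, intersect_genes

__all__ = [
    "MetageneScores",
    "CoxResult",
    "KMCurve",
    "SignatureResult",
    "G2OConfig",
    "G2OResult",
    "compute_metagene",
    "median_dichotomize",
    "fit_cox_binary",
    "km_estimate",
    "average_hr",
    "run_g2o",
]


@dataclass
class MetageneScores:
    """Per-sample mean expression of a gene set."""

    sample_ids: list[str]
    score: np.ndarray
    gene_set: tuple[str, ...]
    n_genes_found: int


@dataclass
class CoxResult:
    """High-vs-low Cox contrast: HR = exp(beta) with Wald 95% CI and p."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_high: int
    n_low: int
    n_events: int
    beta: float
    se: float
    separation_flag: bool = False


@dataclass
class KMCurve:
    """Product-limit curve for one group: stepwise (time, survival, at-risk)."""

    group: str
    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SignatureResult:
    """Survival analysis of one (up or down) metagene."""

    direction: str
    genes: list[str]
    scores: MetageneScores
    cox: CoxResult
    km: dict[str, KMCurve]


@dataclass
class G2OConfig:
    """Bundled settings of the end-to-end pipeline."""

    roc: RocThresholds = field(default_factory=RocThresholds)
    min_mutated: int = DEFAULT_MIN_MUTATED
    hr_min: float = 1.4
    surv_p_max: float = 0.05
    class_filter: object = "all"
    combine: str = "any"
    log_transform_chip: bool = True
    subgroup: tuple[str, object] | None = None  # (clinical column, value)


@dataclass
class G2OResult:
    """End-to-end verdict for one gene (or gene combination)."""

    genes: tuple[str, ...]
    fingerprint: FingerprintSets
    up: SignatureResult | None
    down: SignatureResult | None
    average_hr: float | None
    significant: bool
    na_flag: bool

    @property
    def up_hr(self) -> float | None:
        return self.up.cox.hr if self.up else None

    @property
    def down_hr(self) -> float | None:
        return self.down.cox.hr if self.down else None


def compute_metagene(
    expr: ExpressionMatrix, gene_set, log_transform: bool = False
) -> MetageneScores:
    """Average a gene set into one score per sample.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error. With ``log_transform`` the values are
    mapped through log2(x + 1) before averaging, which is the pipeline
    default for linear-scale chip intensities.
    """
    gene_set = list(dict.fromkeys(gene_set))
    found = [g for g in gene_set if g in expr.data.index]
    missing = [g for g in gene_set if g not in expr.data.index]
    if not found:
        raise ValueError("no gene of the set is present in the expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of the set absent from the cohort: {missing[:5]}",
            stacklevel=2,
        )
    values = expr.data.loc[found].to_numpy(dtype=float)
    if log_transform:
        if (values < 0).any():
            raise ValueError("log2(x+1) transform requires non-negative expression")
        values = np.log2(values + 1.0)
    return MetageneScores(
        sample_ids=expr.sample_ids,
        score=values.mean(axis=0),
        gene_set=tuple(gene_set),
        n_genes_found=len(found),
    )


def median_dichotomize(scores: MetageneScores | np.ndarray) -> np.ndarray:
    """Split samples at the median score: 1 = high (strictly above), 0 = low.

    Ties at the median go to the low group, so "high" always means
    strictly above the cohort median. All-identical scores cannot be
    split and raise.
    """
    values = scores.score if isinstance(scores, MetageneScores) else np.asarray(scores, float)
    if len(values) < 2:
        raise ValueError("need at least two samples to dichotomize")
    groups = (values > np.median(values)).astype(int)
    if groups.sum() == 0 or groups.sum() == len(groups):
        raise ValueError("scores are constant; cannot form two groups")
    return groups


def _survival_frame(groups, clinical: ClinicalTable) -> pd.DataFrame:
    groups = np.asarray(groups, dtype=int)
    if len(groups) != len(clinical.sample_ids):
        raise ValueError("group vector and clinical table differ in length")
    if groups.sum() == 0 or groups.sum() == len(groups):
        raise ValueError("both groups must be non-empty")
    return pd.DataFrame(
        {"time": clinical.time, "event": clinical.event, "group": groups}
    )


def fit_cox_binary(groups, clinical: ClinicalTable) -> CoxResult:
    """Cox proportional-hazards fit of a single binary covariate.

    Maximizes the partial likelihood with Efron's tie correction and
    reports HR = exp(beta) for the high (1) vs low (0) group with a
    Wald 95% CI and p-value. Swapping the labels inverts the HR
    exactly. Complete separation (monotone likelihood) is caught and
    returned as a flagged boundary result rather than an exception.
    """
    df = _survival_frame(groups, clinical)
    if df["event"].sum() == 0:
        raise ValueError("no events observed; Cox model is undefined")
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            # Monotone likelihood: refit with a small ridge penalty and flag.
            separation = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary.loc["group"]
    beta = float(summary["coef"])
    se = float(summary["se(coef)"])
    if not separation and (abs(beta) > 10 or not np.isfinite(se)):
        separation = True
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        p=float(summary["p"]),
        n_high=int(df["group"].sum()),
        n_low=int((1 - df["group"]).sum()),
        n_events=int(df["event"].sum()),
        beta=beta,
        se=se,
        separation_flag=separation,
    )


def km_estimate(groups, clinical: ClinicalTable) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curves for the high and low groups.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times;
    censored subjects leave the risk set after their censoring time.
    """
    df = _survival_frame(groups, clinical)
    curves: dict[str, KMCurve] = {}
    for label, name in ((0, "low"), (1, "high")):
        sub = df[df["group"] == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=name)
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_[name].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
        curves[name] = KMCurve(name, times, surv, at_risk)
    return curves


def average_hr(hr_up: float | None = None, hr_down: float | None = None) -> float:
    """Fold the two signature HRs into one summary >= 1.

    With both present: mean of the larger HR and the reciprocal of the
    smaller. With one present: max(h, 1/h). At least one HR is
    required and HRs must be positive.
    """
    present = [h for h in (hr_up, hr_down) if h is not None]
    if not present:
        raise ValueError("at least one hazard ratio is required")
    if any(h <= 0 for h in present):
        raise ValueError("hazard ratios must be positive")
    if len(present) == 1:
        h = present[0]
        return max(h, 1.0 / h)
    return float((max(present) + 1.0 / min(present)) / 2.0)


def _analyse_signature(
    direction: str,
    genes: list[str],
    chip: ExpressionMatrix,
    clinical: ClinicalTable,
    cfg: G2OConfig,
) -> SignatureResult | None:
    if not genes:
        return None
    present = [g for g in genes if g in chip.data.index]
    if not present:
        warnings.warn(
            f"{direction} signature has no gene in the validation cohort", stacklevel=2
        )
        return None
    scores = compute_metagene(chip, present, log_transform=cfg.log_transform_chip)
    groups = median_dichotomize(scores)
    cox = fit_cox_binary(groups, clinical)
    km = km_estimate(groups, clinical)
    return SignatureResult(direction, present, scores, cox, km)


def run_g2o(
    ngs_expr: ExpressionMatrix,
    chip_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    calls: pd.DataFrame,
    genes,
    cfg: G2OConfig | None = None,
) -> G2OResult:
    """End-to-end genotype-to-outcome analysis for one gene set.

    Pipeline: build the mutation pattern from the (pre-filtered) call
    table on the training cohort; screen all shared genes by ROC into
    up/down fingerprints; score each fingerprint as a metagene in the
    validation cohort; median-dichotomize; fit Cox and Kaplan-Meier;
    fold the HRs into the average HR and apply the significance rule.
    Training samples never enter the survival analysis: the two cohorts
    are distinct by construction and only the fingerprint crosses over.
    """
    cfg = cfg or G2OConfig()
    ngs_expr, chip_expr = intersect_genes(ngs_expr, chip_expr)

    try:
        pattern = genotype.build_mutation_pattern(
            calls,
            ngs_expr.sample_ids,
            genes,
            class_filter=cfg.class_filter,
            combine=cfg.combine,
            gene_universe=ngs_expr.gene_ids,
        )
    except Exception as err:
        raise RuntimeError(f"[genotype] {err}") from err

    try:
        fingerprint = derive_fingerprint(
            ngs_expr, pattern, cfg.roc, min_mutated=cfg.min_mutated
        )
    except Exception as err:
        raise RuntimeError(f"[fingerprint] {err}") from err

    if fingerprint.na:
        return G2OResult(
            genes=pattern.genes,
            fingerprint=fingerprint,
            up=None,
            down=None,
            average_hr=None,
            significant=False,
            na_flag=True,
        )

    if cfg.subgroup is not None:
        clinical = clinical.filter_subgroup(*cfg.subgroup)
    shared_samples = [s for s in chip_expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared_samples:
        raise RuntimeError("[survival] no validation sample has clinical follow-up")
    chip = chip_expr.subset_samples(shared_samples)
    clin = clinical.subset(shared_samples)

    try:
        up = _analyse_signature("up", fingerprint.up_genes, chip, clin, cfg)
        down = _analyse_signature("down", fingerprint.down_genes, chip, clin, cfg)
    except Exception as err:
        raise RuntimeError(f"[survival] {err}") from err

    hrs = {"up": up.cox.hr if up else None, "down": down.cox.hr if down else None}
    if up is None and down is None:
        avg_hr = None
        significant = False
    else:
        avg_hr = average_hr(hrs["up"], hrs["down"])
        pvals = [s.cox.p for s in (up, down) if s is not None]
        significant = avg_hr > cfg.hr_min and all(p <= cfg.surv_p_max for p in pvals)
    return G2OResult(
        genes=pattern.genes,
        fingerprint=fingerprint,
        up=up,
        down=down,
        average_hr=avg_hr,
        significant=significant,
        na_flag=False,
    )
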
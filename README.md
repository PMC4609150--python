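# g2o — genotype-to-outcome via transcriptomic fingerprints

Estimating the prognostic impact of a somatic mutation directly is hard:
cohorts with deep sequencing rarely have mature clinical follow-up, and
cohorts with long follow-up rarely have genotypes. `g2o` implements the
genotype-to-outcome strategy that bridges the two: a mutation is first
translated into a **transcriptomic fingerprint** — the set of genes whose
expression separates mutated from wild-type tumors — in a cohort with both
genotype and RNA-seq data, and that fingerprint is then scored as a
surrogate marker in an independent, well-annotated expression cohort to
test its association with survival.

It is written for computational biologists who want to screen candidate
driver genes for clinical relevance, or to study the behaviour of
surrogate-signature pipelines on controlled synthetic data.

## The method

Given a training cohort with somatic calls and expression, and a
validation cohort with expression and survival:

1. **Mutation pattern.** QC-filter the somatic calls (judgment `KEEP`,
   ≥ 4 supporting reads, ≥ 20× coverage) and form the binary vector
   `m_s ∈ {0,1}` marking samples with a qualifying alteration in the
   selected gene(s) (up to three, combined by OR or AND, optionally
   restricted by function class or extended with gene-level CNV calls
   from SEG-style segments: ≥ 10 probes, |segment mean| > 0.2).
2. **ROC screen.** For every gene g compute the rank-based AUC of its
   expression against the pattern,
   `AUC_g = P(x_g,mut > x_g,wt) + ½·P(tie)`, and the z-score
   `z_g = (AUC_g − ½)/se₀` with `se₀ = √((n₁+n₀+1)/(12 n₁ n₀))`, the
   exact permutation SD of the AUC under the null. Genes with
   `AUC ≥ 0.65` and two-sided normal `p ≤ 0.01` form the upregulated
   fingerprint; `AUC ≤ 0.35` the downregulated one. Fewer than 7
   mutated samples ⇒ the analysis is reported NA.
3. **Metagene survival.** Each fingerprint is averaged into a per-sample
   metagene in the validation cohort (log2(x+1) scale by default), the
   cohort is split at the median, and the high-vs-low contrast is fit
   with a single-covariate Cox model plus Kaplan-Meier curves. The two
   hazard ratios fold into `average HR = mean(max(HR_up, HR_down),
   1/min(HR_up, HR_down))`; the gene is called prognostic when
   average HR > 1.4 and each signature's Cox p ≤ 0.05.

Robustness machinery mirrors the validation studies of the approach:
random-gene permutation runs with `FPR = FP/(FP+TN)` bookkeeping against
an expected density of genuinely cancer-linked genes, repeated 20%
random holdout of training samples, and per-sample Spearman concordance
between expression platforms. A synthetic paired-cohort generator with
planted ground truth makes all of it testable end to end.

## Worked example

```bash
python examples/run_pipeline.py
```

```
driver gene:        G0001
mutated / wildtype: 42 / 158 training samples
fingerprint:        50 up + 51 down genes (AUC >= 0.65, p <= 0.01)
up-signature HR:    2.16  (p = 4.02e-15)
down-signature HR:  0.61  (p = 4.44e-07)
average HR:         1.896
significant:        True
```

The generator planted a driver mutated in ~20% of 200 training samples,
shifting 50 genes up and 50 down by one SD, with the validation cohort's
hazard tied to the true up-metagene (log-hazard 0.7 per SD). The screen
recovers the fingerprint almost exactly; high up-metagene predicts worse
survival (HR 2.16) while high down-metagene is protective (HR 0.61) —
the inverse-correlation pattern of a genuine driver — and the average HR
of 1.90 clears the 1.4 threshold.

Other examples: `permutation_fpr.py` (null-universe FPR study),
`holdout_stability.py` (driver vs high-prevalence passenger),
`platform_concordance.py`, `variant_and_cnv_filtering.py`.

The same pipeline is scriptable from the shell:

```bash
g2o simulate --seed 5 --out demo/
g2o run --genes G0001 --expr-ngs demo/expr_ngs.tsv --expr-chip demo/expr_chip.tsv \
        --clinical demo/clinical.tsv --mutations demo/mutations.tsv --out demo/result/
g2o permute ... ; g2o holdout ... ; g2o concordance --a x.tsv --b y.tsv
```

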
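# Methods

## Model and procedure

`g2o` links genotype to outcome through a surrogate expression
signature. The underlying assumption is that a driver mutation perturbs
a network of downstream genes, so its presence leaves a reproducible
multigene trace ("transcriptomic fingerprint") in the tumor
transcriptome; that trace can be measured in cohorts that lack
genotypes but have survival follow-up.

The pipeline has three stages, each an importable module:

1. **genotype** — somatic calls are accepted when the caller judgment is
   `KEEP`, at least 4 reads support the variant, and coverage is at
   least 20× (inclusive thresholds; the deliberately permissive support
   cutoff tolerates subclonal variants). Copy-number segments qualify
   with ≥ 10 probes and segment mean strictly above 0.2 (amplified) or
   strictly below −0.2 (deleted); classified segments are mapped to
   genes by any-overlap of 1-based inclusive intervals. The binary
   mutation pattern marks samples with ≥ 1 retained call in the selected
   gene(s); up to three genes combine by OR (default) or AND, and the
   function-class presets `altered` (start gain, exon, splice site,
   non-synonymous coding, stop gain, stop loss) and `silent` (intron,
   synonymous coding) support contrasting consequential vs neutral
   alterations. CNV calls merge into the pattern only on request.
2. **fingerprint** — per gene, the rank-based AUC of expression against
   the pattern (midrank tie credit), `z = (AUC − ½)/se₀` with
   `se₀ = √((n₁+n₀+1)/(12 n₁ n₀))`, and a two-sided normal p-value.
   `se₀` is the Hanley–McNeil standard error evaluated at AUC = ½,
   which equals the exact tie-free permutation SD of the AUC — so a
   brute-force permutation enumeration can test the implementation
   exactly, and the normal approximation of the p-value can be checked
   against the exact Mann-Whitney null distribution. Gates: AUC ≥ 0.65
   and p ≤ 0.01 (up), AUC ≤ 0.35 and p ≤ 0.01 (down); both exposed
   (sensible ranges 0.6–0.75 and 0.05–0.0001). No multiple-testing
   correction: the raw-p gate works jointly with the AUC effect-size
   floor, and the permutation study quantifies the resulting
   false-positive rate empirically. Patterns with fewer than 7 mutated
   samples return an NA result rather than an underpowered verdict.
3. **survival** — metagene = mean expression of a fingerprint over the
   validation cohort, on log2(x+1) scale by default (a linear-scale mean
   of chip intensities would be dominated by the few most highly
   expressed genes; raw-scale averaging is available via
   `log_transform=False` / `G2OConfig.log_transform_chip`). Median
   dichotomization sends ties to the low group, so "high" means
   strictly above the median. The high-vs-low contrast is fit with a
   single-covariate Cox model and summarized with Kaplan-Meier curves;
   `average HR = mean(max(HR_up, HR_down), 1/min(HR_up, HR_down))`
   (≥ 1 by construction; with one signature absent, `max(h, 1/h)`).
   Verdict: significant iff average HR > 1.4 and every available
   signature p ≤ 0.05. The verdict uses both p-values when both
   signatures exist — a prognostic driver should show the inverse
   pattern on both sides, and requiring both is the stricter, more
   reproducible reading. Training samples never enter the survival fit.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_alt`, `min_cov` | 4, 20 | somatic-call support thresholds (reads, fold-coverage) |
| `min_probes`, `amp_thresh`, `del_thresh` | 10, 0.2, −0.2 | CNV segment gates (probes; log-ratio) |
| `auc_min`, `p_max` | 0.65, 0.01 | ROC fingerprint gates |
| `min_mutated` | 7 | below this the verdict is NA, not negative |
| `hr_min`, `surv_p_max` | 1.4, 0.05 | survival significance gates |
| `holdout_fraction`, `n_reps` | 0.2, 10 | holdout study design |
| `k_runs`, `genes_per_run` | 100, 100 | permutation study design |
| known-positive density | 571/10 000 | expected genuinely cancer-linked fraction in random draws |

## Statistical and numerical choices

* **Ties** receive midrank credit in the AUC, making the statistic
  invariant under strictly increasing transforms; RNA-seq inputs
  therefore need no pre-transformation for the screen.
* **Two-sided p-values**, since up- and downregulation are classified
  symmetrically; the AUC p is clamped into (0, 1].
* **Cox fitting** uses lifelines' `CoxPHFitter` (Efron tie correction,
  Wald CI/p — the ecosystem defaults). Complete separation is caught
  and returned as a flagged boundary fit (small ridge penalty) rather
  than an exception. Breslow ties and likelihood-ratio p-values are not
  offered: lifelines implements Efron only, and a second hand-written
  Cox solver solely for a tie-method toggle was judged not worth the
  correctness risk.
* **Median dichotomization** is deterministic (ties low); all-constant
  scores raise rather than silently producing a one-group split.
* **FPR bookkeeping**: per run, expected true positives =
  density × genes-per-run; FP = max(0, observed − expected);
  TN = genes-per-run − expected − FP; FPR = FP/(FP+TN). The clamp means
  runs at or below the expected positive count report FPR 0.
* **Holdout** removes samples from the training cohort only — the one
  place where sample loss changes the fingerprint; the validation
  cohort is treated as fixed. Subsample size is round((1−f)·n).
* **Determinism**: permutation and holdout spawn one independent
  substream per run index from the user seed, so any single run can be
  reproduced in isolation.
* **Subgroup analysis** is a row filter on the clinical table before
  the survival fit (no interaction modelling).

## Synthetic data generator

`generate_paired_cohorts` emulates the paired-cohort study design with
known truth: training genotype ~ Bernoulli(prevalence 0.2, n = 200);
expression of gene g in sample s ~ N(μ_g + shift_g·genotype_s, 1) with
shift ±1 SD for 50 up / 50 down planted genes and per-gene baselines
μ_g ~ N(8, 2) on a log2-like scale; each mutated sample emits one
passing somatic call, plus a few QC-failing rows so the filter is
exercised. The validation cohort (n = 600) draws an independent latent
genotype from the same law; chip intensities are 2^(log-values) so the
pipeline's default log2(x+1) averaging applies; survival times are
exponential with hazard `h₀·exp(0.7·z)` where z is the standardized
true up-metagene, and independent exponential censoring is solved
numerically to yield 30% censoring in expectation. A total of 1000
genes keeps a full end-to-end run around a second while leaving ~900
null genes to exercise the false-positive behaviour of the screen.
Optional knobs: `background_prevalence` gives every non-driver gene an
independent null mutation pattern (needed for meaningful permutation
studies, where random genes must have genotypes at all);
`hazard_on_genotype` ties the hazard to the genotype bit instead of the
metagene, for studying the direct-vs-surrogate contrast.

What the generator does **not** emulate: count-distributed RNA-seq
noise, gene–gene correlation, linkage between mutations, copy-number
coupling, batch effects, molecular subtypes, or non-proportional
hazards. Passing recovery tests therefore show the machinery is
correct under its own assumptions, not that real cohorts of this size
would yield the same power.

## Simulation scales used in the tests

Unit and property tests use reduced cohorts (≈100–300 samples, 250–400
genes). The end-to-end recovery study runs 20 seeds at the standard
conditions above; the null calibration runs 40 seeds with effect size
and hazard coefficient set to 0; permutation-study tests use a few runs
of 10–20 genes on a 250-gene null universe. These sizes were chosen so
the full suite runs in a few minutes on one CPU while keeping binomial
noise well inside the asserted margins.

## Known limitations

* Gene identity is exact string match; cross-platform probe-to-gene
  resolution must happen upstream.
* The single-covariate Cox model carries no clinical covariates and no
  proportional-hazards diagnostics; subgroup filters are the only
  confounder handling.
* The analytic AUC p-value is a normal approximation; for very small
  mutated groups (near the NA cutoff of 7) it is conservative relative
  to the exact permutation p.
* The average-HR rule folds both directions into one number and so
  cannot distinguish a gene whose two signatures agree from one driven
  by a single strong signature; the per-signature results are always
  reported alongside.
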
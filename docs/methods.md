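# Methods

## Scales and transforms

Methylation enters as beta values (methylated fraction, strictly in (0,1))
and is tested on M-values, M = log2(β/(1−β)). The two scales are linked by
a strictly monotone bijection, so effect directions agree; M-values are
preferred for testing because they are unbounded and closer to
homoscedastic near the boundaries. Expression is tested on log2(x+1) and
summarised as linear-scale fold changes.

## Differential methylation and consensus

Per CpG, Welch's unequal-variance t-test on M-values compares tumor vs
adjacent-normal samples; Benjamini–Hochberg FDR is computed within each
dataset across all tested CpGs. The consensus across two datasets keeps a
CpG only if it reaches P_FDR < 0.05 in *both* with the same direction —
the BH correction is deliberately per-dataset, before intersection. A CpG
with zero variance in both groups is assigned p = 1 and flagged rather
than raising. The Welch-on-M test is this package's own stand-in for an
array-specific linear-model pipeline; it makes no probe-level corrections
(no normalisation, no cell-type deconvolution) and treats samples as
independent even when the panel is pair-matched.

## The candidate funnel

Stages compose in discovery order; every threshold is a strict inequality
and every stage can only shrink the candidate set (this monotonicity is a
tested invariant):

1. **meQTL intersection.** A SNP–CpG pair survives only with records in
   both the lung-tissue and blood summary tables at P_FDR < 0.05, the CpG
   in the consensus set, and (by default) the same effect sign in both
   sources. Sign agreement is a configurable flag
   (`FunnelThresholds.require_sign_agreement`): the seven bundled axes all
   show agreement, but whether it was a filter or an observation in the
   original design is not stated, so the package makes it explicit and
   switchable.
2. **Correlation.** Pearson r of CpG M-values against log2(expr+1),
   computed on tumor samples only by default (the bundled r column
   describes tumor coupling); `correlation_samples="all"` switches to the
   full panel. Keep |r| > 0.3 with p < 0.05; the signed r is carried
   forward.
3. **Differential expression.** FC = mean(tumor)/mean(normal) on the
   linear scale, Welch t on log2(x+1), BH across tested genes; keep
   FC > 2 or FC < 0.5 with P_FDR < 0.05.
4. **MAF and LD.** Reference-panel MAF (frequency of the counted allele,
   folded at 0.5) must exceed 0.05. LD is composite r² — squared Pearson
   correlation of unphased dosages — rather than EM-phased haplotype r²:
   it is deterministic, panel-agnostic, and invariant to allele flips.
   Greedy pruning visits SNPs by ascending tissue meQTL p (ties broken
   lexicographically by SNP id) and keeps a SNP iff r² < 0.80 against all
   SNPs already kept, so each correlated cluster is represented by its
   strongest meQTL.

`run_funnel` emits a `FunnelReport` of per-stage in/out counts mirroring
the stage order above.

## Association

Case status is regressed on allele dosage (0/1/2 copies of the variant —
always the second allele of the `ref>variant` string, even if its
frequency exceeds 0.5 in a stratum) by maximum-likelihood logistic
regression (Newton iterations, tolerance 1e−10), optionally with
standardized covariates (age by default). OR = e^b, 95% CI = e^(b±1.96·SE)
(Wald, symmetric on the log scale — matching how GWAS tables print CIs),
two-sided Wald p. Perfect separation returns a flagged sentinel result
(NaN OR, CI (0, ∞)) instead of silent numbers. At the candidate stage the
retention rule is raw p < 0.05 with no multiplicity correction, matching
the discovery design; BH-FDR across the tested candidates is attached for
display only. Population-structure adjustment (principal components) and
imputation uncertainty are out of scope.

## Plausibility classifier

The classifier is restricted to the classical negative-regulation model:
promoter hypermethylation silences the gene. Rule 1 (negative
regulation): r < 0 *and* the tumor methylation and expression calls point
in opposite directions. Rule 2 (risk concordance), reasoning from the
allele first: if the variant shifts methylation toward the tumor-like
methylation level (sign '+' with tumor methylation High, or '−' with
Low), the axis predicts OR > 1, otherwise OR < 1; the observed odds-ratio
side must match. Overall = Rule 1 ∧ Rule 2. Axes with positive r fail
Rule 1 rather than being evaluated under a mirrored positive-regulation
model — on the bundled table this yields exactly 2 passes and 5 failures.
"Tumor-like" is defined by the methylation call, not expression, because
the causal chain is read allele → methylation first. OR exactly 1 is
flagged indeterminate (and fails). The classifier assumes OR significance
was imposed upstream, and does not re-impose significance on r (it was
already filtered in the funnel).

## Burden (joint effect)

`co_methylation_set` collects CpGs that are significantly hypermethylated
and correlate with an anchor CpG above a threshold (default r > 0.5 on the
beta scale; the anchor is always included, with a warning if it is not
itself hypermethylated). How a subject "carries" a hypermethylated site is
not a standard quantity; the convention here is **beta > normal mean +
k·sd with k = 1**, thresholds estimated per CpG from the normal panel
only. Burden is the count of such CpGs; default grouping for a 7-site set
is {0}, {1–3}, {4–6}, {7}, with arbitrary partitions accepted. Each group
is compared with the zero group by a two-sided Mann-Whitney U; Spearman
correlation of burden vs expression is the trend measure. By default the
tested samples are the tumor panel (normals supply only thresholds); the
combined panel is equally valid and used in one example.

## Synthetic cohorts

The generator's defaults encode the study composition the pipeline is
aimed at: 3453 cases / 3710 controls in the association cohort and a
455-tumor / 32-normal tissue panel. Tissue and cohort populations are
generated inside one object but are disjoint sample sets, mirroring the
separation of the discovery (tissue) and association (GWAS) populations.

* **Genotypes.** Per SNP, Hardy–Weinberg genotypes from two independent
  haplotypes. LD blocks use a first-order autoregressive copier: within a
  block each haplotype allele copies its left neighbour with probability
  `ld_rho`, else is redrawn at the block MAF, giving adjacent-pair dosage
  correlation ≈ ld_rho. MAF is drawn once per block (uniform in
  `maf_range`) because the copier preserves marginals only when
  neighbours share a frequency.
* **Methylation.** CpG M-value = baseline + meqtl_beta·dosage +
  tumor_meth_shift·1[tumor] + N(0, noise_sd_m), mapped to beta by the
  logistic link — effects live on the M scale so betas stay inside (0,1)
  without clipping. Configs whose expected M at the extreme dosage would
  saturate the beta scale are rejected.
* **Expression.** baseline + meth_expr_slope·(M − baseline_M) + noise,
  floored at 0. The default baseline (3.0) and noise (0.5) are set so
  that a canonical planted axis (slope −1, tumor shift +2 M-units)
  produces a fold change comfortably below 0.5 — i.e. a silencing effect
  a discovery screen would call.
* **Disease.** Case status ~ Bernoulli(logistic(b0 + Σ per_allele_log_or ·
  dosage + b_age·age_std)), with b0 solved numerically so the expected
  case fraction matches the configured case/control mix. Age is uniform
  on [40, 75] and standardized before use — a convention, since no age
  distribution is published for the cohort; age confounding defaults to
  zero (`age_log_or`).

What the generator does **not** emulate: genome-wide LD maps, array probe
artefacts, cell-type composition, batch effects, population
stratification, or paired tumor/normal correlation within subjects.
Passing tests therefore demonstrate the pipeline's statistical logic
under its own assumptions, not robustness to the failure modes of real
array and GWAS data.

## Numerical and testing choices

* BH-FDR, logistic fits and classical tests go through statsmodels/scipy;
  the test suite cross-checks BH, LD r² and exact Mann-Whitney p-values
  against independent brute-force implementations (step-up definition,
  raw-sum correlation, full enumeration of group assignments).
* Matrix TSVs are read with round-trip float parsing so write→read is
  bit-exact; loaders reject ragged rows, duplicate ids, out-of-range
  betas/dosages and non-numeric cells with the offending cell named.
* Simulation is deterministic per seed (single `numpy` Generator), and
  written cohorts are byte-identical across runs of the same seed.
* Problem sizes in the simulation-based tests (e.g. 500 tumor / 50 normal
  with 2000 background CpGs for funnel recovery; 50 replicates of the
  full 3453/3710 cohort for odds-ratio recovery) were chosen as the
  smallest scales at which the planted effects have essentially full
  power, keeping the default suite fast while still testing the stated
  conditions.

## Known limitations

* The Welch-on-M differential test is a simplification of array
  linear-model pipelines; with very few normals (the default panel has
  32) its variance estimate is noisy.
* Composite LD underestimates haplotype r² when phase matters.
* The plausibility classifier is qualitative — sign logic only, no
  mediation or effect-size coherence check.
* The burden threshold (normal mean + 1 sd) is a convention; results
  should be reported together with k.
* Funnel-stage counts from the original genome-wide inputs
  (51,394 consensus CpGs → 93 meQTLs → 7 significant) are not
  reproducible here: they require the restricted genotype, methylation
  and meQTL datasets. The package instead verifies the funnel's recovery
  and error-control properties on synthetic cohorts.
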
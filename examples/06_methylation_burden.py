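"""Joint effect of co-hypermethylated CpGs on expression.

Simulates a 13-CpG island where 7 sites (an anchor plus 6 partners) are
co-hypermethylated in tumors and jointly silence one gene.  Each tumor's
burden is the count of CpGs above its normal-tissue threshold
(normal mean + 1 sd); expression is compared across burden groups.
"""

from meqaxis import (
    DEFAULT_BINS,
    PlantedAxis,
    SimulationConfig,
    burden_expression_test,
    burden_per_sample,
    co_methylation_set,
    simulate_cohort,
    test_differential_methylation,
)

axes = tuple(
    PlantedAxis(0, i, 0, meqtl_beta=0.0, tumor_meth_shift=1.2,
                meth_expr_slope=-0.15, per_allele_log_or=0.0)
    for i in range(7)
)
config = SimulationConfig(n_cases=2, n_controls=2, n_tumor_tissue=150,
                          n_normal_tissue=150, n_snps=2, n_cpgs=13, n_genes=2,
                          planted_axes=axes, noise_sd_m=0.5, seed=5)
cohort = simulate_cohort(config)
panel = cohort.tissue_samples
meth = cohort.methylation_beta.loc[panel]

diff = test_differential_methylation(meth, cohort.tissue_labels)
comet = co_methylation_set(diff, meth.corr(), anchor="cpg00001", r_threshold=0.3)
print(f"co-methylated set around the anchor: {len(comet.cpg_ids)} of 13 CpGs")

# burden across the whole panel: normals anchor the '0' group, tumors the
# high-burden groups; thresholds come from the normal samples alone
normal = cohort.methylation_beta.loc[cohort.normal_samples]
burden = burden_per_sample(meth, comet, normal)
expr = cohort.expression.loc[panel, "gene001"]

result = burden_expression_test(burden, expr, bins=DEFAULT_BINS)
for b in result.bins:
    p = "(reference)" if b.p_vs_zero is None else f"p vs '0' = {b.p_vs_zero:.2e}"
    print(f"burden {b.label:>3}: n = {b.n:3d}, median expression = "
          f"{b.median_expression:.2f} {p}")
print(f"trend: Spearman rho = {result.spearman_rho:.3f} (p = {result.spearman_p:.2e})")
# Median expression should fall monotonically with burden: the more
# hypermethylated CpGs a tumor carries, the lower the gene's expression.
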
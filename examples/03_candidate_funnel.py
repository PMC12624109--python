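"""Run the whole candidate-axis funnel on a synthetic study.

Three coherent axes are planted among 2000 background CpGs; the funnel
(consensus differential methylation -> meQTL intersection -> methylation-
expression correlation -> differential expression -> MAF -> LD pruning)
should recover exactly the three planted SNP-CpG-gene triples.
"""

import numpy as np

from meqaxis import (
    PlantedAxis,
    SimulationConfig,
    run_funnel,
    simulate_cohort,
    simulate_meqtl_tables,
)

axes = tuple(
    PlantedAxis(snp_index=5 * i, cpg_index=100 * i + 3, gene_index=i,
                meqtl_beta=-0.5, tumor_meth_shift=2.0, meth_expr_slope=-1.0,
                per_allele_log_or=np.log(0.8))
    for i in range(3)
)
config = SimulationConfig(
    n_cases=10, n_controls=10, n_tumor_tissue=500, n_normal_tissue=50,
    n_snps=60, n_cpgs=2000, n_genes=120, planted_axes=axes,
    maf_range=(0.1, 0.4), ld_block_size=5, ld_rho=0.6, seed=11,
)
cohort_a = simulate_cohort(config)
cohort_b = simulate_cohort(SimulationConfig(**{**config.__dict__, "seed": 111}))
meqtl_tissue, meqtl_blood = simulate_meqtl_tables(config, seed=211)

panel = cohort_a.tissue_samples
candidates, report = run_funnel(
    cohort_a.methylation_beta.loc[panel], cohort_a.phenotype.loc[panel, "tissue"],
    cohort_b.methylation_beta.loc[cohort_b.tissue_samples],
    cohort_b.phenotype.loc[cohort_b.tissue_samples, "tissue"],
    meqtl_tissue, meqtl_blood,
    cohort_a.expression.loc[panel], cohort_a.phenotype.loc[panel, "tissue"],
    cohort_a.cpg_gene_map, cohort_a.genotypes.loc[panel],
)

print(report.to_frame().to_string(index=False))
print()
for c in candidates:
    print(f"{c.snp_id} -> {c.cpg_id} -> {c.gene_symbol}: "
          f"r = {c.correlation_r:+.2f}, FC = {c.expr_fold_change:.2f}, "
          f"MAF = {c.maf_reference:.2f}")
# Each surviving line is one SNP-CpG-gene axis: negative r (methylation
# silences the gene) and FC < 0.5 (the gene is down in tumors).
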
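import numpy as np
import pytest

from meqaxis import PlantedAxis, SimulationConfig, load_reported_axes, simulate_cohort


@pytest.fixture(scope="session")
def axes_rows():
    """The bundled seven-axis summary table."""
    return load_reported_axes()


def protective_axes(n=3, spacing_snp=5, spacing_cpg=100):
    """Coherent protective chains: variant lowers methylation, tumors are
    hypermethylated, methylation silences expression, allele is protective."""
    return tuple(
        PlantedAxis(
            snp_index=spacing_snp * i,
            cpg_index=spacing_cpg * i + 3,
            gene_index=i,
            meqtl_beta=-0.5,
            tumor_meth_shift=2.0,
            meth_expr_slope=-1.0,
            per_allele_log_or=np.log(0.8),
        )
        for i in range(n)
    )


def funnel_config(seed, planted=True, n_cpgs=2000):
    """The study conditions used for funnel recovery checks: 500 tumor /
    50 normal tissue samples, 2000 CpGs, 3 planted axes on a background of
    null CpGs."""
    return SimulationConfig(
        n_cases=10,
        n_controls=10,
        n_tumor_tissue=500,
        n_normal_tissue=50,
        n_snps=60,
        n_cpgs=n_cpgs,
        n_genes=120,
        planted_axes=protective_axes(3) if planted else (),
        maf_range=(0.1, 0.4),
        ld_block_size=5,
        ld_rho=0.6,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with a single planted protective axis, shared by
    read-only tests."""
    cfg = SimulationConfig(
        n_cases=300,
        n_controls=300,
        n_tumor_tissue=60,
        n_normal_tissue=40,
        n_snps=12,
        n_cpgs=30,
        n_genes=8,
        planted_axes=(
            PlantedAxis(
                snp_index=0, cpg_index=0, gene_index=0,
                meqtl_beta=-0.5, tumor_meth_shift=2.0,
                meth_expr_slope=-1.0, per_allele_log_or=np.log(0.8),
            ),
        ),
        maf_range=(0.2, 0.4),
        seed=42,
    )
    return cfg, simulate_cohort(cfg)
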
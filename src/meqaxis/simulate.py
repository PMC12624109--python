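"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage can be exercised without restricted genotype or methylation data:

* genotypes drawn under Hardy–Weinberg equilibrium, with linkage
  disequilibrium inside blocks produced by a first-order autoregressive
  haplotype copier (pairwise dosage correlation ~ ``ld_rho`` between
  neighbours);
* "planted" SNP–CpG–gene axes: a per-allele meQTL shift on the CpG's
  M-value, a tumor-vs-normal methylation shift, a linear
  methylation→expression slope (negative for the classical
  promoter-silencing model), and a per-allele log odds ratio on disease;
* two populations in one object, mirroring the separation between a
  tissue discovery panel (paired tumor/adjacent-normal methylation and
  expression) and a case-control association cohort (genotypes, age,
  disease status).

Effects are specified on the M-value scale and carried to the beta scale by
the logistic map, which keeps beta values strictly inside (0,1) without
clipping.  The logistic disease model solves its intercept so the expected
case fraction matches the configured cohort composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import AnnotationRecord, write_annotation, write_matrix
from .scales import beta_to_m, m_to_beta
from .screen import MeqtlRecord

__all__ = [
    "PlantedAxis",
    "SimulationConfig",
    "CohortData",
    "simulate_cohort",
    "simulate_meqtl_tables",
    "write_cohort",
]

# |M| beyond which the beta scale saturates to 0/1 in double precision
_M_SAFE = 40.0


@dataclass(frozen=True)
class PlantedAxis:
    """One planted SNP→CpG→gene→risk chain.

    Signs are independently settable so both internally coherent and
    incoherent axes can be planted (e.g. a protective chain has
    ``meqtl_beta < 0``, ``tumor_meth_shift > 0``, ``meth_expr_slope < 0``,
    ``per_allele_log_or < 0``).
    """

    snp_index: int
    cpg_index: int
    gene_index: int
    meqtl_beta: float  # M-value shift per copy of the variant allele
    tumor_meth_shift: float  # M-value shift in tumor vs normal tissue
    meth_expr_slope: float  # expression units per M-value unit (<0: silencing)
    per_allele_log_or: float  # log odds ratio on disease per variant allele

    def __post_init__(self):
        for name in ("meqtl_beta", "tumor_meth_shift", "meth_expr_slope", "per_allele_log_or"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"PlantedAxis.{name} must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one simulated study.

    Cohort sizes default to the association study's composition (3453
    non-smoking cases, 3710 controls) and the tissue panel to the external
    methylation panel (455 tumor / 32 adjacent normal).
    """

    n_cases: int = 3453
    n_controls: int = 3710
    n_normal_tissue: int = 32
    n_tumor_tissue: int = 455
    n_snps: int = 50
    n_cpgs: int = 200
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.6
    planted_axes: tuple[PlantedAxis, ...] = ()
    baseline_beta_mean: float = 0.5
    noise_sd_m: float = 0.5
    baseline_expression: float = 3.0
    noise_sd_expr: float = 0.5
    age_range: tuple[float, float] = (40.0, 75.0)
    age_log_or: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_normal_tissue", "n_tumor_tissue",
                     "n_snps", "n_cpgs", "n_genes", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 < self.baseline_beta_mean < 1.0):
            raise ValueError("baseline_beta_mean must lie in (0, 1)")
        if self.noise_sd_m < 0 or self.noise_sd_expr < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        planted = tuple(self.planted_axes)
        object.__setattr__(self, "planted_axes", planted)
        for ax in planted:
            if not (0 <= ax.snp_index < self.n_snps):
                raise ValueError(f"planted snp_index {ax.snp_index} out of range")
            if not (0 <= ax.cpg_index < self.n_cpgs):
                raise ValueError(f"planted cpg_index {ax.cpg_index} out of range")
            if not (0 <= ax.gene_index < self.n_genes):
                raise ValueError(f"planted gene_index {ax.gene_index} out of range")
        # expected-value safety: at the extreme dosage the mean M must stay
        # far from beta-scale saturation
        base_m = beta_to_m(self.baseline_beta_mean)
        per_cpg: dict[int, float] = {}
        for ax in planted:
            worst = abs(ax.meqtl_beta) * 2 + abs(ax.tumor_meth_shift)
            per_cpg[ax.cpg_index] = per_cpg.get(ax.cpg_index, 0.0) + worst
        for cpg, worst in per_cpg.items():
            if abs(base_m) + worst > _M_SAFE:
                raise ValueError(
                    f"planted effects on CpG index {cpg} push expected beta outside (0,1)"
                )


@dataclass
class CohortData:
    """Aligned matrices for one simulated study.

    All four matrices share the same sample index.  ``phenotype`` carries
    ``population`` ('cohort' for case-control subjects, 'tissue' for the
    paired tumor/normal panel), ``is_case`` (0/1, NA outside the cohort),
    ``tissue`` ('tumor'/'normal', NA outside the panel) and ``age`` in
    years.
    """

    genotypes: pd.DataFrame
    methylation_beta: pd.DataFrame
    expression: pd.DataFrame
    phenotype: pd.DataFrame
    snp_annotation: list[AnnotationRecord] = field(default_factory=list)
    cpg_annotation: list[AnnotationRecord] = field(default_factory=list)
    cpg_gene_map: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        idx = self.genotypes.index
        for name in ("methylation_beta", "expression", "phenotype"):
            other = getattr(self, name).index
            if len(other) != len(idx) or not (other == idx).all():
                raise ValueError(f"sample index of {name} does not match genotypes")
        beta = self.methylation_beta.to_numpy()
        if not np.all((beta > 0) & (beta < 1)):
            raise ValueError("beta values must lie strictly inside (0,1)")
        geno = self.genotypes.to_numpy()
        if not np.all(np.isin(geno, (0, 1, 2))):
            raise ValueError("genotype dosages must be integral in {0,1,2}")

    # -- convenience selectors ------------------------------------------------
    @property
    def tissue_samples(self) -> pd.Index:
        return self.phenotype.index[self.phenotype["population"] == "tissue"]

    @property
    def tumor_samples(self) -> pd.Index:
        return self.phenotype.index[self.phenotype["tissue"] == "tumor"]

    @property
    def normal_samples(self) -> pd.Index:
        return self.phenotype.index[self.phenotype["tissue"] == "normal"]

    @property
    def cohort_samples(self) -> pd.Index:
        return self.phenotype.index[self.phenotype["population"] == "cohort"]

    @property
    def tissue_labels(self) -> pd.Series:
        return self.phenotype.loc[self.tissue_samples, "tissue"]

    @property
    def case_flags(self) -> pd.Series:
        return self.phenotype.loc[self.cohort_samples, "is_case"].astype(int)


def _simulate_genotypes(config: SimulationConfig, n_samples: int, rng: np.random.Generator):
    """HWE genotypes with AR(1)-copier LD blocks.

    Each block shares one MAF (drawn uniform from ``maf_range``): the copier
    only preserves the marginal allele frequency when neighbours share it.
    Two independent haplotypes per sample are summed into dosages, so the
    pairwise dosage correlation of neighbours is ~``ld_rho``.
    """
    n_snps = config.n_snps
    lo, hi = config.maf_range
    n_blocks = int(np.ceil(n_snps / config.ld_block_size))
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    mafs = np.repeat(block_maf, config.ld_block_size)[:n_snps]

    haplos = np.empty((2, n_samples, n_snps), dtype=np.int8)
    for h in (0, 1):
        for b in range(n_blocks):
            start = b * config.ld_block_size
            stop = min(start + config.ld_block_size, n_snps)
            p = block_maf[b]
            block = np.empty((n_samples, stop - start), dtype=np.int8)
            block[:, 0] = rng.random(n_samples) < p
            for j in range(1, stop - start):
                copy = rng.random(n_samples) < config.ld_rho
                fresh = (rng.random(n_samples) < p).astype(np.int8)
                block[:, j] = np.where(copy, block[:, j - 1], fresh)
            haplos[h, :, start:stop] = block
    dosages = haplos.sum(axis=0).astype(np.int64)
    return dosages, mafs, haplos


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Draw one full study (tissue panel + case-control cohort).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_cohort = config.n_cases + config.n_controls
    n_tissue = config.n_tumor_tissue + config.n_normal_tissue
    n = n_cohort + n_tissue
    samples = pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id")

    dosages, mafs, _ = _simulate_genotypes(config, n, rng)
    snp_ids = [f"snp{i + 1:04d}" for i in range(config.n_snps)]
    cpg_ids = [f"cpg{i + 1:05d}" for i in range(config.n_cpgs)]
    gene_ids = [f"gene{i + 1:03d}" for i in range(config.n_genes)]

    population = np.array(["cohort"] * n_cohort + ["tissue"] * n_tissue)
    tissue = np.array(
        [_NAS] * n_cohort
        + ["tumor"] * config.n_tumor_tissue
        + ["normal"] * config.n_normal_tissue
    )
    is_tumor = (tissue == "tumor").astype(float)
    age = rng.uniform(*config.age_range, size=n)
    age_std = (age - age.mean()) / age.std(ddof=0)

    # methylation: M = baseline + planted effects + noise, then beta scale
    base_m = beta_to_m(config.baseline_beta_mean)
    m = np.full((n, config.n_cpgs), base_m)
    for ax in config.planted_axes:
        m[:, ax.cpg_index] += ax.meqtl_beta * dosages[:, ax.snp_index]
        m[:, ax.cpg_index] += ax.tumor_meth_shift * is_tumor
    m += rng.normal(0.0, config.noise_sd_m, size=m.shape)
    beta = np.clip(m_to_beta(m), np.nextafter(0, 1), np.nextafter(1, 0))

    # expression: baseline + slope * M(target CpG) + noise, floored at 0
    expr = np.full((n, config.n_genes), config.baseline_expression)
    for ax in config.planted_axes:
        expr[:, ax.gene_index] += ax.meth_expr_slope * (m[:, ax.cpg_index] - base_m)
    expr += rng.normal(0.0, config.noise_sd_expr, size=expr.shape)
    expr = np.maximum(expr, 0.0)

    # disease status on the cohort: intercept solved so the expected case
    # fraction matches n_cases / (n_cases + n_controls)
    eta = np.zeros(n_cohort)
    for ax in config.planted_axes:
        eta += ax.per_allele_log_or * dosages[:n_cohort, ax.snp_index]
    eta += config.age_log_or * age_std[:n_cohort]
    target = config.n_cases / n_cohort
    b0 = brentq(lambda b: expit(b + eta).mean() - target, -30.0, 30.0)
    p_case = expit(b0 + eta)
    is_case = np.full(n, np.nan)
    is_case[:n_cohort] = (rng.random(n_cohort) < p_case).astype(float)

    phenotype = pd.DataFrame(
        {
            "population": population,
            "is_case": is_case,
            "tissue": tissue,
            "age": age,
        },
        index=samples,
    )
    phenotype["tissue"] = phenotype["tissue"].replace(_NAS, np.nan)

    # annotation: features laid out on one synthetic contig, evenly spaced
    planted_gene = {ax.cpg_index: ax.gene_index for ax in config.planted_axes}
    cpg_gene_map = {
        cpg_ids[i]: gene_ids[planted_gene.get(i, i % config.n_genes)]
        for i in range(config.n_cpgs)
    }
    alleles = ["AC", "AG", "AT", "CG", "CT", "GT"]
    snp_ann = [
        AnnotationRecord(
            feature_id=snp_ids[i],
            chromosome="chrS",
            position=10_000 + 1_000 * i,
            alleles=f"{alleles[i % 6][0]}>{alleles[i % 6][1]}",
        )
        for i in range(config.n_snps)
    ]
    cpg_ann = [
        AnnotationRecord(
            feature_id=cpg_ids[i],
            chromosome="chrS",
            position=10_500 + 1_000 * i,
            gene_symbol=cpg_gene_map[cpg_ids[i]],
        )
        for i in range(config.n_cpgs)
    ]

    cohort = CohortData(
        genotypes=pd.DataFrame(dosages, index=samples, columns=snp_ids),
        methylation_beta=pd.DataFrame(beta, index=samples, columns=cpg_ids),
        expression=pd.DataFrame(expr, index=samples, columns=gene_ids),
        phenotype=phenotype,
        snp_annotation=snp_ann,
        cpg_annotation=cpg_ann,
        cpg_gene_map=cpg_gene_map,
    )
    cohort.validate()
    return cohort


_NAS = "NA"


def simulate_meqtl_tables(
    config: SimulationConfig,
    seed: int,
    n_decoy_pairs: int = 20,
    n_sign_clash_pairs: int = 3,
    n_single_source_pairs: int = 3,
) -> tuple[list[MeqtlRecord], list[MeqtlRecord]]:
    """Build synthetic tissue and blood meQTL summary tables.

    Planted axes appear in both sources with the sign of their true
    M-scale effect and a strong p-value.  Decoy pairs link non-planted SNPs
    to non-planted CpGs, also at strong p, to exercise the downstream
    filters; clash pairs disagree in sign between the two sources, and
    single-source pairs appear only in tissue.
    """
    rng = np.random.default_rng(seed)
    snp_ids = [f"snp{i + 1:04d}" for i in range(config.n_snps)]
    cpg_ids = [f"cpg{i + 1:05d}" for i in range(config.n_cpgs)]
    planted_snp = {ax.snp_index for ax in config.planted_axes}
    planted_cpg = {ax.cpg_index for ax in config.planted_axes}

    def strong_p():
        return float(10.0 ** rng.uniform(-12.0, -6.0))

    tissue: list[MeqtlRecord] = []
    blood: list[MeqtlRecord] = []
    for ax in config.planted_axes:
        sign = "+" if ax.meqtl_beta > 0 else "-"
        for source, out in (("tissue", tissue), ("blood", blood)):
            p = strong_p()
            out.append(MeqtlRecord(snp_ids[ax.snp_index], cpg_ids[ax.cpg_index],
                                   sign, p, min(1.0, p * 5), source))

    free_snps = [i for i in range(config.n_snps) if i not in planted_snp]
    free_cpgs = [i for i in range(config.n_cpgs) if i not in planted_cpg]
    n_extra = n_decoy_pairs + n_sign_clash_pairs + n_single_source_pairs
    snp_pick = rng.choice(free_snps, size=min(n_extra, len(free_snps)), replace=False)
    cpg_pick = rng.choice(free_cpgs, size=min(n_extra, len(free_cpgs)), replace=False)
    for k, (si, ci) in enumerate(zip(snp_pick, cpg_pick)):
        sign = "+" if rng.random() < 0.5 else "-"
        p1, p2 = strong_p(), strong_p()
        rec_t = MeqtlRecord(snp_ids[si], cpg_ids[ci], sign, p1, min(1.0, p1 * 5), "tissue")
        tissue.append(rec_t)
        if k < n_decoy_pairs:
            blood.append(MeqtlRecord(snp_ids[si], cpg_ids[ci], sign, p2, min(1.0, p2 * 5), "blood"))
        elif k < n_decoy_pairs + n_sign_clash_pairs:
            other = "-" if sign == "+" else "+"
            blood.append(MeqtlRecord(snp_ids[si], cpg_ids[ci], other, p2, min(1.0, p2 * 5), "blood"))
        # else: tissue-only pair
    return tissue, blood


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write the four matrices plus SNP/CpG annotation as TSV.

    Byte-identical for byte-identical inputs: pandas' shortest-roundtrip
    float formatting is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.genotypes, outdir / "genotypes.tsv")
    write_matrix(cohort.methylation_beta, outdir / "methylation.tsv")
    write_matrix(cohort.expression, outdir / "expression.tsv")
    cohort.phenotype.to_csv(outdir / "phenotype.tsv", sep="\t", index_label="sample_id", na_rep="NA")
    write_annotation(cohort.snp_annotation, outdir / "snp_annotation.tsv")
    write_annotation(cohort.cpg_annotation, outdir / "cpg_annotation.tsv")
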
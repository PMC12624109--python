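"""The candidate-axis funnel: meQTL intersection, methylation–expression
correlation, differential expression, MAF and LD filters.

Stages compose in the discovery order: (1) consensus differentially
methylated CpGs are intersected with meQTL summary tables from two sources
(lung tissue and blood), requiring FDR significance in both and, by default,
agreement of the meQTL effect sign between sources; (2) CpG M-values must
correlate with their target gene's log2 expression in tumor samples
(|r| > 0.3, p < 0.05); (3) the gene must be differentially expressed
(FC > 2 or FC < 0.5 at BH-FDR < 0.05); (4) SNPs must be common
(reference-panel MAF > 0.05) and (5) pairwise LD r² < 0.80 after greedy
pruning that keeps the smallest tissue-meQTL p per correlated cluster.

All thresholds are strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scales import beta_to_m

__all__ = [
    "MeqtlRecord",
    "AxisCandidate",
    "FunnelStage",
    "FunnelReport",
    "FunnelThresholds",
    "intersect_meqtl",
    "correlation_filter",
    "expression_filter",
    "ld_r2",
    "ld_prune",
    "run_funnel",
]


@dataclass(frozen=True)
class MeqtlRecord:
    """One SNP–CpG association from a meQTL summary table."""

    snp_id: str
    cpg_id: str
    beta_sign: str  # '+' : variant allele raises methylation; '-' : lowers
    p_value: float
    p_fdr: float
    source: str  # 'tissue' or 'blood'

    def __post_init__(self):
        if self.beta_sign not in {"+", "-"}:
            raise ValueError(f"beta_sign must be '+' or '-', got {self.beta_sign!r}")
        if self.source not in {"tissue", "blood"}:
            raise ValueError(f"source must be 'tissue' or 'blood', got {self.source!r}")
        if self.p_fdr < self.p_value:
            raise ValueError(f"{self.snp_id}-{self.cpg_id}: p_fdr < p_value")


@dataclass(frozen=True)
class AxisCandidate:
    """One SNP–CpG–gene triple with the statistics collected along the funnel."""

    snp_id: str
    cpg_id: str
    gene_symbol: str | None = None
    beta_sign_tissue: str | None = None
    beta_sign_blood: str | None = None
    meqtl_p_tissue: float | None = None
    meqtl_p_blood: float | None = None
    correlation_r: float | None = None
    correlation_p: float | None = None
    expr_fold_change: float | None = None
    expr_p_fdr: float | None = None
    maf_reference: float | None = None
    survived_ld: bool = False


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    threshold: str

    def __post_init__(self):
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.name}: items out ({self.n_out}) exceed items in ({self.n_in})")


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, threshold: str) -> None:
        self.stages.append(FunnelStage(name, n_in, n_out, threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out, s.threshold) for s in self.stages],
            columns=["stage", "items_in", "items_out", "threshold"],
        )


@dataclass(frozen=True)
class FunnelThresholds:
    meqtl_fdr: float = 0.05
    require_sign_agreement: bool = True
    r_threshold: float = 0.3
    r_p_threshold: float = 0.05
    fc_low: float = 0.5
    fc_high: float = 2.0
    expr_fdr: float = 0.05
    maf_threshold: float = 0.05
    r2_threshold: float = 0.8
    correlation_samples: str = "tumor"  # or "all"


def intersect_meqtl(
    consensus_cpgs,
    records: list[MeqtlRecord],
    fdr_threshold: float = 0.05,
    require_sign_agreement: bool = True,
) -> list[AxisCandidate]:
    """Keep SNP–CpG pairs whose CpG is in the consensus set and that pass
    meQTL FDR in both tissue and blood (sign agreement optional, default on).

    ``consensus_cpgs`` may be a ConsensusResult, a set of CpG ids, or a set
    of (cpg_id, direction) pairs.  Pairs present in one source only are
    excluded.
    """
    if hasattr(consensus_cpgs, "cpg_ids"):
        cpg_set = set(consensus_cpgs.cpg_ids)
    else:
        cpg_set = {c[0] if isinstance(c, tuple) else c for c in consensus_cpgs}

    by_pair: dict[tuple[str, str], dict[str, MeqtlRecord]] = {}
    for rec in records:
        by_pair.setdefault((rec.snp_id, rec.cpg_id), {})[rec.source] = rec

    out = []
    for (snp, cpg), sources in sorted(by_pair.items()):
        if cpg not in cpg_set:
            continue
        t, b = sources.get("tissue"), sources.get("blood")
        if t is None or b is None:
            continue  # single-source evidence is not enough
        if t.p_fdr >= fdr_threshold or b.p_fdr >= fdr_threshold:
            continue
        if require_sign_agreement and t.beta_sign != b.beta_sign:
            continue
        out.append(
            AxisCandidate(
                snp_id=snp,
                cpg_id=cpg,
                beta_sign_tissue=t.beta_sign,
                beta_sign_blood=b.beta_sign,
                meqtl_p_tissue=t.p_value,
                meqtl_p_blood=b.p_value,
            )
        )
    return out


def correlation_filter(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: list[AxisCandidate],
    cpg_to_gene: dict[str, str],
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    samples=None,
) -> list[AxisCandidate]:
    """Pearson correlation of CpG M-values against log2(expression+1).

    Computed across ``samples`` (typically tumor samples present in both
    matrices); keeps |r| > r_threshold and p < p_threshold, strict.  The
    signed r is recorded on the candidate.
    """
    if samples is None:
        samples = methylation.index.intersection(expression.index)
    else:
        samples = pd.Index(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples for correlation")

    out = []
    for cand in pairs:
        gene = cpg_to_gene.get(cand.cpg_id)
        if gene is None or gene not in expression.columns or cand.cpg_id not in methylation.columns:
            warnings.warn(f"{cand.cpg_id}: no mapped gene in the expression matrix; dropped", stacklevel=2)
            continue
        m = beta_to_m(methylation.loc[samples, cand.cpg_id].to_numpy())
        e = np.log2(expression.loc[samples, gene].to_numpy() + 1.0)
        if np.ptp(e) == 0 or np.ptp(m) == 0:
            warnings.warn(f"{cand.cpg_id}-{gene}: constant vector; pair dropped", stacklevel=2)
            continue
        r, p = stats.pearsonr(m, e)
        if abs(r) > r_threshold and p < p_threshold:
            out.append(replace(cand, gene_symbol=gene, correlation_r=float(r), correlation_p=float(p)))
    return out


def expression_filter(
    expression: pd.DataFrame,
    tissue_labels,
    genes=None,
    fc_low: float = 0.5,
    fc_high: float = 2.0,
    fdr_threshold: float = 0.05,
) -> dict[str, tuple[float, float, str]]:
    """Tumor-vs-normal differential expression per gene.

    Fold change is mean(tumor)/mean(normal) on the linear scale; the test is
    Welch t on log2(expression+1), BH-corrected across the tested genes.
    Returns ``{gene: (fc, p_fdr, direction)}`` for genes kept by
    FC > fc_high or FC < fc_low with p_fdr < threshold; direction is High
    iff FC > 1.
    """
    labels = pd.Series(np.asarray(tissue_labels), index=expression.index)
    if genes is None:
        genes = list(expression.columns)
    else:
        genes = [g for g in genes if g in expression.columns]
    if not genes:
        return {}
    tumor = expression.loc[labels == "tumor", genes]
    normal = expression.loc[labels == "normal", genes]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need at least 2 tumor and 2 normal samples")

    mean_t = tumor.mean(axis=0).to_numpy()
    mean_n = normal.mean(axis=0).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(
            np.log2(tumor.to_numpy() + 1.0), np.log2(normal.to_numpy() + 1.0),
            axis=0, equal_var=False,
        )
    p = np.where(np.isfinite(p), p, 1.0)
    p_fdr = multipletests(p, method="fdr_bh")[1]

    kept: dict[str, tuple[float, float, str]] = {}
    for j, gene in enumerate(genes):
        if mean_n[j] == 0:
            warnings.warn(f"{gene}: zero normal-group mean, fold change undefined; dropped", stacklevel=2)
            continue
        fc = mean_t[j] / mean_n[j]
        if (fc > fc_high or fc < fc_low) and p_fdr[j] < fdr_threshold:
            kept[gene] = (float(fc), float(p_fdr[j]), "High" if fc > 1 else "Low")
    return kept


def ld_r2(a, b, snp_a: str = "a", snp_b: str = "b") -> float:
    """Composite LD: squared Pearson correlation of genotype dosages.

    Invariant to allele flips (dosage -> 2 - dosage).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("dosage vectors must be 1-D, equal length >= 3")
    if np.var(a) == 0:
        raise ValueError(f"SNP {snp_a!r} has zero dosage variance")
    if np.var(b) == 0:
        raise ValueError(f"SNP {snp_b!r} has zero dosage variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    candidates: list[AxisCandidate],
    reference_genotypes: pd.DataFrame,
    maf_threshold: float = 0.05,
    r2_threshold: float = 0.8,
) -> tuple[list[AxisCandidate], list[str], list[FunnelStage]]:
    """MAF gate then greedy LD pruning on the candidate SNPs.

    Reference-panel MAF (minor-allele frequency of the counted allele,
    folded at 0.5) must exceed ``maf_threshold``.  Remaining SNPs are
    visited by ascending tissue meQTL p (ties broken by SNP id) and kept iff
    r² < ``r2_threshold`` against every SNP already kept — deterministic,
    and each correlated cluster is represented by its smallest-p SNP.

    Returns (pruned candidates, missing-SNP exclusion list, report stages).
    """
    missing = sorted({c.snp_id for c in candidates} - set(reference_genotypes.columns))
    present = [c for c in candidates if c.snp_id not in missing]

    freqs = {
        snp: float(reference_genotypes[snp].mean() / 2.0)
        for snp in {c.snp_id for c in present}
    }
    maf = {snp: min(f, 1.0 - f) for snp, f in freqs.items()}
    after_maf = [replace(c, maf_reference=maf[c.snp_id]) for c in present if maf[c.snp_id] > maf_threshold]

    order = sorted(
        {c.snp_id for c in after_maf},
        key=lambda s: (min(c.meqtl_p_tissue if c.meqtl_p_tissue is not None else np.inf
                           for c in after_maf if c.snp_id == s), s),
    )
    kept_snps: list[str] = []
    for snp in order:
        g = reference_genotypes[snp].to_numpy()
        if all(ld_r2(g, reference_genotypes[k].to_numpy(), snp, k) < r2_threshold for k in kept_snps):
            kept_snps.append(snp)
    kept_set = set(kept_snps)
    pruned = [replace(c, survived_ld=True) for c in after_maf if c.snp_id in kept_set]

    stages = [
        FunnelStage("maf_filter", len(present), len(after_maf), f"MAF > {maf_threshold}"),
        FunnelStage("ld_prune", len(after_maf), len(pruned), f"r2 < {r2_threshold}"),
    ]
    return pruned, missing, stages


def run_funnel(
    meth_a: pd.DataFrame,
    labels_a,
    meth_b: pd.DataFrame,
    labels_b,
    meqtl_tissue: list[MeqtlRecord],
    meqtl_blood: list[MeqtlRecord],
    expression: pd.DataFrame,
    expr_labels,
    cpg_to_gene: dict[str, str],
    reference_genotypes: pd.DataFrame,
    thresholds: FunnelThresholds = FunnelThresholds(),
) -> tuple[list[AxisCandidate], FunnelReport]:
    """Compose the funnel stages in discovery order and report counts.

    Datasets A and B are the two tumor/normal methylation panels used for
    the consensus; correlation and differential expression use dataset A's
    samples shared with the expression matrix.
    """
    from .diffmeth import consensus_sites, test_differential_methylation

    report = FunnelReport()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_a = test_differential_methylation(meth_a, labels_a)
        res_b = test_differential_methylation(meth_b, labels_b)
        consensus = consensus_sites(res_a, res_b, fdr_threshold=thresholds.meqtl_fdr)
    n_cpgs = len({r.cpg_id for r in res_a} | {r.cpg_id for r in res_b})
    report.add("consensus_diff_methylation", n_cpgs, len(consensus.sites),
               f"p_fdr < {thresholds.meqtl_fdr} in both, same direction")

    all_records = list(meqtl_tissue) + list(meqtl_blood)
    n_pairs = len({(r.snp_id, r.cpg_id) for r in all_records})
    pairs = intersect_meqtl(
        consensus, all_records,
        fdr_threshold=thresholds.meqtl_fdr,
        require_sign_agreement=thresholds.require_sign_agreement,
    )
    report.add("meqtl_intersection", n_pairs, len(pairs),
               f"meQTL p_fdr < {thresholds.meqtl_fdr} in tissue and blood"
               + (", signs agree" if thresholds.require_sign_agreement else ""))

    labels_a = pd.Series(np.asarray(labels_a), index=meth_a.index)
    if thresholds.correlation_samples == "tumor":
        corr_samples = meth_a.index[labels_a == "tumor"].intersection(expression.index)
    else:
        corr_samples = meth_a.index.intersection(expression.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr_pairs = correlation_filter(
            meth_a, expression, pairs, cpg_to_gene,
            r_threshold=thresholds.r_threshold, p_threshold=thresholds.r_p_threshold,
            samples=corr_samples,
        )
    report.add("methylation_expression_correlation", len(pairs), len(corr_pairs),
               f"|r| > {thresholds.r_threshold}, p < {thresholds.r_p_threshold}")

    genes = sorted({c.gene_symbol for c in corr_pairs})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = expression_filter(
            expression, expr_labels, genes=genes,
            fc_low=thresholds.fc_low, fc_high=thresholds.fc_high,
            fdr_threshold=thresholds.expr_fdr,
        )
    de_pairs = [
        replace(c, expr_fold_change=de[c.gene_symbol][0], expr_p_fdr=de[c.gene_symbol][1])
        for c in corr_pairs
        if c.gene_symbol in de
    ]
    report.add("differential_expression", len(corr_pairs), len(de_pairs),
               f"FC > {thresholds.fc_high} or FC < {thresholds.fc_low}, p_fdr < {thresholds.expr_fdr}")

    pruned, missing, stages = ld_prune(
        de_pairs, reference_genotypes,
        maf_threshold=thresholds.maf_threshold, r2_threshold=thresholds.r2_threshold,
    )
    if missing:
        warnings.warn(f"SNPs missing from the reference panel: {missing}", stacklevel=2)
    report.stages.extend(stages)
    return pruned, report
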
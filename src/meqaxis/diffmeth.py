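"""Tumor-vs-normal differential CpG methylation and cross-dataset consensus.

Per CpG, a Welch two-sample t-test on M-values compares tumor against
adjacent-normal samples; beta-scale group means give the reported effect
(delta beta) and direction.  Benjamini–Hochberg FDR is applied within each
dataset, and the consensus keeps CpGs significant with the same direction in
both datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scales import beta_to_m

__all__ = ["DiffMethResult", "ConsensusResult", "test_differential_methylation", "consensus_sites"]


@dataclass(frozen=True)
class DiffMethResult:
    cpg_id: str
    mean_beta_tumor: float
    mean_beta_normal: float
    delta_beta: float
    statistic: float
    p_value: float
    p_fdr: float
    direction: str  # "Hyper" iff delta_beta > 0 else "Hypo"
    zero_variance: bool = False


@dataclass(frozen=True)
class ConsensusResult:
    """CpGs called in the same direction at FDR < threshold in two datasets."""

    sites: frozenset  # of (cpg_id, direction)
    n_hyper: int
    n_hypo: int

    @property
    def cpg_ids(self) -> frozenset:
        return frozenset(cpg for cpg, _ in self.sites)


def test_differential_methylation(methylation: pd.DataFrame, tissue_labels) -> list[DiffMethResult]:
    """Welch t on M-values per CpG, tumor vs normal, BH-FDR across CpGs.

    ``tissue_labels`` is aligned to the matrix rows with values
    'tumor'/'normal'; each group needs at least two samples.  A CpG with
    zero variance in both groups gets p = 1 and is flagged rather than
    raising.
    """
    labels = pd.Series(np.asarray(tissue_labels), index=methylation.index)
    tumor = methylation.loc[labels == "tumor"]
    normal = methylation.loc[labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need at least 2 tumor and 2 normal samples")

    m_tumor = beta_to_m(tumor.to_numpy())
    m_normal = beta_to_m(normal.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 at flat CpGs
        stat, p = stats.ttest_ind(m_tumor, m_normal, axis=0, equal_var=False)
    flat = ~np.isfinite(p)
    stat = np.where(flat, 0.0, stat)
    p = np.where(flat, 1.0, p)
    p_fdr = multipletests(p, method="fdr_bh")[1]

    mean_t = tumor.mean(axis=0).to_numpy()
    mean_n = normal.mean(axis=0).to_numpy()
    delta = mean_t - mean_n
    return [
        DiffMethResult(
            cpg_id=cpg,
            mean_beta_tumor=float(mean_t[j]),
            mean_beta_normal=float(mean_n[j]),
            delta_beta=float(delta[j]),
            statistic=float(stat[j]),
            p_value=float(p[j]),
            p_fdr=float(p_fdr[j]),
            direction="Hyper" if delta[j] > 0 else "Hypo",
            zero_variance=bool(flat[j]),
        )
        for j, cpg in enumerate(methylation.columns)
    ]


def consensus_sites(
    results_a: list[DiffMethResult],
    results_b: list[DiffMethResult],
    fdr_threshold: float = 0.05,
) -> ConsensusResult:
    """Keep CpGs with p_fdr < threshold in BOTH datasets and equal direction.

    Symmetric in its two arguments.  An empty intersection is valid (a
    warning, not an error).
    """
    by_id_b = {r.cpg_id: r for r in results_b}
    sites = set()
    for ra in results_a:
        rb = by_id_b.get(ra.cpg_id)
        if rb is None:
            continue
        if ra.p_fdr < fdr_threshold and rb.p_fdr < fdr_threshold and ra.direction == rb.direction:
            sites.add((ra.cpg_id, ra.direction))
    if not sites:
        warnings.warn("consensus set is empty", stacklevel=2)
    n_hyper = sum(1 for _, d in sites if d == "Hyper")
    return ConsensusResult(sites=frozenset(sites), n_hyper=n_hyper, n_hypo=len(sites) - n_hyper)
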
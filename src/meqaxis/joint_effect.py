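"""Joint (burden) effect of co-hypermethylated CpG sites on expression.

A single promoter CpG usually has a modest effect on transcription, so
neighbouring sites that are hypermethylated together with an anchor CpG are
pooled: each subject's burden is the number of CpGs in the set at which its
beta value exceeds a normal-tissue-derived threshold (normal mean + k·sd,
k = 1 by convention).  Burden groups (default '0', '1–3', '4–6', '7') are
compared against the zero-burden group by two-sided Mann-Whitney U tests,
with a Spearman correlation of burden against expression as the trend
measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoMethylationSet",
    "BurdenTestResult",
    "DEFAULT_BINS",
    "co_methylation_set",
    "burden_per_sample",
    "burden_expression_test",
]

DEFAULT_BINS: tuple[tuple[int, int], ...] = ((0, 0), (1, 3), (4, 6), (7, 7))


@dataclass(frozen=True)
class CoMethylationSet:
    anchor: str
    cpg_ids: tuple[str, ...]  # anchor included, input order preserved
    anchor_hyper: bool  # False: anchor itself was not called Hyper (warned)


@dataclass(frozen=True)
class BinResult:
    label: str
    low: int
    high: int
    n: int
    median_expression: float
    p_vs_zero: float | None  # None for the reference (zero) bin or empty bins


@dataclass(frozen=True)
class BurdenTestResult:
    bins: tuple[BinResult, ...]
    spearman_rho: float
    spearman_p: float
    trend_defined: bool
    skipped_bins: tuple[str, ...] = field(default=())


def co_methylation_set(
    diff_results,
    beta_correlation: pd.DataFrame,
    anchor: str,
    r_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> CoMethylationSet:
    """CpGs co-hypermethylated with the anchor.

    Keeps CpGs called Hyper at p_fdr < fdr_threshold whose beta-value
    correlation with the anchor exceeds ``r_threshold``; the anchor is
    always included.  ``diff_results`` is a list of DiffMethResult limited
    to the CpGs of one island/region; ``beta_correlation`` is their
    correlation matrix.
    """
    by_id = {r.cpg_id: r for r in diff_results}
    if anchor not in by_id:
        raise KeyError(f"anchor CpG {anchor!r} not among the differential results")
    if anchor not in beta_correlation.index:
        raise KeyError(f"anchor CpG {anchor!r} not in the correlation matrix")

    anchor_res = by_id[anchor]
    anchor_hyper = anchor_res.direction == "Hyper" and anchor_res.p_fdr < fdr_threshold
    if not anchor_hyper:
        warnings.warn(f"anchor {anchor} is not significantly hypermethylated", stacklevel=2)

    members = []
    for res in diff_results:
        if res.cpg_id == anchor:
            members.append(anchor)
            continue
        if res.direction != "Hyper" or res.p_fdr >= fdr_threshold:
            continue
        if res.cpg_id not in beta_correlation.columns:
            continue
        if beta_correlation.loc[anchor, res.cpg_id] > r_threshold:
            members.append(res.cpg_id)
    if anchor not in members:
        members.insert(0, anchor)
    return CoMethylationSet(anchor=anchor, cpg_ids=tuple(members), anchor_hyper=anchor_hyper)


def burden_per_sample(
    methylation: pd.DataFrame,
    cpg_set,
    normal_reference: pd.DataFrame,
    k: float = 1.0,
) -> pd.Series:
    """Count, per sample, the CpGs whose beta exceeds normal mean + k·sd.

    ``normal_reference`` holds the adjacent-normal samples (>= 2 per CpG)
    used only to set per-CpG thresholds.
    """
    cpgs = list(cpg_set.cpg_ids) if isinstance(cpg_set, CoMethylationSet) else list(cpg_set)
    for cpg in cpgs:
        if cpg not in methylation.columns:
            raise KeyError(f"CpG {cpg!r} missing from the methylation matrix")
        if cpg not in normal_reference.columns:
            raise KeyError(f"CpG {cpg!r} missing from the normal reference panel")
    if len(normal_reference) < 2:
        raise ValueError("need at least 2 normal reference samples")
    thresholds = normal_reference[cpgs].mean(axis=0) + k * normal_reference[cpgs].std(axis=0, ddof=1)
    hyper = methylation[cpgs].gt(thresholds, axis=1)
    return hyper.sum(axis=1).astype(int)


def _validate_bins(bins, max_burden: int) -> None:
    covered = []
    for low, high in bins:
        if low > high:
            raise ValueError(f"bin ({low},{high}) has low > high")
        covered.extend(range(low, high + 1))
    if sorted(covered) != list(range(max_burden + 1)):
        raise ValueError(f"bins {bins} do not partition 0..{max_burden}")


def burden_expression_test(
    burden: pd.Series,
    expression: pd.Series,
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS,
) -> BurdenTestResult:
    """Per-bin expression medians, Mann-Whitney U vs the zero bin, and the
    Spearman burden-expression trend.

    The first bin is the reference.  Empty bins are reported and skipped;
    if all samples fall in one bin the trend is undefined and flagged.
    """
    burden = pd.Series(np.asarray(burden), index=expression.index)
    _validate_bins(bins, max_burden=max(int(burden.max()), bins[-1][1]))

    ref_low, ref_high = bins[0]
    ref_mask = (burden >= ref_low) & (burden <= ref_high)
    ref_expr = expression[ref_mask]

    results: list[BinResult] = []
    skipped: list[str] = []
    for i, (low, high) in enumerate(bins):
        label = str(low) if low == high else f"{low}-{high}"
        mask = (burden >= low) & (burden <= high)
        vals = expression[mask]
        if len(vals) == 0:
            skipped.append(label)
            results.append(BinResult(label, low, high, 0, float("nan"), None))
            continue
        if i == 0 or len(ref_expr) == 0:
            p = None
        else:
            p = float(stats.mannwhitneyu(vals, ref_expr, alternative="two-sided").pvalue)
        results.append(BinResult(label, low, high, int(mask.sum()), float(vals.median()), p))

    if burden.nunique() < 2:
        warnings.warn("all samples share one burden value; trend undefined", stacklevel=2)
        rho, p_trend, defined = float("nan"), float("nan"), False
    else:
        rho, p_trend = stats.spearmanr(burden, expression)
        rho, p_trend, defined = float(rho), float(p_trend), True

    return BurdenTestResult(
        bins=tuple(results),
        spearman_rho=rho,
        spearman_p=p_trend,
        trend_defined=defined,
        skipped_bins=tuple(skipped),
    )
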
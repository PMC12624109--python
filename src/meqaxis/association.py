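"""Case-control association under the additive genetic model.

Each SNP is coded as the count (0/1/2) of its variant allele and entered
into a maximum-likelihood logistic regression of case status, optionally
adjusted for covariates (the published analysis adjusts for age).  The
per-allele odds ratio, symmetric Wald 95% CI and two-sided Wald p are
reported together with genotype-count summaries and allele frequencies.
Significance at the candidate stage is the raw p < alpha, with BH-FDR
computed for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "maf_from_counts",
    "genotype_counts",
    "expand_counts",
    "fit_additive_logistic",
    "associate_candidates",
]


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    genotype_counts_cases: tuple[int, int, int]
    genotype_counts_controls: tuple[int, int, int]
    maf_cases: float
    maf_controls: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates_used: tuple[str, ...] = ()
    separated: bool = False  # perfect separation: OR/CI are sentinels
    p_fdr: float | None = None  # display only, never used as a filter


def maf_from_counts(counts) -> float:
    """Variant-allele frequency from (hom-ref, het, hom-var) counts.

    (n1 + 2*n2) / (2*(n0+n1+n2)); the counted allele is the second allele
    of the ref>variant string, even if its frequency exceeds 0.5.
    """
    n0, n1, n2 = counts
    if any(c < 0 for c in (n0, n1, n2)):
        raise ValueError("genotype counts must be nonnegative")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("all genotype counts are zero")
    return (n1 + 2 * n2) / (2 * total)


def genotype_counts(dosages) -> tuple[int, int, int]:
    d = np.asarray(dosages)
    return (int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2)))


def expand_counts(counts_cases, counts_controls) -> tuple[np.ndarray, np.ndarray]:
    """Expand two genotype-count triples into dosage and case-flag vectors."""
    dos, flag = [], []
    for is_case, counts in ((1, counts_cases), (0, counts_controls)):
        for dose, n in enumerate(counts):
            dos.extend([dose] * int(n))
            flag.extend([is_case] * int(n))
    return np.asarray(dos, dtype=float), np.asarray(flag, dtype=int)


def fit_additive_logistic(
    dosages,
    case_flags,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "snp",
) -> AssociationResult:
    """ML logistic fit of case status on allele dosage (+ covariates).

    Newton-Raphson to a tight tolerance; OR = exp(coef), 95% CI =
    exp(coef ± 1.96 SE), two-sided Wald p.  Perfect separation yields a
    flagged result with infinite-CI sentinels instead of silent numbers.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(case_flags, dtype=int)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("dosages and case_flags must be aligned 1-D vectors")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one control")
    if np.var(d) == 0:
        raise ValueError(f"SNP {snp_id!r} has zero dosage variance")

    cols = {"dosage": d}
    names: tuple[str, ...] = ()
    if covariates is not None:
        for name in covariates.columns:
            cols[name] = np.asarray(covariates[name], dtype=float)
        names = tuple(covariates.columns)
    X = sm.add_constant(pd.DataFrame(cols), prepend=True)

    cc = genotype_counts(d[y == 1]), genotype_counts(d[y == 0])
    common = dict(
        snp_id=snp_id,
        genotype_counts_cases=cc[0],
        genotype_counts_controls=cc[1],
        maf_cases=maf_from_counts(cc[0]),
        maf_controls=maf_from_counts(cc[1]),
        covariates_used=names,
    )

    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-10, maxiter=100, disp=0)
        if not fit.mle_retvals.get("converged", False):
            raise PerfectSeparationError("Newton did not converge")
        coef = float(fit.params["dosage"])
        se = float(fit.bse["dosage"])
        if not np.isfinite(coef) or not np.isfinite(se):
            raise PerfectSeparationError("non-finite estimate")
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult(
            or_value=np.nan, ci_low=0.0, ci_high=np.inf, p_value=np.nan,
            separated=True, **common,
        )

    return AssociationResult(
        or_value=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p_value=float(2.0 * (1.0 - _norm_cdf(abs(coef / se)))),
        **common,
    )


def _norm_cdf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(z))


def associate_candidates(
    candidates,
    genotypes: pd.DataFrame,
    phenotype: pd.DataFrame,
    alpha: float = 0.05,
    covariate_names: tuple[str, ...] = ("age",),
) -> tuple[list, list[str]]:
    """Fit every candidate SNP; retain raw p < alpha (no multiplicity
    filter, matching the discovery analysis).

    ``phenotype`` needs an ``is_case`` column and any requested covariate
    columns; continuous covariates are standardized before the fit.  BH-FDR
    across the tested candidates is attached for display.  Returns
    (list of (candidate, AssociationResult) kept, missing SNP ids).
    """
    cohort = phenotype.index[phenotype["is_case"].notna()]
    y = phenotype.loc[cohort, "is_case"].astype(int)
    cov = None
    if covariate_names:
        cov = phenotype.loc[cohort, list(covariate_names)].astype(float)
        cov = (cov - cov.mean()) / cov.std(ddof=0)

    missing = [c.snp_id for c in candidates if c.snp_id not in genotypes.columns]
    fits = []
    for cand in candidates:
        if cand.snp_id in missing:
            continue
        res = fit_additive_logistic(
            genotypes.loc[cohort, cand.snp_id], y, covariates=cov, snp_id=cand.snp_id
        )
        fits.append((cand, res))

    if fits:
        fdr = multipletests([r.p_value if np.isfinite(r.p_value) else 1.0 for _, r in fits],
                            method="fdr_bh")[1]
        fits = [
            (c, AssociationResult(**{**r.__dict__, "p_fdr": float(q)}))
            for (c, r), q in zip(fits, fdr)
        ]
    kept = [(c, r) for c, r in fits if np.isfinite(r.p_value) and r.p_value < alpha]
    return kept, missing
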
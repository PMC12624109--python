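"""Sign-consistency ("biological plausibility") classification of axes.

An axis SNP→CpG→gene→risk is coherent under the classical negative-
regulation model when two rules hold:

Rule 1 (negative regulation): the CpG's methylation is negatively
correlated with the gene's expression (r < 0) and the tumor-vs-normal
methylation and expression calls point in opposite directions
(hypermethylated with lower expression, or vice versa).

Rule 2 (risk concordance): reasoning from the allele first — if the
variant allele shifts methylation TOWARD the tumor-like methylation level
(meQTL sign '+' with tumor methylation High, or '-' with Low) the axis
predicts increased risk (OR > 1); shifting AWAY predicts protection
(OR < 1).  The observed odds-ratio side must match the prediction.

Axes with positive methylation–expression correlation fail Rule 1 rather
than being re-evaluated under a mirrored positive-regulation model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SummaryAxisRow

__all__ = ["PlausibilityVerdict", "SignDisagreementError", "classify_axis", "classify_table"]


class SignDisagreementError(ValueError):
    """meQTL effect signs disagree between tissue and blood."""


@dataclass(frozen=True)
class PlausibilityVerdict:
    axis_id: str
    rule_negative_regulation: bool
    predicted_or_direction: str  # "risk" (OR>1) or "protective" (OR<1)
    rule_or_concordance: bool
    overall: bool
    narrative: str
    indeterminate: bool = False  # OR exactly 1: no side to check

    def __post_init__(self):
        if self.overall != (self.rule_negative_regulation and self.rule_or_concordance):
            raise ValueError("overall must equal the conjunction of the two rules")


def classify_axis(row: SummaryAxisRow) -> PlausibilityVerdict:
    """Apply the two-rule classifier to one axis.

    Requires the meQTL sign to agree between tissue and blood (upstream
    filtering guarantees this for funnel output).  An odds ratio of exactly
    1 has no direction, so the verdict is flagged indeterminate and fails.
    """
    if row.beta_sign_tissue != row.beta_sign_blood:
        raise SignDisagreementError(
            f"{row.snp_id}: meQTL sign differs between tissue ({row.beta_sign_tissue}) "
            f"and blood ({row.beta_sign_blood})"
        )
    sign = row.beta_sign_tissue
    axis_id = f"{row.snp_id}-{row.cpg_id}-{row.gene_symbol}"

    rule1 = row.r < 0 and row.tumor_meth_level != row.tumor_expr_level

    toward_tumor = (sign == "+" and row.tumor_meth_level == "High") or (
        sign == "-" and row.tumor_meth_level == "Low"
    )
    predicted = "risk" if toward_tumor else "protective"

    indeterminate = row.or_value == 1.0
    if indeterminate:
        rule2 = False
    else:
        rule2 = (row.or_value > 1.0) == (predicted == "risk")

    overall = rule1 and rule2
    meth_word = "toward" if toward_tumor else "away from"
    narrative = (
        f"{axis_id}: variant shifts methylation {meth_word} the tumor-like level "
        f"(sign {sign}, tumor methylation {row.tumor_meth_level}), predicting a "
        f"{predicted} allele; r = {row.r:+.2f} with tumor expression "
        f"{row.tumor_expr_level}; observed OR = {row.or_value:.2f} — "
        + ("indeterminate (OR = 1)" if indeterminate else ("coherent" if overall else "incoherent"))
        + " under the negative-regulation model."
    )
    return PlausibilityVerdict(
        axis_id=axis_id,
        rule_negative_regulation=rule1,
        predicted_or_direction=predicted,
        rule_or_concordance=rule2,
        overall=overall,
        narrative=narrative,
        indeterminate=indeterminate,
    )


def classify_table(rows: list[SummaryAxisRow]) -> tuple[list[PlausibilityVerdict], dict[str, int]]:
    """Classify every axis; return verdicts plus pass/fail counts.

    Errors on individual rows are re-raised with the row id attached.
    """
    if not rows:
        raise ValueError("need at least one axis row")
    verdicts = []
    for row in rows:
        try:
            verdicts.append(classify_axis(row))
        except SignDisagreementError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"axis {row.snp_id}: {exc}") from exc
    n_pass = sum(v.overall for v in verdicts)
    return verdicts, {"pass": n_pass, "fail": len(verdicts) - n_pass}
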
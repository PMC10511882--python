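"""Single-marker genetic association models for case-control data.

Five classical contrasts are implemented, each oriented to the risk allele:

multiplicative
    allele-level 2x2 table (each subject contributes two alleles); the OR
    is the cross-product ratio and the test a Pearson 1-df chi-square.
additive
    Cochran-Armitage trend test on genotype counts with scores (0, 1, 2);
    the attached OR is the per-allele (multiplicative) OR, so additive and
    multiplicative differ only in the chi-square statistic.
dominant / recessive
    carrier vs non-carrier, respectively risk-homozygote vs rest, collapsed
    to a subject-level 2x2.
genotypic
    full 2x3 table, 2-df Pearson chi-square, with heterozygote-vs-reference
    and homozygote-vs-reference ORs.

Confidence intervals are Woolf (log-OR +/- z * sqrt(sum of reciprocal
cells)).  A zero cell makes the contrast inapplicable (``applicable=False``,
statistics NaN) rather than silently corrected; pass ``haldane=True`` for
the +0.5 Haldane-Anscombe adjustment where an estimate is still wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import AlleleTable, Cohort, GenotypeCounts, tabulate

__all__ = [
    "AssociationResult",
    "MODELS",
    "allele_table",
    "allelic_association",
    "model_association",
    "trend_association",
    "genotypic_association",
    "association_results",
    "cohort_association_table",
]

MODELS = ("multiplicative", "additive", "dominant", "recessive", "genotypic")

_Z95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AssociationResult:
    """One genetic contrast: OR with Woolf CI, chi-square test, applicability.

    For the genotypic model ``odds_ratio``/``ci_low``/``ci_high`` describe
    the heterozygote-vs-reference contrast (the conventionally reported
    one) and the homozygote-vs-reference OR is in the ``*_hom`` fields.
    """

    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi_square: float
    df: int
    p_value: float
    applicable: bool
    significant_after_correction: bool | None = None
    odds_ratio_hom: float = float("nan")
    ci_low_hom: float = float("nan")
    ci_high_hom: float = float("nan")

    def flagged(self, threshold: float) -> "AssociationResult":
        """Copy with the multiple-testing significance flag filled in."""
        from dataclasses import replace

        sig = bool(self.applicable and self.p_value < threshold)
        return replace(self, significant_after_correction=sig)


def allele_table(case: GenotypeCounts, control: GenotypeCounts) -> AlleleTable:
    """Collapse genotype counts to the 2x2 allele table."""
    return AlleleTable(
        case_risk=case.risk_allele_count,
        case_other=case.other_allele_count,
        control_risk=control.risk_allele_count,
        control_other=control.other_allele_count,
    )


def _woolf_or(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """Cross-product OR of [[a, b], [c, d]] with Woolf 95% CI."""
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return or_, float(np.exp(log_or - _Z95 * se)), float(np.exp(log_or + _Z95 * se))


def _pearson_2x2(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return float(n * (a * d - b * c) ** 2 / denom)


def _from_2x2(model: str, a: int, b: int, c: int, d: int,
              haldane: bool) -> AssociationResult:
    """Build a 1-df result from a 2x2 table [[a, b], [c, d]] (cases on top)."""
    chi2 = _pearson_2x2(a, b, c, d)
    p = float(stats.chi2.sf(chi2, df=1)) if np.isfinite(chi2) else float("nan")
    cells = (a, b, c, d)
    if 0 in cells:
        if haldane:
            or_, lo, hi = _woolf_or(*(x + 0.5 for x in cells))
            return AssociationResult(model, or_, lo, hi, chi2, 1, p, applicable=False)
        nan = float("nan")
        return AssociationResult(model, nan, nan, nan, nan, 1, nan, applicable=False)
    or_, lo, hi = _woolf_or(a, b, c, d)
    return AssociationResult(model, or_, lo, hi, chi2, 1, p, applicable=True)


def allelic_association(table: AlleleTable, haldane: bool = False) -> AssociationResult:
    """Multiplicative (allele-level) association on a 2x2 allele table."""
    return _from_2x2("multiplicative", table.case_risk, table.case_other,
                     table.control_risk, table.control_other, haldane)


def model_association(case: GenotypeCounts, control: GenotypeCounts,
                      model: str, haldane: bool = False) -> AssociationResult:
    """Dominant (carrier vs non-carrier) or recessive (hom-risk vs rest)."""
    if model == "dominant":
        a, b = case.n_het + case.n_hom_risk, case.n_hom_other
        c, d = control.n_het + control.n_hom_risk, control.n_hom_other
    elif model == "recessive":
        a, b = case.n_hom_risk, case.n_het + case.n_hom_other
        c, d = control.n_hom_risk, control.n_het + control.n_hom_other
    else:
        raise ValueError(f"model must be 'dominant' or 'recessive', got {model!r}")
    return _from_2x2(model, a, b, c, d, haldane)


def trend_association(case: GenotypeCounts, control: GenotypeCounts) -> AssociationResult:
    """Cochran-Armitage trend test (scores 0, 1, 2), 'additive' model.

    The reported OR is the per-allele OR from the allele table, so the
    additive row shares its estimate with the multiplicative row while the
    chi-square statistic differs.
    """
    r = case.as_array().astype(float)      # cases per genotype
    n_col = r + control.as_array()         # column totals
    big_n = n_col.sum()
    big_r = r.sum()
    s = np.array([0.0, 1.0, 2.0])
    if big_r == 0 or big_r == big_n or np.count_nonzero(n_col) < 2:
        nan = float("nan")
        return AssociationResult("additive", nan, nan, nan, nan, 1, nan,
                                 applicable=False)
    num = big_n * (s * r).sum() - big_r * (s * n_col).sum()
    var = big_r * (big_n - big_r) * (big_n * (s**2 * n_col).sum()
                                     - (s * n_col).sum() ** 2) / big_n
    chi2 = float(num**2 / var)
    p = float(stats.chi2.sf(chi2, df=1))
    allelic = allelic_association(allele_table(case, control))
    return AssociationResult("additive", allelic.odds_ratio, allelic.ci_low,
                             allelic.ci_high, chi2, 1, p,
                             applicable=allelic.applicable)


def genotypic_association(case: GenotypeCounts,
                          control: GenotypeCounts) -> AssociationResult:
    """2-df Pearson chi-square on the 2x3 genotype table.

    ORs are heterozygote-vs-reference (primary) and risk-homozygote-vs-
    reference (secondary), each with Woolf CIs.
    """
    obs = np.array([case.as_array(), control.as_array()], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    nan = float("nan")
    if (row == 0).any() or case.n_hom_other == 0 or control.n_hom_other == 0:
        return AssociationResult("genotypic", nan, nan, nan, nan, 2, nan,
                                 applicable=False)
    keep = col.ravel() > 0
    expected = row * col / obs.sum()
    chi2 = float(((obs[:, keep] - expected[:, keep]) ** 2 / expected[:, keep]).sum())
    df = 2
    p = float(stats.chi2.sf(chi2, df=df))

    def contrast(n_case: int, n_ctrl: int):
        cells = (n_case, case.n_hom_other, n_ctrl, control.n_hom_other)
        return _woolf_or(*cells) if 0 not in cells else (nan, nan, nan)

    or_het, lo_het, hi_het = contrast(case.n_het, control.n_het)
    or_hom, lo_hom, hi_hom = contrast(case.n_hom_risk, control.n_hom_risk)
    return AssociationResult("genotypic", or_het, lo_het, hi_het, chi2, df, p,
                             applicable=np.isfinite(or_het),
                             odds_ratio_hom=or_hom, ci_low_hom=lo_hom,
                             ci_high_hom=hi_hom)


def association_results(
    case: GenotypeCounts,
    control: GenotypeCounts,
    models: tuple[str, ...] = MODELS,
    correction_threshold: float | None = None,
    haldane: bool = False,
) -> dict[str, AssociationResult]:
    """All requested contrasts for one marker, optionally flagged against a
    Bonferroni-corrected threshold."""
    out: dict[str, AssociationResult] = {}
    for model in models:
        if model == "multiplicative":
            res = allelic_association(allele_table(case, control), haldane)
        elif model == "additive":
            res = trend_association(case, control)
        elif model in ("dominant", "recessive"):
            res = model_association(case, control, model, haldane)
        elif model == "genotypic":
            res = genotypic_association(case, control)
        else:
            raise ValueError(f"unknown model {model!r}")
        if correction_threshold is not None:
            res = res.flagged(correction_threshold)
        out[model] = res
    return out


def cohort_association_table(
    cohort: Cohort,
    models: tuple[str, ...] = MODELS,
    correction_threshold: float | None = None,
    haldane: bool = False,
) -> pd.DataFrame:
    """Long-format association table: one row per marker x model."""
    rows = []
    for j, m in enumerate(cohort.markers):
        case, ctrl = tabulate(cohort, j)
        n_case_obs, n_ctrl_obs = case.total, ctrl.total
        freqs = {
            "case_freq": case.risk_allele_count / (2 * n_case_obs) if n_case_obs else np.nan,
            "control_freq": ctrl.risk_allele_count / (2 * n_ctrl_obs) if n_ctrl_obs else np.nan,
        }
        for model, res in association_results(
            case, ctrl, models, correction_threshold, haldane
        ).items():
            rows.append(
                {
                    "rs_id": m.rs_id,
                    "gene": m.gene,
                    "risk_allele": m.risk_allele,
                    "other_allele": m.other_allele,
                    **freqs,
                    "model": model,
                    "chi_square": res.chi_square,
                    "df": res.df,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "odds_ratio_hom": res.odds_ratio_hom,
                    "p_value": res.p_value,
                    "applicable": res.applicable,
                    "significant_after_correction": res.significant_after_correction,
                }
            )
    return pd.DataFrame(rows)
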
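"""Per-marker QC statistics: allele frequencies, heterozygosity, HWE.

Hardy-Weinberg equilibrium is evaluated on the pooled sample (cases plus
controls) by default, matching the convention of a single QC column per
marker; pass only one group's counts for a per-group test.  Two HWE tests
are offered: the 1-df chi-square goodness-of-fit (default) and the
standard conditional exact test, useful when minor-allele counts are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort, GenotypeCounts, tabulate

__all__ = [
    "HweResult",
    "pooled_counts",
    "pooled_maf",
    "risk_allele_frequency",
    "expected_het",
    "hwe_test",
    "bonferroni_threshold",
    "marker_qc_table",
]


@dataclass(frozen=True)
class HweResult:
    maf: float
    obs_het: float
    exp_het: float
    chi_square: float
    p_value: float
    method: str


def pooled_counts(case: GenotypeCounts, control: GenotypeCounts) -> GenotypeCounts:
    return GenotypeCounts(
        case.n_hom_other + control.n_hom_other,
        case.n_het + control.n_het,
        case.n_hom_risk + control.n_hom_risk,
    )


def risk_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the risk allele (unfolded; may exceed 0.5)."""
    if counts.total == 0:
        raise ValueError("no subjects with observed genotype")
    return counts.risk_allele_count / (2 * counts.total)


def pooled_maf(case: GenotypeCounts, control: GenotypeCounts) -> float:
    """Minor-allele frequency over the pooled sample, folded to <= 0.5.

    When the risk allele is the major allele the folded value refers to
    the *other* allele; report :func:`risk_allele_frequency` alongside when
    the orientation matters.
    """
    p = risk_allele_frequency(pooled_counts(case, control))
    return min(p, 1.0 - p)


def expected_het(p: float) -> float:
    """Expected heterozygosity 2p(1-p) under HWE."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return 2.0 * p * (1.0 - p)


def _hwe_chi2(counts: GenotypeCounts) -> tuple[float, float]:
    n = counts.total
    p = counts.risk_allele_count / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: nothing to test
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts.as_array() - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_exact_p(counts: GenotypeCounts) -> float:
    """Conditional exact HWE test (sum of heterozygote-count probabilities
    no larger than the observed one, given allele counts)."""
    n_het = counts.n_het
    rare = min(counts.risk_allele_count, counts.other_allele_count)
    n = counts.total
    if rare == 0:
        return 1.0
    # heterozygote count shares the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each possible het count
    from scipy.special import gammaln

    def logp(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (h * np.log(2)
                - gammaln(h + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1))

    lp = np.array([logp(h) for h in het_values])
    prob = np.exp(lp - lp.max())
    prob /= prob.sum()
    p_obs = prob[het_values == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(counts: GenotypeCounts, method: str = "chi2") -> HweResult:
    """Test the genotype counts for departure from Hardy-Weinberg proportions.

    ``chi2``: 1-df goodness-of-fit against expectations at the sample
    allele frequency, no continuity correction.  ``exact``: conditional
    exact test; the chi-square statistic is still reported for reference.
    A monomorphic marker yields chi-square 0 and p-value 1.
    """
    if counts.total < 1:
        raise ValueError("need at least one genotyped subject")
    p_risk = counts.risk_allele_count / (2 * counts.total)
    chi2, p_chi2 = _hwe_chi2(counts)
    if method == "chi2":
        p = p_chi2
    elif method == "exact":
        p = _hwe_exact_p(counts)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HweResult(
        maf=min(p_risk, 1 - p_risk),
        obs_het=counts.n_het / counts.total,
        exp_het=expected_het(p_risk),
        chi_square=chi2,
        p_value=p,
        method=method,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / m."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def marker_qc_table(cohort: Cohort, method: str = "chi2") -> pd.DataFrame:
    """Marker-check table: one row per marker with pooled QC statistics."""
    rows = []
    for j, m in enumerate(cohort.markers):
        case, ctrl = tabulate(cohort, j)
        pooled = pooled_counts(case, ctrl)
        res = hwe_test(pooled, method=method)
        rows.append(
            {
                "rs_id": m.rs_id,
                "gene": m.gene,
                "chr": m.chromosome,
                "bp": m.position_bp,
                "alleles": f"{m.other_allele}:{m.risk_allele}",
                "genotyping_rate": pooled.total / cohort.n_subjects,
                "maf": res.maf,
                "risk_allele_freq": risk_allele_frequency(pooled),
                "o_het": res.obs_het,
                "e_het": res.exp_het,
                "hwe_chi2": res.chi_square,
                "hwe_p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
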
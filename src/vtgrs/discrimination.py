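"""ROC/AUC discrimination analysis with DeLong inference.

The empirical AUC is the probability that a randomly chosen case outscores
a randomly chosen control, with ties counted half -- identical to the
normalized Mann-Whitney U.  Standard errors and confidence intervals come
from DeLong's structural-components estimator, which also yields the
paired test for comparing two correlated AUCs measured on the same
subjects.

For score functions of genotype alone the AUC has a closed form under
Hardy-Weinberg equilibrium and inter-locus independence: enumerate the
joint genotype distribution per group and sum P(case score > control
score) + P(tie)/2.  :func:`analytic_snp_auc` does this for one marker
(3x3 states) and :func:`analytic_grs_auc` for a weighted panel (3^k
states), which is exact and instantaneous for the panel sizes used in
candidate-SNP studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_model import Cohort
from .risk_scoring import cohort_allelic_weights, effective_dosages

__all__ = [
    "AucResult",
    "DelongComparison",
    "empirical_auc",
    "delong_paired_test",
    "analytic_snp_auc",
    "analytic_grs_auc",
    "incremental_auc",
]

_Z95 = 1.959964

#: largest panel for exact 3^k enumeration
MAX_ENUM_MARKERS = 12


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class DelongComparison:
    auc1: float
    auc2: float
    delta_auc: float
    se: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, is_case: np.ndarray):
    """AUCs and DeLong covariance for k score vectors on shared subjects.

    ``scores`` has shape (k, n).  Returns (aucs (k,), cov (k, k)) where cov
    is the covariance matrix of the AUC estimates (structural components).
    """
    case = scores[:, is_case]
    ctrl = scores[:, ~is_case]
    m, n = case.shape[1], ctrl.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))  # per-case structural components
    v01 = np.empty((k, n))  # per-control structural components
    for r in range(k):
        all_rank = _midrank(np.concatenate([case[r], ctrl[r]]))
        case_rank = _midrank(case[r])
        ctrl_rank = _midrank(ctrl[r])
        auc = (all_rank[:m].sum() - m * (m + 1) / 2) / (m * n)
        aucs[r] = auc
        v10[r] = (all_rank[:m] - case_rank) / n
        v01[r] = 1.0 - (all_rank[m:] - ctrl_rank) / m
    s10 = np.cov(v10) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def empirical_auc(scores: np.ndarray, is_case: np.ndarray) -> AucResult:
    """Tie-adjusted empirical AUC with DeLong standard error and 95% CI."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if scores.shape != is_case.shape:
        raise ValueError("scores and labels must be aligned")
    m, n = int(is_case.sum()), int((~is_case).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    aucs, cov = _delong_components(scores[None, :], is_case)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    auc = float(aucs[0])
    return AucResult(
        auc=auc,
        se=se,
        ci_low=float(np.clip(auc - _Z95 * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + _Z95 * se, 0.0, 1.0)),
        n_cases=m,
        n_controls=n,
    )


def delong_paired_test(scores1: np.ndarray, scores2: np.ndarray,
                       is_case: np.ndarray) -> DelongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if s1.shape != s2.shape or s1.shape != is_case.shape:
        raise ValueError("score vectors must be defined on identical subjects")
    aucs, cov = _delong_components(np.vstack([s1, s2]), is_case)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        z = 0.0 if delta == 0.0 else float(np.sign(delta) * np.inf)
    else:
        z = delta / se
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return DelongComparison(
        auc1=float(aucs[0]), auc2=float(aucs[1]), delta_auc=delta, se=se,
        z=z, p_value=p if se > 0 or delta != 0 else 1.0,
        ci_low=delta - _Z95 * se, ci_high=delta + _Z95 * se,
    )


# ---------------------------------------------------------------------------
# Closed-form AUC under HWE + inter-locus independence
# ---------------------------------------------------------------------------

def _hwe_genotype_probs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _auc_from_distributions(case_vals, case_probs, ctrl_vals, ctrl_probs) -> float:
    diff = np.subtract.outer(case_vals, ctrl_vals)
    joint = np.multiply.outer(case_probs, ctrl_probs)
    gt = diff > 1e-9
    tie = np.abs(diff) <= 1e-9
    return float((joint * gt).sum() + 0.5 * (joint * tie).sum())


def analytic_snp_auc(p_case: float, p_control: float) -> float:
    """Exact AUC of a single marker's 0/1/2 dosage score when each group is
    in HWE at its own risk-allele frequency."""
    for p in (p_case, p_control):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequencies must be in [0, 1]")
    vals = np.array([0.0, 1.0, 2.0])
    return _auc_from_distributions(
        vals, _hwe_genotype_probs(p_case), vals, _hwe_genotype_probs(p_control)
    )


def _score_distribution(freqs: np.ndarray, weights: np.ndarray):
    """Distribution of the weighted dosage sum by per-marker convolution."""
    vals = np.array([0.0])
    probs = np.array([1.0])
    for p, w in zip(freqs, weights):
        g = _hwe_genotype_probs(p)
        new_vals = (vals[:, None] + w * np.array([0.0, 1.0, 2.0])[None, :]).ravel()
        new_probs = (probs[:, None] * g[None, :]).ravel()
        # merge numerically identical scores to keep the support compact
        order = np.argsort(new_vals)
        new_vals, new_probs = new_vals[order], new_probs[order]
        merged_v = [new_vals[0]]
        merged_p = [new_probs[0]]
        for v, q in zip(new_vals[1:], new_probs[1:]):
            if v - merged_v[-1] <= 1e-9:
                merged_p[-1] += q
            else:
                merged_v.append(v)
                merged_p.append(q)
        vals, probs = np.array(merged_v), np.array(merged_p)
    return vals, probs


def analytic_grs_auc(case_freqs: np.ndarray, control_freqs: np.ndarray,
                     weights: np.ndarray | None = None) -> float:
    """Exact AUC of a weighted risk-allele-count score under HWE and
    inter-locus independence, by full enumeration of joint genotype states.

    ``weights=None`` gives the unweighted score.  Panels beyond
    ``MAX_ENUM_MARKERS`` markers are refused (use Monte-Carlo simulation
    via :mod:`vtgrs.synthetic_cohort` instead).
    """
    cf = np.asarray(case_freqs, dtype=float)
    kf = np.asarray(control_freqs, dtype=float)
    if cf.shape != kf.shape:
        raise ValueError("case and control frequency vectors must match")
    k = cf.size
    if k > MAX_ENUM_MARKERS:
        raise ValueError(
            f"exact enumeration limited to {MAX_ENUM_MARKERS} markers; "
            "use Monte-Carlo simulation for larger panels"
        )
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != cf.shape:
        raise ValueError("weights must have one entry per marker")
    case_vals, case_probs = _score_distribution(cf, w)
    ctrl_vals, ctrl_probs = _score_distribution(kf, w)
    return _auc_from_distributions(case_vals, case_probs, ctrl_vals, ctrl_probs)


# ---------------------------------------------------------------------------
# Incremental marker addition
# ---------------------------------------------------------------------------

def incremental_auc(
    cohort: Cohort,
    weights: np.ndarray | None = None,
    order: list[int] | None = None,
    refit: bool = False,
) -> tuple[list[int], list[AucResult]]:
    """AUC trajectory as markers are added one at a time.

    Markers enter in ``order`` (default: descending allelic OR as
    estimated on this cohort, the natural 'strongest first' ordering).  At
    step j the score is the weighted GRS restricted to the first j markers
    with fixed per-marker weights (default ln allelic OR); with
    ``refit=True`` a logistic model is refit on the j dosage columns and
    its linear predictor scored instead.

    Returns ``(order, [AucResult per step])``.
    """
    complete = cohort.complete_cases()
    if complete.n_markers < 1:
        raise ValueError("need at least one marker")
    w = cohort_allelic_weights(complete) if weights is None \
        else np.asarray(weights, dtype=float)
    if order is None:
        order = list(np.argsort(-w, kind="stable"))
    d = effective_dosages(complete)
    results: list[AucResult] = []
    for j in range(1, len(order) + 1):
        cols = order[:j]
        if refit:
            import pandas as pd

            from .risk_scoring import logistic_fit

            design = pd.DataFrame(
                d[:, cols], columns=[complete.markers[c].rs_id for c in cols]
            )
            fit = logistic_fit(complete.is_case.astype(float), design)
            score = fit.linear_predictor
        else:
            score = d[:, cols] @ w[cols]
        results.append(empirical_auc(score, complete.is_case))
    return order, results
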
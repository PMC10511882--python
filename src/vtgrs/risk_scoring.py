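"""Genetic risk scores and logistic risk models.

The unweighted genetic risk score (unGRS) of a subject is the number of
risk alleles carried over the marker panel; the weighted score (wGRS)
multiplies each marker's dosage by a per-allele weight, conventionally the
natural log of that allele's odds ratio.  Markers whose named allele is
*protective* enter with flipped coding (dosage ``d`` contributes ``2 - d``)
so that every term points in the risk-increasing direction.

Logistic regression (via statsmodels) supplies crude and adjusted odds
ratios for genetic and non-genetic risk factors, and its linear predictor
doubles as a subject-level combined risk score.  The log is invariant to a
common rescaling of GRS weights as far as discrimination is concerned, so
whether weights come from this dataset or external estimates only shifts
the score's scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_models import allele_table, allelic_association
from .cohort_model import Cohort, tabulate

__all__ = [
    "GrsVector",
    "LogisticFit",
    "MannWhitneyResult",
    "effective_dosages",
    "weights_from_or",
    "cohort_allelic_weights",
    "compute_grs",
    "logistic_fit",
    "nagelkerke_r2",
    "mann_whitney",
    "age_in_5y_units",
    "bmi_category_design",
    "non_genetic_design",
]

_Z95 = 1.959964


@dataclass(frozen=True)
class GrsVector:
    """Per-subject genetic risk scores over a fixed marker panel."""

    ids: list[str]
    ungrs: np.ndarray
    wgrs: np.ndarray
    weights: np.ndarray
    is_case: np.ndarray


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float


def effective_dosages(cohort: Cohort) -> np.ndarray:
    """Dosage matrix with protective markers flipped to risk orientation."""
    d = cohort.dosages.copy()
    for j, m in enumerate(cohort.markers):
        if m.protective:
            d[:, j] = 2.0 - d[:, j]
    return d


def weights_from_or(odds_ratios: np.ndarray) -> np.ndarray:
    """Per-allele weights: natural log of the odds ratios."""
    ors = np.asarray(odds_ratios, dtype=float)
    if (ors <= 0).any():
        raise ValueError("odds ratios must be positive")
    return np.log(ors)


def cohort_allelic_weights(cohort: Cohort) -> np.ndarray:
    """ln(allelic OR) per marker, computed from the cohort itself.

    Protective markers are flipped before the OR so every weight points in
    the risk-increasing direction.
    """
    weights = np.empty(cohort.n_markers)
    for j, m in enumerate(cohort.markers):
        case, ctrl = tabulate(cohort, j)
        if m.protective:
            case, ctrl = case.swapped(), ctrl.swapped()
        res = allelic_association(allele_table(case, ctrl))
        if not res.applicable:
            raise ValueError(
                f"{m.rs_id}: allelic OR undefined (zero cell); supply weights explicitly"
            )
        weights[j] = np.log(res.odds_ratio)
    return weights


def compute_grs(cohort: Cohort, weights: np.ndarray | None = None) -> GrsVector:
    """Unweighted and weighted genetic risk scores.

    Subjects with any missing dosage are dropped (complete-case scoring).
    ``weights`` defaults first to the weights stored on the markers and,
    where absent, to ln(allelic OR) estimated from this cohort.
    """
    if weights is None:
        stored = [m.weight for m in cohort.markers]
        weights = (np.array(stored, dtype=float) if all(w is not None for w in stored)
                   else cohort_allelic_weights(cohort))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (cohort.n_markers,):
        raise ValueError(
            f"expected {cohort.n_markers} weights, got {weights.shape}"
        )
    complete = cohort.complete_cases()
    if complete.n_subjects < cohort.n_subjects:
        warnings.warn(
            f"dropped {cohort.n_subjects - complete.n_subjects} subject(s) "
            "with incomplete genotypes from GRS computation"
        )
    d = effective_dosages(complete)
    return GrsVector(
        ids=list(complete.ids),
        ungrs=d.sum(axis=1).astype(int),
        wgrs=d @ weights,
        weights=weights,
        is_case=complete.is_case.copy(),
    )


# ---------------------------------------------------------------------------
# Logistic risk models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``odds_ratios`` etc. are indexed by term name (the intercept is kept as
    ``const``).  ``linear_predictor`` is the subject-level combined risk
    score X @ beta.  ``pseudo_r2`` is Nagelkerke's rescaled Cox-Snell R2.
    """

    terms: list[str]
    coef: pd.Series
    se: pd.Series
    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    llf: float
    llnull: float
    n_obs: int
    pseudo_r2: float
    cox_snell_r2: float
    converged: bool
    linear_predictor: np.ndarray


def _check_design_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == X.shape[1]:
        return
    # identify a minimal offending set by greedy column scan
    bad: list[str] = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        sub = mat[:, kept + [j]]
        if np.linalg.matrix_rank(sub) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(str(X.columns[j]))
    raise ValueError(f"design matrix is rank deficient; collinear term(s): {bad}")


def logistic_fit(outcome: np.ndarray, design: pd.DataFrame,
                 add_constant: bool = True) -> LogisticFit:
    """Fit a logistic regression of case status on the named design terms.

    Raises on a rank-deficient design (naming the collinear columns).
    Complete or quasi-complete separation is flagged through
    ``converged=False`` with NaN estimates rather than silently returned.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(outcome, dtype=float)
    X = design.copy()
    X.columns = [str(c) for c in X.columns]
    if add_constant:
        X.insert(0, "const", 1.0)
    if len(y) < X.shape[1] + 1:
        raise ValueError("need more observations than model terms")
    _check_design_rank(X)

    terms = list(X.columns)
    nan = pd.Series(np.nan, index=terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        separated = np.abs(res.params).max() > 50  # quasi-separation escape
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separated = True
        res = None
    if separated or res is None or not res.mle_retvals.get("converged", False):
        return LogisticFit(terms, nan, nan, nan, nan, nan, nan,
                           llf=np.nan, llnull=np.nan, n_obs=len(y),
                           pseudo_r2=np.nan, cox_snell_r2=np.nan,
                           converged=False,
                           linear_predictor=np.full(len(y), np.nan))

    coef = pd.Series(res.params, index=terms)
    se = pd.Series(res.bse, index=terms)
    llnull = float(res.llnull) if add_constant else float(res.llf)
    r2_n = nagelkerke_r2(float(res.llf), llnull, len(y))
    cs = 1.0 - np.exp(2.0 * (llnull - float(res.llf)) / len(y))
    return LogisticFit(
        terms=terms,
        coef=coef,
        se=se,
        odds_ratios=np.exp(coef),
        ci_low=np.exp(coef - _Z95 * se),
        ci_high=np.exp(coef + _Z95 * se),
        p_values=pd.Series(res.pvalues, index=terms),
        llf=float(res.llf),
        llnull=llnull,
        n_obs=len(y),
        pseudo_r2=r2_n,
        cox_snell_r2=float(cs),
        converged=True,
        linear_predictor=np.asarray(X.to_numpy(dtype=float) @ coef.to_numpy()),
    )


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell rescaled by its attainable maximum."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (normal approximation, tie-corrected).

    The returned U counts pairs where group A wins plus half the ties, so
    ``U / (n_a * n_b)`` is the empirical AUC of A-vs-B.
    """
    a, b = np.asarray(group_a), np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Covariate design helpers (non-genetic risk model)
# ---------------------------------------------------------------------------

def age_in_5y_units(age: np.ndarray) -> np.ndarray:
    """Age expressed in 5-year intervals (continuous)."""
    return np.asarray(age, dtype=float) / 5.0

def bmi_category_design(bmi: np.ndarray) -> pd.DataFrame:
    """Dummy columns for BMI category: <25 reference, 25-30, >=30 kg/m2."""
    bmi = np.asarray(bmi, dtype=float)
    return pd.DataFrame(
        {
            "bmi_25_30": ((bmi >= 25) & (bmi < 30)).astype(float),
            "bmi_ge30": (bmi >= 30).astype(float),
        }
    )


def non_genetic_design(cohort: Cohort) -> pd.DataFrame:
    """Design matrix of the non-genetic risk model: age (5-year units),
    sex and BMI category."""
    df = bmi_category_design(cohort.bmi)
    df.insert(0, "age5", age_in_5y_units(cohort.age))
    df.insert(1, "male", cohort.male.astype(float))
    return df
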
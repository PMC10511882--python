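"""Synthetic case-control cohorts for the five-SNP venous-thrombosis panel.

Real subject-level genotypes for the Hungarian VT case-control study this
package models are not public; what *is* public are group-level summaries:
risk-allele frequencies per group, covariate moments and group sizes.  This
module (a) rebuilds integer count tables from such printed frequencies and
(b) simulates whole cohorts with the statistical structure the downstream
analysis assumes -- Hardy-Weinberg equilibrium within each group,
independence between loci, and normal-ish covariates truncated to
plausible ranges.

Two generative modes are provided:

``marginal``
    each group is sampled directly from its own allele frequencies; this is
    the structure implied by group-level frequency tables and is the default.
``logistic``
    genotypes are drawn for a source population at control-like frequencies
    and case status assigned through a logistic disease model with known
    per-allele log odds ratios; useful for estimator-recovery experiments
    where the truth must be a regression coefficient rather than a pair of
    group frequencies.

The module-level defaults (:data:`STUDY_MARKERS`, :data:`CASE_FREQS`, ...)
encode the published study conditions: 298 VT cases vs 400 controls typed at
rs6025 (F5 Leiden), rs2066865 (FGG), rs2036914 (F11), rs8176719 (ABO) and
rs1799963 (F2 G20210A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_model import Cohort, GenotypeCounts, MarkerDef

__all__ = [
    "GroupMoments",
    "SimConfig",
    "STUDY_MARKERS",
    "CASE_FREQS",
    "CONTROL_FREQS",
    "CASE_COVARIATES",
    "CONTROL_COVARIATES",
    "default_config",
    "reconstruct_allele_counts",
    "reconstruct_genotype_counts",
    "simulate_cohort",
    "simulate_cohort_logistic",
]

# Published study conditions: the five strongly associated prothrombotic
# SNPs with their per-group risk-allele frequencies (A1 = risk allele).
STUDY_MARKERS: tuple[MarkerDef, ...] = (
    MarkerDef("rs6025", "T", "C", gene="F5", chromosome="1", position_bp=169549811),
    MarkerDef("rs2066865", "A", "G", gene="FGG", chromosome="4", position_bp=154604124),
    MarkerDef("rs2036914", "C", "T", gene="F11", chromosome="4", position_bp=186271327),
    MarkerDef("rs8176719", "C", "DEL", gene="ABO", chromosome="9", position_bp=133257521),
    MarkerDef("rs1799963", "A", "G", gene="F2", chromosome="11", position_bp=46739505),
)

CASE_FREQS: tuple[float, ...] = (0.203, 0.2836, 0.6191, 0.5956, 0.0302)
CONTROL_FREQS: tuple[float, ...] = (0.0675, 0.2312, 0.5412, 0.5262, 0.02)

# Plausibility bounds for the truncated-normal covariate draws.
AGE_BOUNDS = (18.0, 100.0)
BMI_BOUNDS = (15.0, 60.0)


def annotate_study_markers(cohort: Cohort) -> Cohort:
    """Replace placeholder marker definitions by the study panel's, matched
    by rs id.  Useful after reading a cohort TSV, whose header carries only
    rs ids; markers outside the panel are left untouched."""
    known = {m.rs_id: m for m in STUDY_MARKERS}
    cohort.markers = [known.get(m.rs_id, m) for m in cohort.markers]
    return cohort


@dataclass(frozen=True)
class GroupMoments:
    """Covariate summary for one phenotype group."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_prop: float

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValueError("covariate standard deviations must be positive")
        if not 0.0 <= self.male_prop <= 1.0:
            raise ValueError("male_prop must be a probability")


CASE_COVARIATES = GroupMoments(age_mean=63.4, age_sd=16.4, bmi_mean=28.2,
                               bmi_sd=8.2, male_prop=0.51)
CONTROL_COVARIATES = GroupMoments(age_mean=43.8, age_sd=12.6, bmi_mean=27.2,
                                  bmi_sd=5.5, male_prop=0.44)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated case-control cohort."""

    n_cases: int = 298
    n_controls: int = 400
    markers: tuple[MarkerDef, ...] = STUDY_MARKERS
    case_freqs: tuple[float, ...] = CASE_FREQS
    control_freqs: tuple[float, ...] = CONTROL_FREQS
    case_covariates: GroupMoments = CASE_COVARIATES
    control_covariates: GroupMoments = CONTROL_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be at least 1")
        k = len(self.markers)
        if len(self.case_freqs) != k or len(self.control_freqs) != k:
            raise ValueError("frequency vectors must match the marker panel length")
        for f in (*self.case_freqs, *self.control_freqs):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency {f} outside [0, 1]")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The published study conditions with a caller-chosen seed."""
    return SimConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Reconstruction of integer count tables from printed frequencies
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reconstruct_allele_counts(freq: float, n_subjects: int) -> tuple[int, int]:
    """Integer (risk, other) allele counts implied by a printed frequency.

    Each of ``n_subjects`` contributes two alleles; the risk count is the
    frequency times ``2n`` rounded to the nearest integer.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must be a probability")
    risk = _round_half_up(freq * 2 * n_subjects)
    return risk, 2 * n_subjects - risk


def reconstruct_genotype_counts(maf: float, obs_het: float, n: int) -> GenotypeCounts:
    """Genotype counts implied by printed MAF and observed heterozygosity.

    Returns counts ordered (major hom, het, minor hom).  Raises if the two
    frequencies are arithmetically inconsistent (negative implied count).
    """
    n_het = _round_half_up(obs_het * n)
    minor_alleles = _round_half_up(maf * 2 * n)
    n_hom_minor = _round_half_up((minor_alleles - n_het) / 2)
    n_hom_major = n - n_het - n_hom_minor
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError(
            f"inconsistent inputs: maf={maf}, obs_het={obs_het}, n={n} imply "
            f"counts ({n_hom_major}, {n_het}, {n_hom_minor})"
        )
    return GenotypeCounts(n_hom_major, n_het, n_hom_minor)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_covariates(rng: np.random.Generator, mom: GroupMoments, n: int):
    age = _truncated_normal(rng, mom.age_mean, mom.age_sd, AGE_BOUNDS, n)
    bmi = _truncated_normal(rng, mom.bmi_mean, mom.bmi_sd, BMI_BOUNDS, n)
    male = rng.random(n) < mom.male_prop
    return age, bmi, male


def _assemble(config: SimConfig, case_dos: np.ndarray, ctrl_dos: np.ndarray,
              rng_cov: np.random.Generator) -> Cohort:
    n_ca, n_co = case_dos.shape[0], ctrl_dos.shape[0]
    age_ca, bmi_ca, male_ca = _draw_covariates(rng_cov, config.case_covariates, n_ca)
    age_co, bmi_co, male_co = _draw_covariates(rng_cov, config.control_covariates, n_co)
    return Cohort(
        markers=list(config.markers),
        ids=[f"case_{i + 1:04d}" for i in range(n_ca)]
        + [f"ctrl_{i + 1:04d}" for i in range(n_co)],
        is_case=np.r_[np.ones(n_ca, bool), np.zeros(n_co, bool)],
        dosages=np.vstack([case_dos, ctrl_dos]).astype(float),
        age=np.r_[age_ca, age_co],
        male=np.r_[male_ca, male_co],
        bmi=np.r_[bmi_ca, bmi_co],
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Marginal-mode simulation: each group at its own allele frequencies.

    Per subject and marker the dosage is Binomial(2, p_group) -- two
    independent allele draws, i.e. HWE within group -- and loci are
    independent.  Genotypes and covariates use separate random substreams
    of the single seed, so changing the marker panel leaves covariate
    draws untouched.  Identical config (incl. seed) gives an identical
    cohort.
    """
    ss_geno, ss_cov = np.random.SeedSequence(config.seed).spawn(2)
    rng_g = np.random.default_rng(ss_geno)
    case_dos = rng_g.binomial(2, np.asarray(config.case_freqs),
                              size=(config.n_cases, len(config.markers)))
    ctrl_dos = rng_g.binomial(2, np.asarray(config.control_freqs),
                              size=(config.n_controls, len(config.markers)))
    return _assemble(config, case_dos, ctrl_dos, np.random.default_rng(ss_cov))


def simulate_cohort_logistic(
    config: SimConfig,
    per_allele_log_or: np.ndarray,
    intercept: float = -4.0,
    population_freqs: tuple[float, ...] | None = None,
    max_draws: int = 2_000_000,
) -> Cohort:
    """Logistic-mode simulation with known per-allele effects.

    A source population is drawn under HWE at ``population_freqs``
    (defaults to the config's control frequencies); each individual becomes
    a case with probability ``expit(intercept + dosages @ log_or)`` and
    sampling continues in fixed-size chunks until both group quotas are
    met.  With a rare-disease intercept the control group stays close to
    the population frequencies, making the allele-level odds ratio equal
    ``exp(per_allele_log_or)`` in expectation.
    """
    beta = np.asarray(per_allele_log_or, dtype=float)
    if beta.shape != (len(config.markers),):
        raise ValueError("per_allele_log_or must have one entry per marker")
    freqs = np.asarray(population_freqs if population_freqs is not None
                       else config.control_freqs)

    ss_geno, ss_cov = np.random.SeedSequence(config.seed).spawn(2)
    rng_g = np.random.default_rng(ss_geno)

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_ca = n_co = drawn = 0
    chunk = 8192
    while (n_ca < config.n_cases or n_co < config.n_controls) and drawn < max_draws:
        dos = rng_g.binomial(2, freqs, size=(chunk, len(freqs)))
        p = 1.0 / (1.0 + np.exp(-(intercept + dos @ beta)))
        is_case = rng_g.random(chunk) < p
        cases.append(dos[is_case])
        controls.append(dos[~is_case])
        n_ca += int(is_case.sum())
        n_co += int((~is_case).sum())
        drawn += chunk
    if n_ca < config.n_cases or n_co < config.n_controls:
        raise RuntimeError(
            "case/control quota not reached; raise max_draws or the intercept"
        )
    case_dos = np.vstack(cases)[: config.n_cases]
    ctrl_dos = np.vstack(controls)[: config.n_controls]
    return _assemble(config, case_dos, ctrl_dos, np.random.default_rng(ss_cov))
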
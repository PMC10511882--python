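"""Domain types and I/O for case-control SNP cohorts.

The central object is the :class:`Cohort`: a marker panel (each marker
oriented to its *risk* allele) together with subject-level phenotype,
risk-allele dosages and the non-genetic covariates used in venous-thrombosis
risk modelling (age, sex, BMI).  Dosage is the number of risk-allele copies
a subject carries (0, 1 or 2), stored as ``float`` with ``NaN`` for missing.

Cohorts round-trip through a simple TSV dialect (one row per subject,
header ``id  phenotype  sex  age  bmi  <rs_id...>``, missing dosage ``.``)
and genotypes can be pulled from standard VCF via :func:`read_vcf_dosages`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerDef",
    "GenotypeCounts",
    "AlleleTable",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "read_vcf_dosages",
    "tabulate",
    "MISSING_TOKEN",
]

#: token used for a missing dosage in the cohort TSV
MISSING_TOKEN = "."

#: token used for a deletion allele (e.g. the ABO exon-6 single-base deletion)
DELETION_TOKEN = "DEL"


@dataclass(frozen=True)
class MarkerDef:
    """Identity and allele semantics of one biallelic marker.

    ``risk_allele`` is the allele whose dosage the cohort stores; when
    ``protective`` is true the named allele lowers disease odds and risk
    scores flip its coding (dosage ``d`` contributes ``2 - d``).
    ``weight`` is an optional per-allele weight for weighted risk scores,
    conventionally the natural log of the allele's odds ratio.
    """

    rs_id: str
    risk_allele: str
    other_allele: str
    gene: str = ""
    chromosome: str = ""
    position_bp: int = 1
    protective: bool = False
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele == self.other_allele:
            raise ValueError(
                f"{self.rs_id}: risk and other allele must differ "
                f"(both {self.risk_allele!r})"
            )
        if self.position_bp < 1:
            raise ValueError(f"{self.rs_id}: position_bp must be >= 1 (1-based)")
        if self.weight is not None and not np.isfinite(self.weight):
            raise ValueError(f"{self.rs_id}: weight must be finite")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one marker in one group, oriented to the risk allele.

    Order is (other-allele homozygotes, heterozygotes, risk-allele
    homozygotes), i.e. by increasing dosage.
    """

    n_hom_other: int
    n_het: int
    n_hom_risk: int

    def __post_init__(self) -> None:
        if min(self.n_hom_other, self.n_het, self.n_hom_risk) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_other + self.n_het + self.n_hom_risk

    @property
    def risk_allele_count(self) -> int:
        return 2 * self.n_hom_risk + self.n_het

    @property
    def other_allele_count(self) -> int:
        return 2 * self.n_hom_other + self.n_het

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom_other, self.n_het, self.n_hom_risk])

    def swapped(self) -> "GenotypeCounts":
        """Counts with the roles of risk and other allele exchanged."""
        return GenotypeCounts(self.n_hom_risk, self.n_het, self.n_hom_other)


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table (each subject contributes two alleles)."""

    case_risk: int
    case_other: int
    control_risk: int
    control_other: int

    def __post_init__(self) -> None:
        if min(self.case_risk, self.case_other, self.control_risk, self.control_other) < 0:
            raise ValueError("allele counts must be non-negative")

    def swapped(self) -> "AlleleTable":
        """Table for the complementary allele (inverts the odds ratio)."""
        return AlleleTable(
            self.case_other, self.case_risk, self.control_other, self.control_risk
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_risk, self.case_other], [self.control_risk, self.control_other]]
        )


@dataclass
class Cohort:
    """Subject-level case-control data: phenotype, dosages and covariates.

    Arrays are aligned on subjects (rows); ``dosages`` has one column per
    marker in ``markers`` order and holds 0/1/2 or NaN.
    """

    markers: list[MarkerDef]
    ids: list[str]
    is_case: np.ndarray
    dosages: np.ndarray
    age: np.ndarray
    male: np.ndarray
    bmi: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.male = np.asarray(self.male, dtype=bool)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.bmi = np.asarray(self.bmi, dtype=float)
        if not self._validated:
            self.validate()
            self._validated = True

    def validate(self) -> None:
        n = len(self.ids)
        if self.dosages.shape != (n, len(self.markers)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n} subjects x {len(self.markers)} markers"
            )
        for arr, name in ((self.is_case, "is_case"), (self.age, "age"),
                          (self.male, "male"), (self.bmi, "bmi")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per subject")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad!r}")
        if (self.age <= 0).any():
            raise ValueError("age must be positive")
        if (self.bmi <= 0).any():
            raise ValueError("bmi must be positive")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def marker_index(self, rs_id: str) -> int:
        for j, m in enumerate(self.markers):
            if m.rs_id == rs_id:
                return j
        raise KeyError(rs_id)

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            markers=list(self.markers),
            ids=[i for i, keep in zip(self.ids, mask) if keep],
            is_case=self.is_case[mask],
            dosages=self.dosages[mask],
            age=self.age[mask],
            male=self.male[mask],
            bmi=self.bmi[mask],
            _validated=True,
        )

    def complete_cases(self) -> "Cohort":
        """Subjects with a non-missing dosage at every marker."""
        return self.subset(~np.isnan(self.dosages).any(axis=1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "phenotype": np.where(self.is_case, "case", "control"),
                "sex": np.where(self.male, "male", "female"),
                "age": self.age,
                "bmi": self.bmi,
            }
        )
        for j, m in enumerate(self.markers):
            df[m.rs_id] = self.dosages[:, j]
        return df


# ---------------------------------------------------------------------------
# TSV reader / writer
# ---------------------------------------------------------------------------

_PHENOTYPE_LABELS = {"case": True, "1": True, "control": False, "0": False}
_SEX_LABELS = {"male": True, "m": True, "1": True, "female": False, "f": False, "0": False}
_COVARIATE_COLUMNS = ("id", "phenotype", "sex", "age", "bmi")


def read_cohort(path: str | Path, markers: list[MarkerDef] | None = None) -> Cohort:
    """Read a cohort TSV.

    The header must start with ``id phenotype sex age bmi``; every further
    column is a marker (dosages 0/1/2, missing ``.``).  If ``markers`` is
    given, the dosage columns are matched to it by rs id (order follows the
    marker list); otherwise minimal :class:`MarkerDef` stubs are created.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _COVARIATE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")

    rs_cols = [c for c in df.columns if c not in _COVARIATE_COLUMNS]
    if markers is None:
        markers = [MarkerDef(rs, risk_allele="A1", other_allele="A2") for rs in rs_cols]
    else:
        wanted = [m.rs_id for m in markers]
        absent = sorted(set(wanted) - set(rs_cols))
        if absent:
            raise ValueError(f"{path}: marker column(s) {absent} not present")
        rs_cols = wanted

    pheno = df["phenotype"].str.strip().str.lower().map(_PHENOTYPE_LABELS)
    if pheno.isna().any():
        row = int(pheno.isna().idxmax())
        raise ValueError(
            f"{path}: unknown phenotype label {df['phenotype'][row]!r} in row {row + 2} "
            "(expected case/1 or control/0)"
        )
    sex = df["sex"].str.strip().str.lower().map(_SEX_LABELS)
    if sex.isna().any():
        row = int(sex.isna().idxmax())
        raise ValueError(f"{path}: unknown sex label {df['sex'][row]!r} in row {row + 2}")

    dosages = np.full((len(df), len(rs_cols)), np.nan)
    for j, rs in enumerate(rs_cols):
        raw = df[rs].astype(str).str.strip()
        for i, tok in enumerate(raw):
            if tok in (MISSING_TOKEN, "", "nan", "NaN", "NA"):
                continue
            if tok not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: malformed dosage {tok!r} in row {i + 2}, column {rs!r} "
                    "(expected 0, 1, 2 or '.')"
                )
            dosages[i, j] = float(tok)

    return Cohort(
        markers=list(markers),
        ids=df["id"].astype(str).tolist(),
        is_case=pheno.to_numpy(dtype=bool),
        dosages=dosages,
        age=df["age"].astype(float).to_numpy(),
        male=sex.to_numpy(dtype=bool),
        bmi=df["bmi"].astype(float).to_numpy(),
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to TSV so that :func:`read_cohort` restores it exactly."""
    df = cohort.to_frame()
    for m in cohort.markers:
        col = df[m.rs_id]
        df[m.rs_id] = np.where(np.isnan(col), MISSING_TOKEN,
                               col.fillna(0).astype(int).astype(str))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF dosage extraction
# ---------------------------------------------------------------------------

def _match_allele_index(marker: MarkerDef, alleles: list[str]) -> int | None:
    """Index of the marker's risk allele among a site's REF+ALT alleles.

    Indels are matched by length: a ``DEL`` marker allele maps to the
    shortest allele at the site and its partner to the longest, since VCF
    encodes deletions/insertions with an anchor base rather than a symbol.
    """
    if DELETION_TOKEN in (marker.risk_allele, marker.other_allele):
        lengths = [len(a) for a in alleles]
        idx_short = int(np.argmin(lengths))
        idx_long = int(np.argmax(lengths))
        if idx_short == idx_long:  # no length difference: not an indel site
            return None
        return idx_short if marker.risk_allele == DELETION_TOKEN else idx_long
    ups = [a.upper() for a in alleles]
    risk = marker.risk_allele.upper()
    return ups.index(risk) if risk in ups else None


def read_vcf_dosages(
    path: str | Path, markers: list[MarkerDef]
) -> tuple[list[str], np.ndarray]:
    """Extract risk-allele dosages for ``markers`` from a VCF.

    Returns ``(sample_ids, matrix)`` with one dosage column per marker.
    Sites are matched by rs id or by (chromosome, position).  A genotype
    with any missing allele yields a missing dosage; a marker absent from
    the file is left all-missing with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    mat = np.full((len(samples), len(markers)), np.nan)

    by_id = {m.rs_id: j for j, m in enumerate(markers)}
    by_pos = {(str(m.chromosome), int(m.position_bp)): j for j, m in enumerate(markers)}
    found: set[int] = set()

    for var in vcf:
        j = by_id.get(var.ID) if var.ID else None
        if j is None:
            j = by_pos.get((str(var.CHROM).removeprefix("chr"), var.POS))
        if j is None or j in found:
            continue
        marker = markers[j]
        alleles = [var.REF] + list(var.ALT)
        risk_idx = _match_allele_index(marker, alleles)
        if risk_idx is None:
            warnings.warn(
                f"{marker.rs_id}: risk allele {marker.risk_allele!r} not among "
                f"site alleles {alleles}; leaving marker missing"
            )
            continue
        found.add(j)
        for i, gt in enumerate(var.genotypes):
            a = [int(x) for x in gt[:-1]]  # last entry is phase flag
            if len(a) < 2 or min(a) < 0:
                continue  # half- or fully-missing genotype
            mat[i, j] = float(sum(x == risk_idx for x in a))

    for j, m in enumerate(markers):
        if j not in found:
            warnings.warn(f"{m.rs_id}: not found in VCF; recorded as all-missing")
    return samples, mat


# ---------------------------------------------------------------------------
# Genotype tabulation
# ---------------------------------------------------------------------------

def tabulate(cohort: Cohort, marker: int | str) -> tuple[GenotypeCounts, GenotypeCounts]:
    """Per-group genotype counts (cases, controls) for one marker.

    Subjects with a missing dosage at the marker are excluded from both
    groups (complete-case per marker).
    """
    j = cohort.marker_index(marker) if isinstance(marker, str) else marker
    if not 0 <= j < cohort.n_markers:
        raise IndexError(f"marker index {j} out of range")
    d = cohort.dosages[:, j]
    ok = ~np.isnan(d)

    def counts(mask: np.ndarray) -> GenotypeCounts:
        dd = d[mask & ok]
        return GenotypeCounts(
            int((dd == 0).sum()), int((dd == 1).sum()), int((dd == 2).sum())
        )

    return counts(cohort.is_case), counts(~cohort.is_case)
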
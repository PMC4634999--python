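"""Cohort tabulation and genotype-phenotype statistics.

The study cohort is 53 tuberous sclerosis (TSC) subjects in whom
conventional diagnostic testing found no mutation ("no mutation
identified", NMI).  Each subject carries per-organ counts of major
diagnostic features over four organ systems — skin, brain (CNS), heart,
and kidney/lung (renal angiomyolipoma and pulmonary LAM share a
pathogenesis and are merged into one system) — plus the mutation found by
the deep-sequencing re-analysis: heterozygous, mosaic (allele fraction
below 50%), or persistently NMI.

Binary feature associations use the Pearson chi-square test; quantitative
comparisons use the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ORGAN_SYSTEMS = ("skin", "brain", "heart", "kidney_lung")

#: sha256 of the packaged Table 1 transcription; guards silent fixture edits.
_TABLE1_SHA256 = "806738e9cda45a0125e2a4c8294bba1a4ac87609b08f5be307b1dcbfd64b9beb"


@dataclass
class SubjectRecord:
    """One study subject with phenotype and mutation-detection status."""

    subject_id: str
    status: str  # "heterozygous" | "mosaic" | "persistent_NMI"
    gene: str  # "TSC1" | "TSC2" | "none"
    mutation: str = ""
    mutation_type: str = "none"  # nonsense|missense|indel|splice|large_del|none
    af: float | None = None  # mutant allele fraction; None for skin-only detections
    tissues: str = ""
    age_years: float | None = None
    sex: str = ""
    organ_majors: dict[str, int] = field(default_factory=dict)
    familial: bool = False

    def __post_init__(self) -> None:
        if (self.status == "persistent_NMI") != (self.gene == "none"):
            raise ValueError(
                f"{self.subject_id}: status {self.status!r} inconsistent with gene {self.gene!r}"
            )
        for organ in ORGAN_SYSTEMS:
            self.organ_majors.setdefault(organ, 0)
            if self.organ_majors[organ] < 0:
                raise ValueError(f"{self.subject_id}: negative major-feature count")

    @property
    def identified(self) -> bool:
        return self.status != "persistent_NMI"

    @property
    def skin_only(self) -> bool:
        """Mutation demonstrated only in skin-lesion DNA (no blood/saliva AF)."""
        return self.identified and self.af is None


def organ_systems_involved(subject: SubjectRecord) -> int:
    """Number of organ systems (0-4) with at least one major feature."""
    return sum(subject.organ_majors[o] > 0 for o in ORGAN_SYSTEMS)


def major_feature_total(subject: SubjectRecord) -> int:
    """Total count of major diagnostic features across all organ systems."""
    return sum(subject.organ_majors[o] for o in ORGAN_SYSTEMS)


@dataclass(frozen=True)
class CohortSummary:
    """Headline tabulations of a cohort."""

    n_subjects: int
    n_with_mutation: int
    frac_identified: float
    n_heterozygous: int
    n_mosaic: int
    frac_mosaic_of_identified: float
    n_splice: int
    frac_splice_of_identified: float
    n_tsc1: int
    n_tsc2: int
    n_af_below_5pct: int
    n_af_below_1pct: int
    n_skin_only: int


def summarize_cohort(subjects: Sequence[SubjectRecord]) -> CohortSummary:
    """Compute the headline fractions and AF bins of a cohort.

    Skin-only detections (no measurable blood/saliva AF) are counted in the
    < 5% AF bin and reported separately; the < 1% bin counts measured AFs
    only.
    """
    n = len(subjects)
    identified = [s for s in subjects if s.identified]
    n_id = len(identified)
    n_mosaic = sum(s.status == "mosaic" for s in identified)
    n_splice = sum(s.mutation_type == "splice" for s in identified)
    af_below_5 = sum(1 for s in identified if s.skin_only or (s.af is not None and s.af < 0.05))
    af_below_1 = sum(1 for s in identified if s.af is not None and s.af < 0.01)
    return CohortSummary(
        n_subjects=n,
        n_with_mutation=n_id,
        frac_identified=n_id / n if n else 0.0,
        n_heterozygous=sum(s.status == "heterozygous" for s in identified),
        n_mosaic=n_mosaic,
        frac_mosaic_of_identified=n_mosaic / n_id if n_id else 0.0,
        n_splice=n_splice,
        frac_splice_of_identified=n_splice / n_id if n_id else 0.0,
        n_tsc1=sum(s.gene == "TSC1" for s in identified),
        n_tsc2=sum(s.gene == "TSC2" for s in identified),
        n_af_below_5pct=af_below_5,
        n_af_below_1pct=af_below_1,
        n_skin_only=sum(s.skin_only for s in identified),
    )


def group_medians(
    subjects: Iterable[SubjectRecord],
    by: Callable[[SubjectRecord], str] = lambda s: s.status,
    value: Callable[[SubjectRecord], float] = major_feature_total,
) -> dict[str, float]:
    """Median of ``value`` per group (mean of the central pair for even n)."""
    groups: dict[str, list[float]] = {}
    for s in subjects:
        groups.setdefault(by(s), []).append(value(s))
    return {g: float(median(v)) for g, v in groups.items()}


def organ_status_table(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Contingency table: mutation status x number of organ systems involved."""
    statuses = ("heterozygous", "mosaic", "persistent_NMI")
    counts = {st: {} for st in statuses}
    levels = sorted({organ_systems_involved(s) for s in subjects})
    for st in statuses:
        for lv in levels:
            counts[st][lv] = sum(
                1 for s in subjects if s.status == st and organ_systems_involved(s) == lv
            )
    return pd.DataFrame(counts).T


def chi_square_test(
    contingency_table, yates_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table.

    Returns (statistic, degrees of freedom, p).  No continuity correction by
    default; Yates correction available for 2x2 tables.  Zero marginals are
    an error (expected counts must be positive).
    """
    table = np.asarray(contingency_table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=yates_correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The exact null distribution of U is used for small tie-free samples
    (n_a * n_b <= 400); otherwise the normal approximation with midrank tie
    correction and continuity correction.  Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) * len(b) <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _fixture_path() -> Path:
    return Path(str(resources.files("mosaicscan").joinpath("data", "table1.tsv")))


def load_table1(path: str | Path | None = None, verify_checksum: bool = True) -> list[SubjectRecord]:
    """Load the packaged 53-subject cohort table (or a compatible TSV).

    The packaged fixture's content hash is verified so a silently edited
    transcription cannot masquerade as the study table.
    """
    if path is None:
        path = _fixture_path()
        if verify_checksum:
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            if digest != _TABLE1_SHA256:
                raise ValueError(
                    f"table1.tsv checksum mismatch: {digest} != {_TABLE1_SHA256}"
                )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                status=row["status"],
                gene=row["gene"] or "none",
                mutation=row["mutation"],
                mutation_type=row["mutation_type"] or "none",
                af=float(row["af"]) if row["af"] else None,
                tissues=row["tissues"],
                age_years=float(row["age_years"]) if row["age_years"] else None,
                sex=row["sex"],
                organ_majors={
                    organ: int(row[organ] or 0) for organ in ORGAN_SYSTEMS
                },
                familial=row["familial"] == "yes",
            )
        )
    return subjects
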
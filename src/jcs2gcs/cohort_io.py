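"""Cohort containers, CSV I/O, ICD-10 chapter classification and summaries.

A cohort is an ordered collection of paired (JCS, GCS) observations with
optional covariates: age, sex, ambulance (EMS) use, hospital admission, and
the ICD-10 code of the primary ED diagnosis.  Diagnoses are grouped into the
17 chapter-style categories used in general-ED case-mix tables, keyed to the
first letter of the ICD-10 code.
"""

from __future__ import annotations

import csv
import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .scales import GCSValue, JCSValue, ScaleError, validate_gcs, validate_jcs

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Observation",
    "Cohort",
    "CohortReadError",
    "ReadResult",
    "read_cohort",
    "write_cohort",
    "icd10_chapter",
    "ICD10_CHAPTERS",
    "AGE_BINS",
    "summarize_cohort",
    "CohortSummary",
]


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


# Accepted spellings on read; anything else maps to UNKNOWN.
_SEX_CODES = {
    "m": Sex.MALE, "male": Sex.MALE, "1": Sex.MALE,
    "f": Sex.FEMALE, "female": Sex.FEMALE, "2": Sex.FEMALE,
}


@dataclass(frozen=True)
class Observation:
    """One patient: paired JCS and GCS plus optional covariates."""

    jcs: JCSValue
    gcs: GCSValue
    age: int | None = None
    sex: Sex | None = None
    ems_use: bool | None = None
    admitted: bool | None = None
    icd10: str | None = None

    def __post_init__(self) -> None:
        if self.age is not None and (not isinstance(self.age, int) or self.age < 0):
            raise ValueError(f"age must be a non-negative integer, got {self.age!r}")


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of observations with provenance metadata."""

    observations: tuple[Observation, ...]
    label: str = "cohort"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def __getitem__(self, idx: int) -> Observation:
        return self.observations[idx]

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[int, int]],
        label: str = "cohort",
        provenance: str = "",
    ) -> "Cohort":
        """Build a covariate-free cohort from raw (jcs, gcs) integer pairs."""
        obs = tuple(
            Observation(jcs=validate_jcs(j), gcs=validate_gcs(g)) for j, g in pairs
        )
        return cls(observations=obs, label=label, provenance=provenance)

    def filter(self, predicate, provenance_note: str = "") -> "Cohort":
        """Sub-cohort of observations satisfying ``predicate``; order kept."""
        kept = tuple(o for o in self.observations if predicate(o))
        note = f"{self.provenance}; {provenance_note}".strip("; ")
        return replace(self, observations=kept, provenance=note)


class CohortReadError(ValueError):
    """Raised on unreadable cohort files or, in strict mode, invalid rows."""


@dataclass(frozen=True)
class ReadResult:
    """A read cohort plus the tally of rows dropped in lenient mode."""

    cohort: Cohort
    n_excluded: int
    exclusion_reasons: tuple[str, ...] = ()


_COLUMNS = ("jcs", "gcs", "age", "sex", "ems", "admitted", "icd10")


def _parse_bool(cell: str) -> bool:
    if cell in ("0", "1"):
        return cell == "1"
    raise ValueError(f"boolean cell must be 0 or 1, got {cell!r}")


def _parse_row(row: dict[str, str]) -> Observation:
    jcs = validate_jcs(int(row["jcs"]))
    gcs = validate_gcs(int(row["gcs"]))
    age = None
    if row.get("age", "").strip():
        age = int(row["age"])
    sex = None
    if row.get("sex", "").strip():
        sex = _SEX_CODES.get(row["sex"].strip().lower(), Sex.UNKNOWN)
    ems = None
    if row.get("ems", "").strip():
        ems = _parse_bool(row["ems"].strip())
    admitted = None
    if row.get("admitted", "").strip():
        admitted = _parse_bool(row["admitted"].strip())
    icd10 = row.get("icd10", "").strip() or None
    return Observation(jcs=jcs, gcs=gcs, age=age, sex=sex,
                       ems_use=ems, admitted=admitted, icd10=icd10)


def read_cohort(path: str | Path, strict: bool = True, label: str | None = None) -> ReadResult:
    """Read a cohort CSV (header ``jcs,gcs[,age,sex,ems,admitted,icd10]``).

    In strict mode any invalid row aborts with its line number.  In lenient
    mode invalid rows are dropped and tallied in the result, mirroring the
    exclusion flow of registry studies that drop records missing either
    scale.
    """
    path = Path(path)
    try:
        fh = open(path, "r", encoding="utf-8", newline="")
    except OSError as exc:
        raise CohortReadError(f"cannot read {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"jcs", "gcs"} <= set(reader.fieldnames):
            raise CohortReadError(
                f"{path}: header must contain at least 'jcs' and 'gcs' columns"
            )
        rows: list[Observation] = []
        excluded = 0
        reasons: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(_parse_row(row))
            except (ScaleError, ValueError, TypeError) as exc:
                if strict:
                    raise CohortReadError(f"{path}, line {lineno}: {exc}") from exc
                excluded += 1
                reasons.append(f"line {lineno}: {exc}")
    cohort = Cohort(
        observations=tuple(rows),
        label=label or path.stem,
        provenance=f"read from {path}",
    )
    return ReadResult(cohort=cohort, n_excluded=excluded,
                      exclusion_reasons=tuple(reasons))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV with the full column set; missing cells empty."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for o in cohort:
            writer.writerow([
                int(o.jcs),
                int(o.gcs),
                "" if o.age is None else o.age,
                "" if o.sex is None else o.sex.value,
                "" if o.ems_use is None else int(o.ems_use),
                "" if o.admitted is None else int(o.admitted),
                o.icd10 or "",
            ])


# -- ICD-10 chapter classification ----------------------------------------

#: 17-category diagnosis grouping keyed to the first letter of the ICD-10
#: code, as used in general-ED case-mix tables.
ICD10_CHAPTERS: dict[str, str] = {
    **dict.fromkeys("AB", "infectious"),
    **dict.fromkeys("CD", "neoplasms"),
    "E": "endocrine_metabolic",
    "F": "mental_behavioral",
    "G": "nervous",
    "H": "eye_ear",
    "I": "circulatory",
    "J": "respiratory",
    "K": "digestive",
    "L": "skin",
    "M": "musculoskeletal",
    "N": "genitourinary",
    **dict.fromkeys("OP", "pregnancy_perinatal"),
    "R": "symptoms_signs",
    **dict.fromkeys("ST", "injury_poisoning"),
    **dict.fromkeys("XZQ", "others"),
}

#: Chapter labels in fixed presentation order (the 17 categories).
CHAPTER_ORDER: tuple[str, ...] = (
    "infectious", "neoplasms", "endocrine_metabolic", "mental_behavioral",
    "nervous", "eye_ear", "circulatory", "respiratory", "digestive", "skin",
    "musculoskeletal", "genitourinary", "pregnancy_perinatal",
    "symptoms_signs", "injury_poisoning", "others", "missing",
)

# Letters outside the enumerated scheme (U, V, W, Y); folded into "others"
# with a warning so case-mix tables stay comparable.
_UNLISTED_LETTERS = set("UVWY")


def icd10_chapter(code: str | None) -> str:
    """Chapter label for an ICD-10 code, by its first letter.

    Total and case-insensitive: empty or unparseable input returns
    ``"missing"``; letters outside the enumerated scheme fold into
    ``"others"`` with a logged warning.
    """
    if code is None:
        return "missing"
    stripped = code.strip().upper()
    if not stripped or not stripped[0].isalpha():
        return "missing"
    letter = stripped[0]
    if letter in _UNLISTED_LETTERS:
        logger.warning(
            "ICD-10 letter %r is outside the 17-category scheme; mapped to 'others'",
            letter,
        )
        return "others"
    return ICD10_CHAPTERS.get(letter, "missing")


# -- Descriptive summary ----------------------------------------------------

#: Age bins used in baseline-characteristics tables: ≤34, 35–54, 55–64,
#: 65–84, ≥85 years.
AGE_BINS: tuple[tuple[int, int], ...] = (
    (0, 34), (35, 54), (55, 64), (65, 84), (85, 200),
)

_AGE_BIN_LABELS = ("<=34", "35-54", "55-64", "65-84", ">=85")


def _lower_median(sorted_vals: Sequence[int]) -> int:
    # order statistic at position ceil(n/2); identical convention to derive
    return sorted_vals[(len(sorted_vals) - 1) // 2]


def _type1_quantile(sorted_vals: Sequence[int], p: float) -> int:
    # nearest-order-statistic (type-1) quantile
    import math

    n = len(sorted_vals)
    idx = max(1, math.ceil(p * n))
    return sorted_vals[idx - 1]


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive characteristics of a cohort (baseline table style)."""

    n: int
    age_median: int | None
    age_q1: int | None
    age_q3: int | None
    age_bin_counts: dict[str, int]
    age_missing: int
    sex_counts: dict[str, int]
    sex_missing: int
    ems_count: int
    ems_missing: int
    admitted_count: int
    admitted_missing: int
    icd10_chapter_counts: dict[str, int]

    def as_rows(self) -> list[tuple[str, int, float]]:
        """(label, count, percent-of-n) rows in fixed presentation order."""
        rows: list[tuple[str, int, float]] = []
        for label in _AGE_BIN_LABELS:
            c = self.age_bin_counts[label]
            rows.append((f"age {label}", c, 100.0 * c / self.n))
        rows.append(("sex male", self.sex_counts["male"], 100.0 * self.sex_counts["male"] / self.n))
        rows.append(("ems use", self.ems_count, 100.0 * self.ems_count / self.n))
        rows.append(("admission", self.admitted_count, 100.0 * self.admitted_count / self.n))
        for label in CHAPTER_ORDER:
            c = self.icd10_chapter_counts.get(label, 0)
            rows.append((f"icd10 {label}", c, 100.0 * c / self.n))
        return rows


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Baseline-characteristics summary: median/IQR age, age bins, sex,
    EMS use, admission, and ICD-10 chapter distribution.

    Percentages are over cohort size; missing optional fields are tallied
    separately.  Median and quartiles use the lower-median / type-1
    convention shared with the table-derivation module.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")

    ages = sorted(o.age for o in cohort if o.age is not None)
    age_median = age_q1 = age_q3 = None
    if ages:
        age_median = _lower_median(ages)
        age_q1 = _type1_quantile(ages, 0.25)
        age_q3 = _type1_quantile(ages, 0.75)

    bin_counts = dict.fromkeys(_AGE_BIN_LABELS, 0)
    for o in cohort:
        if o.age is None:
            continue
        for (lo, hi), label in zip(AGE_BINS, _AGE_BIN_LABELS):
            if lo <= o.age <= hi:
                bin_counts[label] += 1
                break

    sex_counts = {"male": 0, "female": 0, "unknown": 0}
    sex_missing = 0
    for o in cohort:
        if o.sex is None:
            sex_missing += 1
        else:
            sex_counts[o.sex.value] += 1

    chapter_counts = dict.fromkeys(CHAPTER_ORDER, 0)
    for o in cohort:
        chapter_counts[icd10_chapter(o.icd10)] += 1

    return CohortSummary(
        n=len(cohort),
        age_median=age_median,
        age_q1=age_q1,
        age_q3=age_q3,
        age_bin_counts=bin_counts,
        age_missing=sum(1 for o in cohort if o.age is None),
        sex_counts=sex_counts,
        sex_missing=sex_missing,
        ems_count=sum(1 for o in cohort if o.ems_use),
        ems_missing=sum(1 for o in cohort if o.ems_use is None),
        admitted_count=sum(1 for o in cohort if o.admitted),
        admitted_missing=sum(1 for o in cohort if o.admitted is None),
        icd10_chapter_counts=chapter_counts,
    )
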
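"""Domain types for the two coma scales and the published conversion table.

The Japan Coma Scale (JCS) grades consciousness into ten categories keyed to
arousability: 0 (alert), 1–3 (awake without stimuli), 10–30 (arousable by
stimuli), 100–300 (unarousable).  The Glasgow Coma Scale (GCS) total score
runs from 3 (deep coma) to 15 (fully conscious).  A conversion table assigns
each JCS category a single predicted GCS value; the published reference table
was derived as the per-category median GCS in a multicentre emergency-
department development cohort.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "JCS_CODES",
    "GCS_MIN",
    "GCS_MAX",
    "JCSGrade",
    "JCSValue",
    "GCSValue",
    "TableSource",
    "ConversionTable",
    "ScaleError",
    "MissingEntryError",
    "validate_jcs",
    "validate_gcs",
    "published_table",
    "convert",
    "relative_window",
]

#: The ten admissible JCS category codes, in severity order.  The codes are
#: labels, not magnitudes: severity ordering is position in this tuple.
JCS_CODES: tuple[int, ...] = (0, 1, 2, 3, 10, 20, 30, 100, 200, 300)

GCS_MIN = 3
GCS_MAX = 15


class ScaleError(ValueError):
    """Raised when a raw value is not an admissible scale score."""


class MissingEntryError(KeyError):
    """Raised when a conversion table lacks an entry for a JCS category."""

    def __init__(self, code: int) -> None:
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; give a real message
        return f"conversion table has no entry for JCS category {self.code}"


class JCSGrade(enum.Enum):
    """Arousability grade of a JCS category."""

    ALERT = "alert"
    SINGLE_DIGIT = "single_digit"
    DOUBLE_DIGIT = "double_digit"
    TRIPLE_DIGIT = "triple_digit"


def _grade_of(code: int) -> JCSGrade:
    if code == 0:
        return JCSGrade.ALERT
    if code in (1, 2, 3):
        return JCSGrade.SINGLE_DIGIT
    if code in (10, 20, 30):
        return JCSGrade.DOUBLE_DIGIT
    return JCSGrade.TRIPLE_DIGIT


@dataclass(frozen=True, order=False)
class JCSValue:
    """A validated JCS category code with its arousability grade."""

    value: int

    def __post_init__(self) -> None:
        if not isinstance(self.value, int) or isinstance(self.value, bool):
            raise ScaleError(f"JCS score must be an integer, got {self.value!r}")
        if self.value not in JCS_CODES:
            raise ScaleError(
                f"invalid JCS score {self.value}: admissible codes are "
                f"{', '.join(map(str, JCS_CODES))}"
            )

    @property
    def grade(self) -> JCSGrade:
        return _grade_of(self.value)

    @property
    def severity_rank(self) -> int:
        """Position in the severity ordering 0 < 1 < 2 < 3 < 10 < ... < 300."""
        return JCS_CODES.index(self.value)

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class GCSValue:
    """A validated total GCS score (3–15)."""

    value: int

    def __post_init__(self) -> None:
        if not isinstance(self.value, int) or isinstance(self.value, bool):
            raise ScaleError(f"GCS score must be an integer, got {self.value!r}")
        if not GCS_MIN <= self.value <= GCS_MAX:
            raise ScaleError(
                f"invalid GCS score {self.value}: total score must be in "
                f"[{GCS_MIN}, {GCS_MAX}]"
            )

    def __int__(self) -> int:
        return self.value


def validate_jcs(raw: int) -> JCSValue:
    """Validate a raw integer as a JCS category code.

    Suffix-modified scores such as ``"30R"`` are not integers and are
    rejected rather than stripped: silent coercion would hide data errors.
    """
    return JCSValue(raw)


def validate_gcs(raw: int) -> GCSValue:
    """Validate a raw integer as a total GCS score in 3–15."""
    return GCSValue(raw)


class TableSource(enum.Enum):
    PUBLISHED = "published"
    DERIVED = "derived"


@dataclass(frozen=True)
class ConversionTable:
    """Mapping from JCS category to predicted GCS total score.

    A published table is complete over the ten categories; a derived table
    may be partial when some categories were absent from the development
    cohort.  ``per_category_n`` records the observation count behind each
    entry (zero for the published reference table).
    """

    entries: Mapping[int, int]
    per_category_n: Mapping[int, int] = field(default_factory=dict)
    source: TableSource = TableSource.DERIVED

    def __post_init__(self) -> None:
        for jcs, gcs in self.entries.items():
            validate_jcs(jcs)
            validate_gcs(gcs)
        if self.source is TableSource.PUBLISHED and set(self.entries) != set(JCS_CODES):
            raise ScaleError("a published table must cover all 10 JCS categories")

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    def __getitem__(self, code: int) -> int:
        try:
            return self.entries[code]
        except KeyError:
            raise MissingEntryError(code) from None

    @property
    def categories(self) -> tuple[int, ...]:
        """Covered JCS categories in severity order."""
        return tuple(c for c in JCS_CODES if c in self.entries)

    def is_monotone(self) -> bool:
        """True when predicted GCS is non-increasing with JCS severity."""
        values = [self.entries[c] for c in self.categories]
        return all(a >= b for a, b in zip(values, values[1:]))

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as two-column CSV (``jcs,gcs``), UTF-8, LF."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["jcs", "gcs"])
            for code in self.categories:
                writer.writerow([code, self.entries[code]])

    @classmethod
    def from_csv(cls, path: str | Path, source: TableSource = TableSource.DERIVED) -> "ConversionTable":
        """Read and re-validate a table from two-column CSV."""
        entries: dict[int, int] = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"jcs", "gcs"} <= set(reader.fieldnames):
                raise ScaleError(f"{path}: expected header containing 'jcs,gcs'")
            for i, row in enumerate(reader, start=2):
                try:
                    jcs = int(row["jcs"])
                    gcs = int(row["gcs"])
                except (TypeError, ValueError) as exc:
                    raise ScaleError(f"{path}: non-integer cell at line {i}") from exc
                if jcs in entries:
                    raise ScaleError(f"{path}: duplicate JCS category {jcs} at line {i}")
                entries[int(validate_jcs(jcs))] = int(validate_gcs(gcs))
        return cls(entries=entries, source=source)


#: Reference conversion table: per-category median GCS in the development
#: cohort of a three-centre Japanese ED study.
_PUBLISHED_ENTRIES: dict[int, int] = {
    0: 15,
    1: 15,
    2: 14,
    3: 13,
    10: 12,
    20: 12,
    30: 9,
    100: 7,
    200: 6,
    300: 3,
}


def published_table() -> ConversionTable:
    """The published JCS→GCS reference conversion table."""
    return ConversionTable(
        entries=dict(_PUBLISHED_ENTRIES),
        per_category_n={c: 0 for c in JCS_CODES},
        source=TableSource.PUBLISHED,
    )


def convert(jcs: JCSValue | int, table: ConversionTable | None = None) -> GCSValue:
    """Convert a JCS category to its predicted GCS total score.

    Defaults to the published reference table.  Raises
    :class:`MissingEntryError` when a partial derived table lacks the
    category.
    """
    if table is None:
        table = published_table()
    code = int(validate_jcs(int(jcs)))
    return GCSValue(table[code])


def relative_window(
    jcs: JCSValue | int, table: ConversionTable | None = None
) -> tuple[GCSValue, GCSValue]:
    """The ±1-point GCS window around the converted value, clipped to [3, 15].

    This is the acceptance region for relative concordance: an observed GCS
    inside the window counts as agreeing with the conversion.  Clipping keeps
    the window well-defined at predictions of 3 and 15 and cannot change any
    concordance classification, since observed GCS values outside [3, 15] are
    impossible.
    """
    predicted = int(convert(jcs, table))
    low = max(GCS_MIN, predicted - 1)
    high = min(GCS_MAX, predicted + 1)
    return GCSValue(low), GCSValue(high)
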
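"""Derive a JCS→GCS conversion table from a development cohort.

The conversion rule is deliberately simple: for each JCS category, the
predicted GCS is the median of the observed GCS values in that category.
Both scales are ordinal, so no regression model is fit — the median is the
natural centre for an ordered categorical outcome.

Medians here are *lower medians*: the order statistic at position ⌈n/2⌉ of
the sorted values.  For odd n this is the usual middle value; for even n it
is the lower of the two middle values, which is deterministic, always an
observed integer score, and conservative toward severity (GCS is lower when
more impaired).  The raw sample median (possibly half-integer) is reported
alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .cohort_io import Cohort
from .scales import JCS_CODES, ConversionTable, TableSource

__all__ = [
    "DerivationReport",
    "BoxplotStats",
    "derive_conversion_table",
    "boxplot_stats",
    "lower_median",
    "type1_quantile",
]


def lower_median(values: Sequence[int]) -> int:
    """Lower median: order statistic at position ⌈n/2⌉ of the sorted values."""
    if not values:
        raise ValueError("lower_median of empty sequence")
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def type1_quantile(values: Sequence[int], p: float) -> int:
    """Nearest-order-statistic (type-1) quantile: sorted[⌈pn⌉] (1-based).

    Consistent with :func:`lower_median` at p = 0.5.
    """
    if not values:
        raise ValueError("quantile of empty sequence")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    s = sorted(values)
    idx = max(1, math.ceil(p * len(s)))
    return s[idx - 1]


def _raw_median(values: Sequence[int]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0


@dataclass(frozen=True)
class DerivationReport:
    """A derived conversion table with its derivation diagnostics."""

    table: ConversionTable
    per_category_median_raw: dict[int, float]
    per_category_n: dict[int, int]
    warnings: tuple[str, ...] = ()

    def to_csv(self, path) -> None:
        """Write ``jcs,gcs,n,raw_median`` rows in severity order."""
        import csv

        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["jcs", "gcs", "n", "raw_median"])
            for code in self.table.categories:
                writer.writerow([
                    code,
                    self.table.entries[code],
                    self.per_category_n[code],
                    self.per_category_median_raw[code],
                ])


def derive_conversion_table(
    cohort: Cohort, sparsity_threshold: int = 10
) -> DerivationReport:
    """Derive a conversion table as the per-category lower-median GCS.

    Categories absent from the cohort are absent from the table (the table
    is partial, never imputed).  Warnings are attached when the derived
    table is not monotone non-increasing with JCS severity, and for any
    category whose count falls below ``sparsity_threshold`` — intermediate
    consciousness levels are typically sparse in general-ED cohorts, and a
    median over a handful of patients is fragile.

    The derivation depends only on the multiset of GCS values per category,
    so it is invariant to row order.
    """
    if len(cohort) == 0:
        raise ValueError("cannot derive a conversion table from an empty cohort")

    by_category: dict[int, list[int]] = {}
    for obs in cohort:
        by_category.setdefault(int(obs.jcs), []).append(int(obs.gcs))

    entries: dict[int, int] = {}
    raw: dict[int, float] = {}
    counts: dict[int, int] = {}
    warnings: list[str] = []
    for code in JCS_CODES:
        if code not in by_category:
            continue
        values = by_category[code]
        entries[code] = lower_median(values)
        raw[code] = _raw_median(values)
        counts[code] = len(values)
        if len(values) < sparsity_threshold:
            warnings.append(
                f"JCS {code}: only {len(values)} observations "
                f"(threshold {sparsity_threshold}); median may be unstable"
            )

    table = ConversionTable(
        entries=entries, per_category_n=dict(counts), source=TableSource.DERIVED
    )
    if not table.is_monotone():
        warnings.append(
            "derived table is not monotone non-increasing with JCS severity; "
            "no isotonic correction is applied"
        )
    return DerivationReport(
        table=table,
        per_category_median_raw=raw,
        per_category_n=counts,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary of GCS within one JCS category.

    Quartiles are type-1 (nearest order statistic); whiskers extend to the
    most extreme observed values within 1.5 × IQR of the box edges, the
    usual Tukey convention.
    """

    n: int
    q1: int
    median: int
    q3: int
    whisker_low: int
    whisker_high: int


def boxplot_stats(cohort: Cohort) -> dict[int, BoxplotStats]:
    """Per-JCS-category five-number summaries of GCS.

    Supports regenerating the development-cohort box plot of GCS against
    JCS.  Categories with no observations are omitted, not zero-filled.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")

    by_category: dict[int, list[int]] = {}
    for obs in cohort:
        by_category.setdefault(int(obs.jcs), []).append(int(obs.gcs))

    out: dict[int, BoxplotStats] = {}
    for code in JCS_CODES:
        if code not in by_category:
            continue
        values = sorted(by_category[code])
        q1 = type1_quantile(values, 0.25)
        q3 = type1_quantile(values, 0.75)
        iqr = q3 - q1
        in_fence = [v for v in values if q1 - 1.5 * iqr <= v <= q3 + 1.5 * iqr]
        out[code] = BoxplotStats(
            n=len(values),
            q1=q1,
            median=lower_median(values),
            q3=q3,
            whisker_low=min(in_fence),
            whisker_high=max(in_fence),
        )
    return out
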
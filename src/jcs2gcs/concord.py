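"""Concordance validation of a JCS→GCS conversion table.

Two agreement statistics are computed on a validation cohort:

* **absolute concordance** — the fraction of patients whose observed GCS
  exactly equals the table-converted GCS;
* **relative concordance** — the fraction whose observed GCS lies within
  ±1 point of the converted GCS.

Each proportion carries an exact two-sided Clopper–Pearson 95% confidence
interval.  Because patients who are alert (JCS = 0, almost always GCS 15)
trivially agree and inflate both rates, a sensitivity analysis recomputes
both statistics after excluding them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from scipy.stats import beta as _beta

from .cohort_io import Cohort
from .scales import ConversionTable, published_table

__all__ = [
    "ConcordanceKind",
    "ConcordanceResult",
    "ValidationReport",
    "clopper_pearson",
    "absolute_concordance",
    "relative_concordance",
    "exclude_alert",
    "validation_report",
    "format_pct",
]


class ConcordanceKind(enum.Enum):
    ABSOLUTE = "absolute"
    RELATIVE = "relative"


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided Clopper–Pearson confidence interval for a proportion.

    Bounds are Beta-distribution quantiles:
    lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k), with the lower
    bound 0 when k = 0 and the upper bound 1 when k = n.  The interval is
    exact (coverage ≥ 1−α for every true proportion), hence conservative.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = successes
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class ConcordanceResult:
    """A concordance proportion with its exact binomial confidence interval."""

    kind: ConcordanceKind
    successes: int
    n: int
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.n:
            raise ValueError("successes must be in [0, n]")
        if not self.ci_low <= self.proportion <= self.ci_high:
            raise ValueError("confidence interval must bracket the proportion")

    @property
    def proportion(self) -> float:
        return self.successes / self.n

    def __str__(self) -> str:
        return (
            f"{self.kind.value} concordance {format_pct(self.proportion)}% "
            f"({format_pct(self.ci_low)}-{format_pct(self.ci_high)}%), "
            f"{self.successes}/{self.n}"
        )


def format_pct(fraction: float) -> str:
    """Format a fraction as a percentage at one decimal, round-half-even."""
    return str(Decimal(repr(fraction * 100.0)).quantize(Decimal("0.1"), ROUND_HALF_EVEN))


def _concordance(
    cohort: Cohort,
    table: ConversionTable,
    kind: ConcordanceKind,
    alpha: float,
) -> ConcordanceResult:
    if len(cohort) == 0:
        raise ValueError("cannot compute concordance on an empty cohort")
    tol = 0 if kind is ConcordanceKind.ABSOLUTE else 1
    successes = 0
    for obs in cohort:
        predicted = table[int(obs.jcs)]  # raises MissingEntryError if partial
        if abs(int(obs.gcs) - predicted) <= tol:
            successes += 1
    low, high = clopper_pearson(successes, len(cohort), alpha)
    return ConcordanceResult(
        kind=kind, successes=successes, n=len(cohort),
        ci_low=low, ci_high=high, alpha=alpha,
    )


def absolute_concordance(
    cohort: Cohort, table: ConversionTable | None = None, alpha: float = 0.05
) -> ConcordanceResult:
    """Exact-match concordance of observed GCS with the converted GCS."""
    return _concordance(cohort, table or published_table(),
                        ConcordanceKind.ABSOLUTE, alpha)


def relative_concordance(
    cohort: Cohort, table: ConversionTable | None = None, alpha: float = 0.05
) -> ConcordanceResult:
    """±1-point concordance of observed GCS with the converted GCS.

    Always at least as large as absolute concordance on the same cohort:
    the ±1 window contains the exact match.
    """
    return _concordance(cohort, table or published_table(),
                        ConcordanceKind.RELATIVE, alpha)


def exclude_alert(cohort: Cohort) -> Cohort:
    """Sub-cohort with alert patients (JCS = 0) removed.

    The sensitivity analysis re-runs both concordance statistics on this
    sub-cohort, since alert patients' trivially correct conversions inflate
    agreement.
    """
    return cohort.filter(lambda o: int(o.jcs) != 0,
                         provenance_note="excluded JCS=0 (alert)")


@dataclass(frozen=True)
class ValidationReport:
    """Primary and alert-excluded concordance results for one cohort.

    ``sensitivity_*`` are None when every patient was alert (the sub-cohort
    is empty and the statistic is not computable — it is reported as absent,
    never fabricated).
    """

    primary_absolute: ConcordanceResult
    primary_relative: ConcordanceResult
    sensitivity_absolute: ConcordanceResult | None
    sensitivity_relative: ConcordanceResult | None

    def results(self) -> tuple[tuple[str, ConcordanceResult | None], ...]:
        """(analysis label, result) pairs in fixed report order."""
        return (
            ("primary", self.primary_absolute),
            ("primary", self.primary_relative),
            ("sensitivity", self.sensitivity_absolute),
            ("sensitivity", self.sensitivity_relative),
        )

    def to_csv_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for analysis, res in self.results():
            if res is None:
                rows.append({"analysis": analysis, "kind": "", "n": 0,
                             "successes": "", "proportion_pct": "not computable",
                             "ci_low_pct": "", "ci_high_pct": ""})
                continue
            rows.append({
                "analysis": analysis,
                "kind": res.kind.value,
                "n": res.n,
                "successes": res.successes,
                "proportion_pct": format_pct(res.proportion),
                "ci_low_pct": format_pct(res.ci_low),
                "ci_high_pct": format_pct(res.ci_high),
            })
        return rows

    def to_text(self) -> str:
        """Aligned plain-text report, outcomes-table style."""
        lines = ["Outcomes                     Percentage  (95% CI)"]
        blocks = (
            ("Primary analysis", self.primary_absolute, self.primary_relative),
            ("Sensitivity analysis", self.sensitivity_absolute, self.sensitivity_relative),
        )
        for title, abs_res, rel_res in blocks:
            n = abs_res.n if abs_res is not None else 0
            lines.append(f"{title} (n = {n})")
            for label, res in (("Absolute concordance", abs_res),
                               ("Relative concordance", rel_res)):
                if res is None:
                    lines.append(f"  {label:<26} not computable")
                else:
                    pct = format_pct(res.proportion) + "%"
                    ci = f"({format_pct(res.ci_low)}-{format_pct(res.ci_high)}%)"
                    lines.append(f"  {label:<26} {pct:>6}  {ci}")
        return "\n".join(lines)


def validation_report(
    cohort: Cohort, table: ConversionTable | None = None, alpha: float = 0.05
) -> ValidationReport:
    """Full validation: absolute and relative concordance on the whole
    cohort and on the alert-excluded sub-cohort."""
    table = table or published_table()
    sub = exclude_alert(cohort)
    sens_abs = sens_rel = None
    if len(sub) > 0:
        sens_abs = absolute_concordance(sub, table, alpha)
        sens_rel = relative_concordance(sub, table, alpha)
    return ValidationReport(
        primary_absolute=absolute_concordance(cohort, table, alpha),
        primary_relative=relative_concordance(cohort, table, alpha),
        sensitivity_absolute=sens_abs,
        sensitivity_relative=sens_rel,
    )
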
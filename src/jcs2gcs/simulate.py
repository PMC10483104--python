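"""Seeded synthetic ED-cohort generator.

The original development and validation cohorts are not publicly available,
so the package ships a generator that emulates the joint JCS–GCS structure
of a general emergency-department population: a JCS marginal dominated by
alert patients (JCS = 0), and a conditional GCS-given-JCS distribution whose
per-category population median equals a configurable target conversion
table.

The conditional distribution is a discretized symmetric triangular kernel on
the integers, centred at ``target_table[jcs] + miscalibration[jcs]`` with a
non-negative half-width ``dispersion``.  It is truncated to the GCS range
[3, 15] by *folding* out-of-range mass onto the nearer boundary, which keeps
the population median exactly at the centre for every dispersion.  At
dispersion 0 the draw is the centre with probability 1, so a perfectly
calibrated, dispersion-free cohort has absolute concordance exactly 1.

One integer seed drives every draw through a single NumPy generator; no
global state is touched, and identical configurations yield byte-identical
cohort CSVs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_io import Cohort, Observation, Sex
from .scales import (
    GCS_MAX,
    GCS_MIN,
    JCS_CODES,
    ConversionTable,
    published_table,
    validate_gcs,
    validate_jcs,
)

__all__ = [
    "SimConfig",
    "default_ed_marginal",
    "conditional_pmf",
    "expected_concordance",
    "generate_cohort",
]


def default_ed_marginal() -> dict[int, float]:
    """Default JCS marginal for a general adult ED population.

    Mass 0.675 at JCS 0 — most ED patients are alert — with mass decreasing
    over deeper grades.  The alert fraction matches the ratio implied by a
    validation cohort of 821 with 267 non-alert patients; the split of the
    remaining mass across non-alert categories is configuration chosen to
    exercise every category, not an empirical claim.
    """
    marginal = {
        0: 0.675,
        1: 0.080,
        2: 0.050,
        3: 0.020,
        10: 0.060,
        20: 0.035,
        30: 0.020,
        100: 0.025,
        200: 0.020,
        300: 0.015,
    }
    assert abs(sum(marginal.values()) - 1.0) < 1e-12
    return marginal


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    ``dispersion`` and ``miscalibration`` may be a single number (applied to
    every category) or a per-category mapping.  ``miscalibration`` shifts
    the conditional centre by an integer number of GCS points — useful for
    constructing cohorts whose absolute concordance is 0 but whose relative
    concordance is 1.
    """

    n: int
    jcs_marginal: dict[int, float] = field(default_factory=default_ed_marginal)
    target_table: ConversionTable = field(default_factory=published_table)
    dispersion: float | dict[int, float] = 1.0
    miscalibration: int | dict[int, int] = 0
    covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if set(self.jcs_marginal) - set(JCS_CODES):
            raise ValueError("jcs_marginal keys must be JCS category codes")
        total = sum(self.jcs_marginal.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"jcs_marginal must sum to 1, got {total}")
        if any(p < 0 for p in self.jcs_marginal.values()):
            raise ValueError("jcs_marginal probabilities must be non-negative")
        for code in self.jcs_marginal:
            if self.jcs_marginal[code] > 0 and code not in self.target_table:
                raise ValueError(f"target_table lacks an entry for JCS {code}")
            if self.dispersion_for(code) < 0:
                raise ValueError("dispersion must be non-negative")
            if self.jcs_marginal[code] > 0:
                center = self.center_for(code)
                if not GCS_MIN <= center <= GCS_MAX:
                    raise ValueError(
                        f"miscalibrated centre {center} for JCS {code} leaves "
                        f"the GCS range [{GCS_MIN}, {GCS_MAX}]"
                    )

    def dispersion_for(self, code: int) -> float:
        if isinstance(self.dispersion, dict):
            return float(self.dispersion.get(code, 0.0))
        return float(self.dispersion)

    def miscalibration_for(self, code: int) -> int:
        if isinstance(self.miscalibration, dict):
            return int(self.miscalibration.get(code, 0))
        return int(self.miscalibration)

    def center_for(self, code: int) -> int:
        return self.target_table[code] + self.miscalibration_for(code)

    def to_json(self) -> str:
        """JSON echo of the full configuration, including the seed."""
        payload = {
            "n": self.n,
            "jcs_marginal": {str(k): v for k, v in self.jcs_marginal.items()},
            "target_table": {str(k): self.target_table[k]
                             for k in self.target_table.categories},
            "dispersion": (
                {str(k): v for k, v in self.dispersion.items()}
                if isinstance(self.dispersion, dict) else self.dispersion
            ),
            "miscalibration": (
                {str(k): v for k, v in self.miscalibration.items()}
                if isinstance(self.miscalibration, dict) else self.miscalibration
            ),
            "covariates": self.covariates,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


def conditional_pmf(center: int, dispersion: float) -> dict[int, float]:
    """PMF of GCS given a category: folded discretized triangular kernel.

    Weights are ``max(0, dispersion + 1 − |offset|)`` on integer offsets;
    values falling outside [3, 15] are folded onto the nearer boundary.
    Folding (rather than renormalizing) preserves symmetry of cumulative
    mass about the centre, so the population lower median equals the centre
    for every dispersion — the property the median-based derivation relies
    on.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if not GCS_MIN <= center <= GCS_MAX:
        raise ValueError(f"centre {center} outside the GCS range")
    reach = math.ceil(dispersion)
    weights: dict[int, float] = {}
    for offset in range(-reach, reach + 1):
        w = dispersion + 1.0 - abs(offset)
        if w <= 0:
            continue
        value = min(GCS_MAX, max(GCS_MIN, center + offset))
        weights[value] = weights.get(value, 0.0) + w
    total = sum(weights.values())
    return {v: w / total for v, w in sorted(weights.items())}


def expected_concordance(config: SimConfig, table: ConversionTable | None = None,
                         tolerance: int = 0) -> float:
    """Analytic expected concordance of a generated cohort against a table.

    Sums, over JCS categories, the marginal probability times the conditional
    mass within ``tolerance`` points of the table's prediction.  With
    ``tolerance=0`` this is the expected absolute concordance; with 1, the
    expected relative concordance.  Exact (no simulation), so it serves as
    the analytic reference that Monte-Carlo estimates are checked against.
    """
    table = table or config.target_table
    total = 0.0
    for code, p in config.jcs_marginal.items():
        if p == 0:
            continue
        pmf = conditional_pmf(config.center_for(code), config.dispersion_for(code))
        predicted = table[code]
        total += p * sum(mass for v, mass in pmf.items()
                         if abs(v - predicted) <= tolerance)
    return total


# Covariate generation parameters: age-bin probabilities follow the
# validation-cohort case mix of a general adult ED (bins <=34, 35-54, 55-64,
# 65-84, >=85); sex/EMS/admission rates likewise.  For I/O and summary
# testing only — no claimed clinical realism.
_AGE_BIN_EDGES = ((17, 34), (35, 54), (55, 64), (65, 84), (85, 99))
_AGE_BIN_PROBS = (0.114, 0.189, 0.101, 0.463, 0.133)
_P_MALE = 0.53
_P_EMS = 0.663
_P_ADMIT = 0.486
_ICD10_LETTERS = ("I", "S", "R", "K", "J", "G", "E", "N", "A", "C", "F", "M", "")
_ICD10_PROBS = (0.16, 0.19, 0.16, 0.10, 0.06, 0.04, 0.04, 0.04, 0.02, 0.02,
                0.03, 0.02, 0.12)


def _draw_covariates(rng: np.random.Generator) -> dict:
    bin_idx = rng.choice(len(_AGE_BIN_PROBS), p=_AGE_BIN_PROBS)
    lo, hi = _AGE_BIN_EDGES[bin_idx]
    letter = _ICD10_LETTERS[rng.choice(len(_ICD10_PROBS), p=_ICD10_PROBS)]
    icd10 = f"{letter}{rng.integers(0, 100):02d}" if letter else None
    return {
        "age": int(rng.integers(lo, hi + 1)),
        "sex": Sex.MALE if rng.random() < _P_MALE else Sex.FEMALE,
        "ems_use": bool(rng.random() < _P_EMS),
        "admitted": bool(rng.random() < _P_ADMIT),
        "icd10": icd10,
    }


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a synthetic cohort under ``config``; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    codes = sorted(config.jcs_marginal, key=JCS_CODES.index)
    probs = np.array([config.jcs_marginal[c] for c in codes])
    probs = probs / probs.sum()  # guard float drift at 1e-9 scale
    jcs_idx = rng.choice(len(codes), size=config.n, p=probs)

    # One pmf per category; GCS drawn by inverse-CDF on a shared uniform
    # stream, vectorized per category.
    uniforms = rng.random(config.n)
    gcs_arr = np.empty(config.n, dtype=np.int64)
    for i, code in enumerate(codes):
        mask = jcs_idx == i
        if not mask.any():
            continue
        pmf = conditional_pmf(config.center_for(code), config.dispersion_for(code))
        values = np.array(list(pmf))
        cum = np.cumsum(list(pmf.values()))
        picks = np.searchsorted(cum, uniforms[mask], side="right")
        gcs_arr[mask] = values[np.minimum(picks, len(values) - 1)]

    observations = []
    for idx, gcs in zip(jcs_idx, gcs_arr):
        extra = _draw_covariates(rng) if config.covariates else {}
        observations.append(
            Observation(jcs=validate_jcs(codes[idx]), gcs=validate_gcs(int(gcs)),
                        **extra)
        )
    return Cohort(
        observations=tuple(observations),
        label=f"synthetic-seed{config.seed}",
        provenance=f"generate_cohort(n={config.n}, seed={config.seed})",
    )
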
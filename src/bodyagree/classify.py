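"""Lowest-quintile low-muscle-mass classification and diagnostic accuracy.

The 20th percentile of the reference-device distribution, derived per sex,
serves as the low-mass cut-off.  Both devices are classified against the
same sex-specific reference-derived cut-off (strict ``value < cutoff``),
the reference classification is treated as truth, and sensitivity /
specificity follow from the confusion counts.  Pooled ("all") results sum
the per-sex confusion tables before computing rates.

Fixed EWGSOP2 ALM-index cut-offs (male < 7.0, female < 6.0 kg/m²) are used
for the prevalence estimate only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .agreement import Measure, Stratum, measure_value
from .cohort import Cohort, Sex
from .errors import InsufficientDataError

__all__ = [
    "LOW_MASS_QUANTILE",
    "EWGSOP2_ALMI_CUTOFF",
    "CutoffClassification",
    "SubjectLabel",
    "Prevalence",
    "quintile_cutoff",
    "classify_low",
    "low_mass_labels",
    "diagnostic_table",
    "prevalence_ewgsop2",
]

LOW_MASS_QUANTILE = 0.20

#: Fixed EWGSOP2 ALM-index cut-offs, kg/m².
EWGSOP2_ALMI_CUTOFF = {Sex.MALE: 7.0, Sex.FEMALE: 6.0}


def quintile_cutoff(values, q: float = LOW_MASS_QUANTILE, method: str = "linear") -> float:
    """20th-percentile cut-off of a reference-value vector.

    ``method`` is any quantile convention accepted by :func:`numpy.quantile`;
    the default ``"linear"`` interpolates between order statistics at
    h = q·(n−1) (the "type 7" convention).  ``"weibull"`` gives the
    h = q·(n+1) convention used by some statistical packages.  Requires at
    least 5 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 5:
        raise InsufficientDataError("quintile cut-off needs at least 5 values")
    if not np.isfinite(arr).all():
        raise InsufficientDataError("quintile cut-off input must be finite")
    return float(np.quantile(arr, q, method=method))


def classify_low(value: float, cutoff: float) -> bool:
    """Low iff strictly below the cut-off; a value equal to it is normal."""
    return value < cutoff


@dataclass(frozen=True)
class SubjectLabel:
    """Per-subject classification of both devices against one cut-off."""

    subject_id: str
    sex: Sex
    ref_value: float
    cand_value: float
    cutoff: float
    ref_low: bool
    cand_low: bool


@dataclass(frozen=True)
class CutoffClassification:
    """Confusion table and rates for one measure × stratum.

    ``cutoff`` is None for the pooled stratum, whose counts are sums of the
    two sex-specific tables (each with its own cut-off).  Rates are NaN when
    their denominator is zero.
    """

    measure: Measure
    stratum: Stratum
    cutoff: Optional[float]
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_ref_low(self) -> int:
        return self.tp + self.fn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else math.nan


def low_mass_labels(
    cohort: Cohort, measure, quantile_method: str = "linear"
) -> Dict[str, SubjectLabel]:
    """Classify every subject on both devices, with per-sex cut-offs.

    Cut-offs are derived from the reference values of each sex separately
    (at least 5 subjects per sex required); both devices' values are then
    compared against the same cut-off.
    """
    measure = Measure(measure)
    labels: Dict[str, SubjectLabel] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        records = cohort.sex_records(sex)
        if not records:
            continue
        if len(records) < 5:
            raise InsufficientDataError(
                f"cannot derive a quintile cut-off for sex '{sex.value}' "
                f"with {len(records)} subjects (need >= 5)"
            )
        ref = np.array([measure_value(r, measure, "reference") for r in records])
        cutoff = quintile_cutoff(ref, method=quantile_method)
        for r in records:
            rv = measure_value(r, measure, "reference")
            cv = measure_value(r, measure, "candidate")
            labels[r.subject_id] = SubjectLabel(
                subject_id=r.subject_id,
                sex=sex,
                ref_value=rv,
                cand_value=cv,
                cutoff=cutoff,
                ref_low=classify_low(rv, cutoff),
                cand_low=classify_low(cv, cutoff),
            )
    return labels


def _counts(labels: Sequence[SubjectLabel]):
    tp = sum(1 for l in labels if l.ref_low and l.cand_low)
    fn = sum(1 for l in labels if l.ref_low and not l.cand_low)
    fp = sum(1 for l in labels if not l.ref_low and l.cand_low)
    tn = sum(1 for l in labels if not l.ref_low and not l.cand_low)
    return tp, fn, fp, tn


def diagnostic_table(
    cohort: Cohort, measure, stratum, quantile_method: str = "linear"
) -> CutoffClassification:
    """Confusion table of candidate vs. reference low-mass classification.

    The reference classification is truth.  For the pooled stratum the two
    per-sex tables (each using its own sex-specific cut-off) are summed
    before computing sensitivity and specificity.
    """
    measure = Measure(measure)
    stratum = Stratum(stratum)
    labels = low_mass_labels(cohort, measure, quantile_method=quantile_method)
    if stratum is Stratum.ALL:
        subset = list(labels.values())
        cutoff = None
    else:
        sex = Sex(stratum.value)
        subset = [l for l in labels.values() if l.sex is sex]
        if not subset:
            raise InsufficientDataError(f"no subjects in stratum '{stratum.value}'")
        cutoff = subset[0].cutoff
    tp, fn, fp, tn = _counts(subset)
    return CutoffClassification(
        measure=measure, stratum=stratum, cutoff=cutoff, tp=tp, fn=fn, fp=fp, tn=tn
    )


@dataclass(frozen=True)
class Prevalence:
    sex: Sex
    n_low: int
    n_total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_low / self.n_total

    @property
    def percent_int(self) -> int:
        """Nearest-integer percent for display (half rounds up)."""
        return int(math.floor(self.percent + 0.5))


def prevalence_ewgsop2(cohort: Cohort) -> Dict[Sex, Prevalence]:
    """Per-sex prevalence of low reference ALM-index under EWGSOP2 cut-offs."""
    out: Dict[Sex, Prevalence] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        records = cohort.sex_records(sex)
        if not records:
            continue
        cutoff = EWGSOP2_ALMI_CUTOFF[sex]
        n_low = sum(
            1
            for r in records
            if classify_low(measure_value(r, Measure.ALMI, "reference"), cutoff)
        )
        out[sex] = Prevalence(sex=sex, n_low=n_low, n_total=len(records))
    if not out:
        raise InsufficientDataError("cohort has no subjects")
    return out
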
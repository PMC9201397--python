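"""Agreement statistics for paired device measurements.

Implements the four validity criteria used to compare a candidate device
against a reference device on the same subjects:

1. bias — mean of per-subject (candidate − reference) differences, with the
   per-subject percent bias (denominator = reference value);
2. accuracy classification — the share of subjects whose candidate value
   falls within ±5% of the reference value (inclusive bounds), with
   under-/over-estimation shares (strict bounds);
3. mean absolute error;
4. Bland–Altman limits of agreement (bias ± 1.96·SD of differences) with a
   proportional-bias regression of the difference on the mean of methods.

A sex-interaction regression decides whether analyses should be stratified.
All SDs use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np
from scipy import stats

from .cohort import Cohort, Sex, SubjectRecord
from .errors import DegenerateRegressionError, InsufficientDataError

__all__ = [
    "Measure",
    "Stratum",
    "PairedSeries",
    "ProportionalBias",
    "BlandAltman",
    "AccuracyBreakdown",
    "AgreementSummary",
    "InteractionResult",
    "paired_series",
    "bias_summary",
    "accuracy_classification",
    "mean_absolute_error",
    "bland_altman",
    "sex_interaction_test",
    "summarize_agreement",
    "LOA_MULTIPLIER",
    "ACCURACY_BAND",
]

#: Limits-of-agreement multiplier (exactly 1.96, not 2).
LOA_MULTIPLIER = 1.96
#: Half-width of the accurate-prediction band as a ratio (±5%).
ACCURACY_BAND = 0.05
#: Stratification threshold for the sex-interaction p-value.
INTERACTION_ALPHA = 0.10
#: Significance threshold for proportional bias.
PROP_BIAS_ALPHA = 0.05


class Measure(str, Enum):
    """Body-composition quantity; index measures divide mass by height²."""

    ALM = "ALM"
    ALMI = "ALMi"
    FFM = "FFM"
    FFMI = "FFMi"

    @property
    def is_index(self) -> bool:
        return self in (Measure.ALMI, Measure.FFMI)

    @property
    def units(self) -> str:
        return "kg/m2" if self.is_index else "kg"


class Stratum(str, Enum):
    ALL = "all"
    MALE = "male"
    FEMALE = "female"


_MEASURE_FIELDS = {
    Measure.ALM: ("alm_dxa_kg", "alm_bia_kg"),
    Measure.ALMI: ("alm_dxa_kg", "alm_bia_kg"),
    Measure.FFM: ("ffm_dxa_kg", "ffm_bia_kg"),
    Measure.FFMI: ("ffm_dxa_kg", "ffm_bia_kg"),
}


def measure_value(record: SubjectRecord, measure: Measure, device: str) -> float:
    """Extract one subject's value; ``device`` is 'reference' or 'candidate'."""
    ref_field, cand_field = _MEASURE_FIELDS[Measure(measure)]
    mass = getattr(record, ref_field if device == "reference" else cand_field)
    if Measure(measure).is_index:
        return mass / record.height_m**2
    return mass


@dataclass(frozen=True)
class PairedSeries:
    """Aligned (reference, candidate) vectors for one measure and stratum."""

    measure: Measure
    stratum: Stratum
    reference: np.ndarray
    candidate: np.ndarray
    subject_ids: tuple

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        cand = np.asarray(self.candidate, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "candidate", cand)
        if ref.shape != cand.shape or ref.ndim != 1:
            raise InsufficientDataError("reference and candidate must be equal-length 1-d")
        if ref.size < 2:
            raise InsufficientDataError("paired series needs at least 2 subjects")
        if not (np.isfinite(ref).all() and np.isfinite(cand).all()):
            raise InsufficientDataError("paired series must not contain missing values")

    @property
    def n(self) -> int:
        return self.reference.size

    @property
    def differences(self) -> np.ndarray:
        """Per-subject candidate − reference."""
        return self.candidate - self.reference

    @property
    def means(self) -> np.ndarray:
        """Per-subject mean of the two methods (Bland–Altman x-axis)."""
        return (self.candidate + self.reference) / 2.0


@dataclass(frozen=True)
class ProportionalBias:
    """OLS of difference on mean-of-methods; significant at p < 0.05."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r_squared: float

    @property
    def significant(self) -> bool:
        return self.p_value < PROP_BIAS_ALPHA


@dataclass(frozen=True)
class BlandAltman:
    loa_low: float
    loa_high: float
    prop_bias: ProportionalBias


@dataclass(frozen=True)
class AccuracyBreakdown:
    pct_accurate: float
    pct_under: float
    pct_over: float


@dataclass(frozen=True)
class AgreementSummary:
    """All validity statistics for one (measure, stratum) panel."""

    measure: Measure
    stratum: Stratum
    n: int
    ref_mean: float
    ref_sd: float
    cand_mean: float
    cand_sd: float
    bias_mean: float
    bias_sd: float
    bias_pct_mean: float
    bias_pct_sd: float
    mae: float
    pct_accurate: float
    pct_under: float
    pct_over: float
    loa_low: float
    loa_high: float
    prop_bias: ProportionalBias


def paired_series(cohort: Cohort, measure, stratum) -> PairedSeries:
    """Build the aligned (reference, candidate) vectors for one stratum.

    Index measures (ALMi, FFMi) are computed per subject as mass / height².
    Raises :class:`InsufficientDataError` for strata with fewer than 2
    members.
    """
    measure = Measure(measure)
    stratum = Stratum(stratum)
    if stratum is Stratum.ALL:
        records = cohort.records
    else:
        records = cohort.sex_records(Sex(stratum.value))
    if len(records) < 2:
        raise InsufficientDataError(
            f"stratum '{stratum.value}' has {len(records)} members; need >= 2"
        )
    ref = np.array([measure_value(r, measure, "reference") for r in records])
    cand = np.array([measure_value(r, measure, "candidate") for r in records])
    return PairedSeries(
        measure=measure,
        stratum=stratum,
        reference=ref,
        candidate=cand,
        subject_ids=tuple(r.subject_id for r in records),
    )


def percent_differences(series: PairedSeries) -> np.ndarray:
    """Per-subject percent bias, 100·(candidate − reference)/reference."""
    return 100.0 * series.differences / series.reference


def bias_summary(series: PairedSeries) -> Tuple[float, float, float, float]:
    """Return (bias_mean, bias_sd, bias_pct_mean, bias_pct_sd).

    Percent bias is mean-of-ratios: each subject's percent deviation from the
    reference value is computed first, then averaged.
    """
    d = series.differences
    pct = percent_differences(series)
    return (
        float(np.mean(d)),
        float(np.std(d, ddof=1)),
        float(np.mean(pct)),
        float(np.std(pct, ddof=1)),
    )


def accuracy_classification(series: PairedSeries) -> AccuracyBreakdown:
    """Three-way accurate/under/over partition as percentages of n.

    A subject is accurate when candidate/reference lies in [0.95, 1.05]
    (inclusive); under when strictly below 0.95; over when strictly above
    1.05.  The three percentages sum to 100 exactly as count fractions.
    """
    if np.any(series.reference <= 0):
        raise InsufficientDataError("accuracy classification needs reference > 0")
    ratio = series.candidate / series.reference
    under = np.count_nonzero(ratio < 1.0 - ACCURACY_BAND)
    over = np.count_nonzero(ratio > 1.0 + ACCURACY_BAND)
    accurate = series.n - under - over
    scale = 100.0 / series.n
    return AccuracyBreakdown(accurate * scale, under * scale, over * scale)


def mean_absolute_error(series: PairedSeries) -> float:
    """Mean of |candidate − reference|; always ≥ |bias_mean|."""
    return float(np.mean(np.abs(series.differences)))


def bland_altman(series: PairedSeries) -> BlandAltman:
    """Limits of agreement and proportional-bias regression.

    LoA are bias_mean ± 1.96·bias_sd.  Proportional bias is the OLS fit of
    the per-subject difference on the per-subject mean of the two methods;
    the slope's two-sided p-value comes from the usual t-statistic.
    Requires n ≥ 3; a constant mean-of-methods axis is degenerate.
    """
    if series.n < 3:
        raise InsufficientDataError("Bland-Altman regression needs n >= 3")
    d = series.differences
    m = series.means
    bias_mean = float(np.mean(d))
    bias_sd = float(np.std(d, ddof=1))
    if np.ptp(m) == 0:
        raise DegenerateRegressionError(
            "mean-of-methods axis has zero variance; proportional-bias fit undefined"
        )
    fit = stats.linregress(m, d)
    prop = ProportionalBias(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
    )
    return BlandAltman(
        loa_low=bias_mean - LOA_MULTIPLIER * bias_sd,
        loa_high=bias_mean + LOA_MULTIPLIER * bias_sd,
        prop_bias=prop,
    )


@dataclass(frozen=True)
class InteractionResult:
    measure: Measure
    p_value: float

    @property
    def stratify(self) -> bool:
        return self.p_value < INTERACTION_ALPHA


def sex_interaction_test(cohort: Cohort, measure) -> InteractionResult:
    """Test whether the candidate→reference relation differs by sex.

    Fits reference ~ candidate + sex + candidate×sex by OLS and returns the
    interaction term's p-value; stratification is indicated at p < 0.10.
    Requires at least 3 subjects of each sex.
    """
    import statsmodels.api as sm

    measure = Measure(measure)
    if cohort.n_male < 3 or cohort.n_female < 3:
        raise InsufficientDataError(
            "sex interaction test needs >= 3 subjects of each sex "
            f"(have {cohort.n_male} male, {cohort.n_female} female)"
        )
    ref = np.array([measure_value(r, measure, "reference") for r in cohort])
    cand = np.array([measure_value(r, measure, "candidate") for r in cohort])
    male = np.array([1.0 if r.sex is Sex.MALE else 0.0 for r in cohort])
    X = sm.add_constant(np.column_stack([cand, male, cand * male]))
    fit = sm.OLS(ref, X).fit()
    return InteractionResult(measure=measure, p_value=float(fit.pvalues[3]))


def summarize_agreement(series: PairedSeries) -> AgreementSummary:
    """Assemble the full validity panel for one paired series."""
    bias_mean, bias_sd, pct_mean, pct_sd = bias_summary(series)
    acc = accuracy_classification(series)
    ba = bland_altman(series)
    return AgreementSummary(
        measure=series.measure,
        stratum=series.stratum,
        n=series.n,
        ref_mean=float(np.mean(series.reference)),
        ref_sd=float(np.std(series.reference, ddof=1)),
        cand_mean=float(np.mean(series.candidate)),
        cand_sd=float(np.std(series.candidate, ddof=1)),
        bias_mean=bias_mean,
        bias_sd=bias_sd,
        bias_pct_mean=pct_mean,
        bias_pct_sd=pct_sd,
        mae=mean_absolute_error(series),
        pct_accurate=acc.pct_accurate,
        pct_under=acc.pct_under,
        pct_over=acc.pct_over,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        prop_bias=ba.prop_bias,
    )
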
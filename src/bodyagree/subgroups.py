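"""Covariate comparison of misclassified vs. correctly classified subjects.

Among reference-low subjects, the false negatives (candidate called them
normal) are compared to the true positives on covariates such as BMI and
fat percentage, with a two-sample t-test (Welch by default, pooled
available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

from .agreement import Measure, Stratum
from .classify import low_mass_labels
from .cohort import Cohort, Sex
from .errors import InsufficientGroupError, MissingCovariateError

__all__ = [
    "GroupComparison",
    "compare_misclassified",
    "ttest_from_summary",
    "COMPARABLE_COVARIATES",
]

COMPARABLE_COVARIATES = ("bmi", "fat_pct", "age", "height_m", "weight_kg")


@dataclass(frozen=True)
class GroupComparison:
    """t-test of false negatives (group a) vs. true positives (group b)."""

    covariate: str
    variant: str
    group_a_n: int
    group_b_n: int
    group_a_mean: float
    group_a_sd: float
    group_b_mean: float
    group_b_sd: float
    t_statistic: float
    df: float
    p_value: float


def _covariate_values(records, covariate: str) -> np.ndarray:
    values = []
    for r in records:
        v = getattr(r, covariate, None)
        if v is None:
            raise MissingCovariateError(
                f"covariate '{covariate}' missing for subject {r.subject_id}"
            )
        values.append(float(v))
    return np.asarray(values)


def compare_misclassified(
    cohort: Cohort,
    measure=Measure.ALM,
    stratum=Stratum.FEMALE,
    covariates: Sequence[str] = ("bmi", "fat_pct"),
    variant: str = "welch",
    quantile_method: str = "linear",
) -> List[GroupComparison]:
    """Compare false negatives against true positives on each covariate.

    Groups are formed among the reference-low subjects of ``stratum`` using
    the lowest-quintile classification of ``measure``.  Raises
    :class:`InsufficientGroupError` naming the offending group when either
    has fewer than 2 members (as happens when almost nobody is missed).
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    stratum = Stratum(stratum)
    labels = low_mass_labels(cohort, measure, quantile_method=quantile_method)
    by_id = {r.subject_id: r for r in cohort.records}
    low = [l for l in labels.values() if l.ref_low]
    if stratum is not Stratum.ALL:
        sex = Sex(stratum.value)
        low = [l for l in low if l.sex is sex]
    fn_recs = [by_id[l.subject_id] for l in low if not l.cand_low]
    tp_recs = [by_id[l.subject_id] for l in low if l.cand_low]
    if len(fn_recs) < 2:
        raise InsufficientGroupError(
            f"false-negative group has {len(fn_recs)} member(s) in stratum "
            f"'{stratum.value}'; comparison needs >= 2"
        )
    if len(tp_recs) < 2:
        raise InsufficientGroupError(
            f"true-positive group has {len(tp_recs)} member(s) in stratum "
            f"'{stratum.value}'; comparison needs >= 2"
        )
    out = []
    for covariate in covariates:
        a = _covariate_values(fn_recs, covariate)
        b = _covariate_values(tp_recs, covariate)
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        out.append(
            GroupComparison(
                covariate=covariate,
                variant=variant,
                group_a_n=a.size,
                group_b_n=b.size,
                group_a_mean=float(np.mean(a)),
                group_a_sd=float(np.std(a, ddof=1)),
                group_b_mean=float(np.mean(b)),
                group_b_sd=float(np.std(b, ddof=1)),
                t_statistic=float(res.statistic),
                df=float(res.df),
                p_value=float(res.pvalue),
            )
        )
    return out


def ttest_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    variant: str = "pooled",
):
    """Two-sided t-test from summary statistics; returns (t, df, p).

    Useful when only published group summaries are available.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientGroupError("summary t-test needs n >= 2 in both groups")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p
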
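"""Synthetic paired-device cohorts with controllable agreement structure.

The generator works on the scale the agreement analysis consumes: for each
subject it draws a latent mean-of-methods value ``m`` per sex from a
zero-truncated normal and constructs the between-device difference as

    d = bias_add + bias_slope * (m - center) + noise,

then sets reference = m − d/2 and candidate = m + d/2.  Because ``noise``
is independent of ``m``, the *population* slope of the Bland–Altman
regression (difference on mean of methods) equals ``bias_slope`` exactly,
and centring the slope term at the population mean keeps the mean
difference equal to ``bias_add``.  The centre is chosen so the reference
marginal mean matches the requested per-sex mean.  A naive
"candidate = reference + slope·midpoint + noise" construction would not
have this property: the noise leaks into the x-axis and attenuates the
realised slope.

Fat-free mass is generated as ALM plus a positive sex-specific residual,
so ALM < FFM holds by construction on both devices (violations from noise
are resampled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .cohort import Cohort, Sex, SubjectRecord
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SexParams",
    "SyntheticParams",
    "DEFAULT_SEED",
    "generate_cohort",
    "generate_misclassification_scenario",
    "high_bmi_subject_ids",
    "params_from_mapping",
]

#: Documented default seed; there is no hidden global randomness.
DEFAULT_SEED = 12021


@dataclass(frozen=True)
class SexParams:
    """Marginal distribution parameters for one sex (masses kg, height m)."""

    alm_mean: float
    alm_sd: float
    ffm_mean: float
    ffm_sd: float
    height_mean: float
    height_sd: float
    bmi_mean: float
    bmi_sd: float
    fat_mean: float
    fat_sd: float


# Defaults reproduce the two-sex marginal structure of a community-dwelling
# older-adult cohort (58 men, 144 women).
DEFAULT_MALE = SexParams(
    alm_mean=25.6, alm_sd=3.1,
    ffm_mean=60.5, ffm_sd=7.8,
    height_mean=1.77, height_sd=0.07,
    bmi_mean=25.2, bmi_sd=3.0,
    fat_mean=24.9, fat_sd=3.1,
)
DEFAULT_FEMALE = SexParams(
    alm_mean=18.3, alm_sd=2.4,
    ffm_mean=45.6, ffm_sd=5.3,
    height_mean=1.64, height_sd=0.06,
    bmi_mean=25.6, bmi_sd=3.8,
    fat_mean=34.8, fat_sd=4.9,
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration.

    ``bias_add`` is the additive candidate-minus-reference bias,
    ``bias_slope`` the population slope of the difference on the mean of
    methods, and ``noise_sd`` the SD of independent candidate-device noise
    on the difference scale.  The default ``noise_sd`` of 1.2 kg is
    calibrated so the synthetic ALM SD of differences matches a typical
    reported limits-of-agreement width; it is a calibration choice, not an
    estimate of any instrument's true error.
    """

    n_male: int = 58
    n_female: int = 144
    male: SexParams = field(default_factory=lambda: DEFAULT_MALE)
    female: SexParams = field(default_factory=lambda: DEFAULT_FEMALE)
    bias_add: float = -0.6
    bias_slope: float = 0.0
    noise_sd: float = 1.2
    age_mean: float = 72.1
    age_sd: float = 6.4
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ParameterError("subject counts must be >= 0")
        if self.n_male + self.n_female < 1:
            raise ParameterError("need at least one subject")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if abs(self.bias_slope) >= 2.0:
            raise ParameterError("bias_slope magnitude >= 2 is not meaningful")
        for sex, p in (("male", self.male), ("female", self.female)):
            for name in ("alm_sd", "ffm_sd", "height_sd", "bmi_sd", "fat_sd"):
                if getattr(p, name) < 0:
                    raise ParameterError(f"{sex}.{name} must be >= 0")
            for name in ("alm_mean", "ffm_mean", "height_mean", "bmi_mean", "fat_mean"):
                if getattr(p, name) <= 0:
                    raise ParameterError(f"{sex}.{name} must be > 0")
            if p.ffm_mean <= p.alm_mean:
                raise ParameterError(f"{sex}: ffm_mean must exceed alm_mean")
            # refuse parameter sets where zero-truncation would badly distort
            # the requested marginal (mean close to 0 relative to the SD)
            for mean, sd, name in (
                (p.alm_mean, p.alm_sd, "alm"),
                (p.height_mean, p.height_sd, "height"),
            ):
                if sd > 0 and stats.norm.cdf(0.0, loc=mean, scale=sd) > 0.25:
                    raise ParameterError(
                        f"{sex}.{name}: mean/sd imply heavy truncation below zero"
                    )
        if self.age_sd < 0:
            raise ParameterError("age_sd must be >= 0")


def _truncnorm(rng, mean, sd, size, low=0.0):
    """Zero-truncated normal draws; degenerates to a constant when sd == 0."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (low - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _generate_sex(rng, sex: Sex, n: int, p: SexParams, params: SyntheticParams):
    """Return a dict of column arrays for one sex."""
    bias, slope, noise_sd = params.bias_add, params.bias_slope, params.noise_sd
    # centre the latent mean-of-methods so the reference marginal mean is
    # p.alm_mean: E[ref] = E[m] - bias/2.
    alm_center = p.alm_mean + bias / 2.0
    ffm_center = p.ffm_mean + bias / 2.0
    resid_mean = p.ffm_mean - p.alm_mean
    resid_sd = float(np.sqrt(max(p.ffm_sd**2 - p.alm_sd**2, 0.0)))

    cols = None
    rows_needed = n
    for _attempt in range(100):
        m_alm = _truncnorm(rng, alm_center, p.alm_sd, rows_needed)
        resid = _truncnorm(rng, resid_mean, resid_sd, rows_needed)
        m_ffm = m_alm + resid
        d_alm = bias + slope * (m_alm - alm_center) + rng.normal(0.0, noise_sd, rows_needed) if noise_sd > 0 else bias + slope * (m_alm - alm_center)
        d_ffm = bias + slope * (m_ffm - ffm_center) + rng.normal(0.0, noise_sd, rows_needed) if noise_sd > 0 else bias + slope * (m_ffm - ffm_center)
        alm_ref, alm_cand = m_alm - d_alm / 2.0, m_alm + d_alm / 2.0
        ffm_ref, ffm_cand = m_ffm - d_ffm / 2.0, m_ffm + d_ffm / 2.0
        height = _truncnorm(rng, p.height_mean, p.height_sd, rows_needed)
        age = _truncnorm(rng, params.age_mean, params.age_sd, rows_needed)
        bmi = _truncnorm(rng, p.bmi_mean, p.bmi_sd, rows_needed)
        fat = _truncnorm(rng, p.fat_mean, p.fat_sd, rows_needed)
        batch = {
            "alm_ref": alm_ref, "alm_cand": alm_cand,
            "ffm_ref": ffm_ref, "ffm_cand": ffm_cand,
            "height": height, "age": age, "bmi": bmi, "fat": fat,
        }
        ok = (
            (alm_ref > 0) & (alm_cand > 0)
            & (alm_ref < ffm_ref) & (alm_cand < ffm_cand)
        )
        kept = {k: v[ok] for k, v in batch.items()}
        if cols is None:
            cols = kept
        else:
            cols = {k: np.concatenate([cols[k], kept[k]]) for k in cols}
        rows_needed = n - cols["alm_ref"].size
        if rows_needed <= 0:
            return {k: v[:n] for k, v in cols.items()}
    raise ParameterError(
        f"could not generate {n} feasible subjects for sex '{sex.value}'; "
        "parameters imply frequent invariant violations"
    )


def generate_cohort(params: Optional[SyntheticParams] = None) -> Cohort:
    """Generate a paired-device cohort; bit-identical given (params, seed).

    With ``bias_add = bias_slope = noise_sd = 0`` the candidate equals the
    reference for every subject.
    """
    params = params or SyntheticParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    records = []
    for sex, n, p in (
        (Sex.MALE, params.n_male, params.male),
        (Sex.FEMALE, params.n_female, params.female),
    ):
        if n == 0:
            continue
        cols = _generate_sex(rng, sex, n, p, params)
        prefix = "M" if sex is Sex.MALE else "F"
        for i in range(n):
            h = cols["height"][i]
            records.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:05d}",
                    sex=sex,
                    age=float(cols["age"][i]),
                    height_m=float(h),
                    alm_dxa_kg=float(cols["alm_ref"][i]),
                    alm_bia_kg=float(cols["alm_cand"][i]),
                    ffm_dxa_kg=float(cols["ffm_ref"][i]),
                    ffm_bia_kg=float(cols["ffm_cand"][i]),
                    weight_kg=float(cols["bmi"][i] * h**2),
                    bmi=float(cols["bmi"][i]),
                    fat_pct=float(cols["fat"][i]),
                )
            )
    provenance = (
        f"synthetic(seed={params.seed}, n_male={params.n_male}, "
        f"n_female={params.n_female}, bias_add={params.bias_add}, "
        f"bias_slope={params.bias_slope}, noise_sd={params.noise_sd})"
    )
    return Cohort(records=tuple(records), provenance=provenance)


def high_bmi_subject_ids(cohort: Cohort, fraction: float) -> frozenset:
    """Ids of the highest-BMI ``fraction`` of subjects (ties → id order)."""
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    ranked = sorted(
        cohort.records,
        key=lambda r: (-(r.bmi if r.bmi is not None else -np.inf), r.subject_id),
    )
    k = int(round(fraction * cohort.n))
    return frozenset(r.subject_id for r in ranked[:k])


def generate_misclassification_scenario(
    base: Optional[SyntheticParams],
    obese_extra_bias: float,
    obese_fraction: float,
) -> Cohort:
    """Cohort where the highest-BMI subgroup gets extra candidate bias.

    The subgroup is the top ``obese_fraction`` of subjects by BMI; their
    candidate (not reference) ALM and FFM are shifted by
    ``obese_extra_bias`` kg, emulating a device that overestimates lean
    mass in adiposity.  With ``obese_extra_bias = 0`` the output is
    identical to :func:`generate_cohort`; with ``obese_fraction = 1`` the
    shift is equivalent to increasing ``bias_add`` uniformly.
    """
    if not 0.0 <= obese_fraction <= 1.0:
        raise ParameterError("obese_fraction must be in [0, 1]")
    cohort = generate_cohort(base)
    flagged = high_bmi_subject_ids(cohort, obese_fraction)
    records = []
    for r in cohort.records:
        if r.subject_id in flagged and obese_extra_bias != 0.0:
            new_alm = r.alm_bia_kg + obese_extra_bias
            new_ffm = r.ffm_bia_kg + obese_extra_bias
            if new_alm <= 0 or new_ffm <= 0:
                raise ParameterError(
                    "obese_extra_bias drives a candidate mass non-positive"
                )
            r = replace(r, alm_bia_kg=new_alm, ffm_bia_kg=new_ffm)
        records.append(r)
    provenance = (
        f"{cohort.provenance} + misclassification(extra_bias={obese_extra_bias}, "
        f"fraction={obese_fraction})"
    )
    return Cohort(records=tuple(records), provenance=provenance)


_SEX_PREFIXES = {"male": "male", "female": "female"}


def params_from_mapping(mapping: Mapping) -> SyntheticParams:
    """Build :class:`SyntheticParams` from a flat key-value mapping.

    Top-level keys (``n_male``, ``bias_add``, ``noise_sd``, ``seed``, ...)
    map directly; per-sex marginals use ``male_``/``female_`` prefixes,
    e.g. ``female_alm_mean: 18.3``.  Unknown keys raise ParameterError.
    """
    top: dict = {}
    sex_over: dict = {"male": {}, "female": {}}
    scalar_fields = {
        "n_male", "n_female", "bias_add", "bias_slope", "noise_sd",
        "age_mean", "age_sd", "seed",
    }
    sex_fields = {f for f in SexParams.__dataclass_fields__}
    for key, value in mapping.items():
        if key in scalar_fields:
            top[key] = int(value) if key in ("n_male", "n_female", "seed") else float(value)
            continue
        for prefix in ("male_", "female_"):
            if key.startswith(prefix) and key[len(prefix):] in sex_fields:
                sex_over[prefix[:-1]][key[len(prefix):]] = float(value)
                break
        else:
            raise ParameterError(f"unknown synthetic parameter {key!r}")
    male = replace(DEFAULT_MALE, **sex_over["male"]) if sex_over["male"] else DEFAULT_MALE
    female = (
        replace(DEFAULT_FEMALE, **sex_over["female"]) if sex_over["female"] else DEFAULT_FEMALE
    )
    return SyntheticParams(male=male, female=female, **top)
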
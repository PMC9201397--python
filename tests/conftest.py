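import numpy as np
import pytest

from bodyagree import Cohort, Sex, SubjectRecord, SyntheticParams, generate_cohort


def make_record(
    subject_id,
    sex,
    alm_ref,
    alm_cand,
    height=1.60,
    ffm_offset=25.0,
    ffm_cand_offset=None,
    age=70.0,
    **extra,
):
    """Record with consistent FFM fields derived from the ALM pair."""
    if ffm_cand_offset is None:
        ffm_cand_offset = ffm_offset
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        age=age,
        height_m=height,
        alm_dxa_kg=alm_ref,
        alm_bia_kg=alm_cand,
        ffm_dxa_kg=alm_ref + ffm_offset,
        ffm_bia_kg=alm_cand + ffm_cand_offset,
        **extra,
    )


def build_cohort(male_pairs=(), female_pairs=(), **record_kwargs):
    """Cohort from (ref, cand) ALM pairs per sex."""
    records = []
    for i, (r, c) in enumerate(male_pairs):
        records.append(make_record(f"M{i:04d}", Sex.MALE, r, c, **record_kwargs))
    for i, (r, c) in enumerate(female_pairs):
        records.append(make_record(f"F{i:04d}", Sex.FEMALE, r, c, **record_kwargs))
    return Cohort(records=tuple(records), provenance="test")


def random_small_cohort(rng, n_min=5, n_max=10):
    """Random tie-free cohort with 5-10 subjects per sex for oracle checks."""
    records = []
    for sex, prefix, base in ((Sex.MALE, "M", 24.0), (Sex.FEMALE, "F", 17.0)):
        n = int(rng.integers(n_min, n_max + 1))
        ref = base + rng.uniform(-4.0, 6.0, n)
        cand = ref + rng.normal(-0.5, 1.5, n)
        cand = np.maximum(cand, 0.5)
        for i in range(n):
            records.append(
                make_record(
                    f"{prefix}{i:04d}",
                    sex,
                    float(ref[i]),
                    float(cand[i]),
                    height=float(rng.uniform(1.5, 1.9)),
                    ffm_offset=float(rng.uniform(20.0, 30.0)),
                    ffm_cand_offset=float(rng.uniform(20.0, 30.0)),
                )
            )
    return Cohort(records=tuple(records), provenance="random-small")


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticParams(seed=20401))


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero bias, zero noise: candidate identical to reference."""
    return generate_cohort(
        SyntheticParams(bias_add=0.0, bias_slope=0.0, noise_sd=0.0, seed=7)
    )
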
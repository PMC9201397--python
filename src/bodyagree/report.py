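"""Pipeline orchestration and Table-style validity report rendering."""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .agreement import (
    AgreementSummary,
    InteractionResult,
    Measure,
    Stratum,
    paired_series,
    sex_interaction_test,
    summarize_agreement,
)
from .classify import CutoffClassification, diagnostic_table, prevalence_ewgsop2
from .cohort import Cohort, read_cohort
from .errors import (
    ConfigError,
    InsufficientDataError,
    InsufficientGroupError,
    MissingCovariateError,
)
from .subgroups import GroupComparison, compare_misclassified
from .synthetic import SyntheticParams, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidityReport", "run_pipeline", "render_report"]

ALL_MEASURES = (Measure.ALM, Measure.ALMI, Measure.FFM, Measure.FFMI)
ALL_STRATA = (Stratum.ALL, Stratum.MALE, Stratum.FEMALE)


@dataclass(frozen=True)
class RunConfig:
    """What to run on: exactly one of ``input_path`` or ``synthetic``."""

    input_path: Optional[str] = None
    column_map: Optional[dict] = None
    height_unit: str = "m"
    synthetic: Optional[SyntheticParams] = None
    seed: Optional[int] = None  # overrides synthetic.seed when given
    measures: Tuple[Measure, ...] = ALL_MEASURES
    quantile_method: str = "linear"
    ttest_variant: str = "welch"
    subgroup_covariates: Tuple[str, ...] = ("bmi", "fat_pct")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValidityReport:
    cohort: Cohort
    agreement: Dict[Tuple[Measure, Stratum], AgreementSummary]
    classification: Dict[Tuple[Measure, Stratum], CutoffClassification]
    interaction: Dict[Measure, Optional[InteractionResult]]
    prevalence: dict
    subgroup: Dict[Stratum, List[GroupComparison]]
    subgroup_notes: Dict[Stratum, str]
    provenance: str
    seed: Optional[int]
    config_hash: str
    measures: Tuple[Measure, ...] = ALL_MEASURES


def _resolve_cohort(config: RunConfig) -> Tuple[Cohort, Optional[int]]:
    if config.input_path is not None and config.synthetic is not None:
        raise ConfigError("give either input_path or synthetic parameters, not both")
    if config.input_path is not None:
        cohort = read_cohort(
            config.input_path,
            column_map=config.column_map,
            height_unit=config.height_unit,
        )
        return cohort, config.seed
    if config.synthetic is not None:
        params = config.synthetic
        if config.seed is not None:
            from dataclasses import replace

            params = replace(params, seed=config.seed)
        return generate_cohort(params), params.seed
    raise ConfigError("config must name an input cohort file or synthetic parameters")


def run_pipeline(config: RunConfig) -> ValidityReport:
    """Load or generate a cohort and compute the full validity report.

    All measures × all three strata are always emitted, regardless of the
    interaction-test outcome (the decision is recorded alongside).
    """
    t0 = time.perf_counter()
    cohort, seed = _resolve_cohort(config)
    logger.info("stage load/generate: n=%d (%.3fs)", cohort.n, time.perf_counter() - t0)

    interaction: Dict[Measure, Optional[InteractionResult]] = {}
    t1 = time.perf_counter()
    for measure in config.measures:
        try:
            interaction[measure] = sex_interaction_test(cohort, measure)
        except InsufficientDataError as err:
            logger.warning("interaction test skipped for %s: %s", measure.value, err)
            interaction[measure] = None
    logger.info("stage interaction tests (%.3fs)", time.perf_counter() - t1)

    agreement = {}
    classification = {}
    t2 = time.perf_counter()
    for measure in config.measures:
        for stratum in ALL_STRATA:
            series = paired_series(cohort, measure, stratum)
            agreement[(measure, stratum)] = summarize_agreement(series)
            classification[(measure, stratum)] = diagnostic_table(
                cohort, measure, stratum, quantile_method=config.quantile_method
            )
    logger.info("stage agreement + classification (%.3fs)", time.perf_counter() - t2)

    prevalence = prevalence_ewgsop2(cohort)

    subgroup: Dict[Stratum, List[GroupComparison]] = {}
    subgroup_notes: Dict[Stratum, str] = {}
    t3 = time.perf_counter()
    for stratum in ALL_STRATA:
        try:
            subgroup[stratum] = compare_misclassified(
                cohort,
                measure=Measure.ALM,
                stratum=stratum,
                covariates=config.subgroup_covariates,
                variant=config.ttest_variant,
                quantile_method=config.quantile_method,
            )
        except (InsufficientGroupError, MissingCovariateError, InsufficientDataError) as err:
            subgroup[stratum] = []
            subgroup_notes[stratum] = str(err)
    logger.info("stage subgroup comparison (%.3fs)", time.perf_counter() - t3)

    return ValidityReport(
        cohort=cohort,
        agreement=agreement,
        classification=classification,
        interaction=interaction,
        prevalence=prevalence,
        subgroup=subgroup,
        subgroup_notes=subgroup_notes,
        provenance=cohort.provenance,
        seed=seed,
        config_hash=config.config_hash(),
        measures=tuple(config.measures),
    )


def _tidy_rows(report: ValidityReport):
    """Every number in the report as (measure, stratum, statistic, value)."""
    rows = []

    def add(measure, stratum, statistic, value):
        rows.append(
            {
                "measure": measure,
                "stratum": stratum,
                "statistic": statistic,
                "value": value,
            }
        )

    for (measure, stratum), s in report.agreement.items():
        m, st = measure.value, stratum.value
        add(m, st, "n", s.n)
        add(m, st, "ref_mean", s.ref_mean)
        add(m, st, "ref_sd", s.ref_sd)
        add(m, st, "cand_mean", s.cand_mean)
        add(m, st, "cand_sd", s.cand_sd)
        add(m, st, "bias_mean", s.bias_mean)
        add(m, st, "bias_sd", s.bias_sd)
        add(m, st, "bias_pct_mean", s.bias_pct_mean)
        add(m, st, "bias_pct_sd", s.bias_pct_sd)
        add(m, st, "mae", s.mae)
        add(m, st, "pct_accurate", s.pct_accurate)
        add(m, st, "pct_under", s.pct_under)
        add(m, st, "pct_over", s.pct_over)
        add(m, st, "loa_low", s.loa_low)
        add(m, st, "loa_high", s.loa_high)
        add(m, st, "prop_bias_slope", s.prop_bias.slope)
        add(m, st, "prop_bias_intercept", s.prop_bias.intercept)
        add(m, st, "prop_bias_se", s.prop_bias.slope_se)
        add(m, st, "prop_bias_p", s.prop_bias.p_value)
        add(m, st, "prop_bias_r2", s.prop_bias.r_squared)
    for (measure, stratum), c in report.classification.items():
        m, st = measure.value, stratum.value
        for name in ("tp", "fn", "fp", "tn"):
            add(m, st, name, getattr(c, name))
        add(m, st, "sensitivity", c.sensitivity)
        add(m, st, "specificity", c.specificity)
        if c.cutoff is not None:
            add(m, st, "cutoff", c.cutoff)
    for measure, res in report.interaction.items():
        if res is not None:
            add(measure.value, "all", "interaction_p", res.p_value)
            add(measure.value, "all", "stratify", int(res.stratify))
    for sex, prev in report.prevalence.items():
        add("ALMi", sex.value, "ewgsop2_n_low", prev.n_low)
        add("ALMi", sex.value, "ewgsop2_prevalence_pct", prev.percent)
    for stratum, comparisons in report.subgroup.items():
        for gc in comparisons:
            base = f"subgroup_{gc.covariate}"
            st = stratum.value
            add("ALM", st, f"{base}_fn_n", gc.group_a_n)
            add("ALM", st, f"{base}_fn_mean", gc.group_a_mean)
            add("ALM", st, f"{base}_fn_sd", gc.group_a_sd)
            add("ALM", st, f"{base}_tp_n", gc.group_b_n)
            add("ALM", st, f"{base}_tp_mean", gc.group_b_mean)
            add("ALM", st, f"{base}_tp_sd", gc.group_b_sd)
            add("ALM", st, f"{base}_t", gc.t_statistic)
            add("ALM", st, f"{base}_p", gc.p_value)
    return rows


def _fmt(value, decimals=1):
    return f"{value:.{decimals}f}"


def _render_text(report: ValidityReport) -> str:
    buf = io.StringIO()
    cohort = report.cohort
    w = buf.write
    w("Device validity report\n")
    w(f"provenance: {report.provenance}\n")
    w(f"seed: {report.seed}  config: {report.config_hash}\n")
    w(f"N = {cohort.n} ({cohort.n_male} male, {cohort.n_female} female)\n")
    for sex, prev in report.prevalence.items():
        w(
            f"EWGSOP2 low ALMi prevalence, {sex.value}: {prev.percent_int}% "
            f"({prev.n_low} of {prev.n_total})\n"
        )
    w("Sex-interaction tests (stratify at p < 0.10):\n")
    for measure, res in report.interaction.items():
        if res is None:
            w(f"  {measure.value}: not computed (insufficient data)\n")
        else:
            w(
                f"  {measure.value}: p = {res.p_value:.4f}"
                f" -> {'stratify' if res.stratify else 'no stratification required'}\n"
            )
    w("\n")

    measures = list(report.measures)
    header = [""] + [f"{m.value} ({m.units})" for m in measures]
    col = 16

    def row(label, cells):
        w(label.ljust(26) + "".join(str(c).rjust(col) for c in cells) + "\n")

    stratum_n = {
        Stratum.ALL: cohort.n,
        Stratum.MALE: cohort.n_male,
        Stratum.FEMALE: cohort.n_female,
    }
    for stratum in ALL_STRATA:
        w(f"=== {stratum.value.capitalize()} (N = {stratum_n[stratum]}) ===\n")
        row(header[0], header[1:])
        summaries = [report.agreement[(m, stratum)] for m in measures]
        tables = [report.classification[(m, stratum)] for m in measures]
        row(
            "Reference mean (SD)",
            [f"{_fmt(s.ref_mean)} ({_fmt(s.ref_sd)})" for s in summaries],
        )
        row(
            "Candidate mean (SD)",
            [f"{_fmt(s.cand_mean)} ({_fmt(s.cand_sd)})" for s in summaries],
        )
        row(
            "Mean bias (SD)",
            [f"{_fmt(s.bias_mean, 2)} ({_fmt(s.bias_sd, 2)})" for s in summaries],
        )
        row(
            "Mean bias % (SD)",
            [f"{_fmt(s.bias_pct_mean)} ({_fmt(s.bias_pct_sd)})" for s in summaries],
        )
        row("MAE", [_fmt(s.mae) for s in summaries])
        row("Accurate (%)", [_fmt(s.pct_accurate) for s in summaries])
        row("Under (%)", [_fmt(s.pct_under) for s in summaries])
        row("Over (%)", [_fmt(s.pct_over) for s in summaries])
        row(
            "LoA",
            [f"{_fmt(s.loa_low)} to {_fmt(s.loa_high)}" for s in summaries],
        )
        row(
            "Prop. bias slope (p)",
            [
                f"{s.prop_bias.slope:.2f} ({s.prop_bias.p_value:.3f})"
                + ("*" if s.prop_bias.significant else "")
                for s in summaries
            ],
        )
        row("Sensitivity (%)", [_fmt(t.sensitivity) for t in tables])
        row("Specificity (%)", [_fmt(t.specificity) for t in tables])
        row(
            "Cut-off (reference)",
            [("-" if t.cutoff is None else _fmt(t.cutoff)) for t in tables],
        )
        w("\n")

    w("Misclassified (FN) vs correctly classified (TP), reference-low ALM:\n")
    for stratum in ALL_STRATA:
        note = report.subgroup_notes.get(stratum)
        if note:
            w(f"  {stratum.value}: not performed ({note})\n")
            continue
        for gc in report.subgroup[stratum]:
            w(
                f"  {stratum.value} {gc.covariate}: FN {gc.group_a_mean:.1f} "
                f"({gc.group_a_sd:.1f}, n={gc.group_a_n}) vs TP {gc.group_b_mean:.1f} "
                f"({gc.group_b_sd:.1f}, n={gc.group_b_n}), t={gc.t_statistic:.2f}, "
                f"p={gc.p_value:.3f} [{gc.variant}]\n"
            )
    return buf.getvalue()


def render_report(report: ValidityReport, format: str = "text") -> str:
    """Render the report; ``format`` is 'text' (panel layout) or 'csv' (tidy).

    The CSV holds every numeric field at full precision, one row per
    measure × stratum × statistic; the text layout rounds for display only.
    """
    if format == "text":
        return _render_text(report)
    if format == "csv":
        df = pd.DataFrame(_tidy_rows(report), columns=["measure", "stratum", "statistic", "value"])
        return df.to_csv(index=False)
    raise ConfigError(f"unknown report format {format!r} (use 'text' or 'csv')")
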
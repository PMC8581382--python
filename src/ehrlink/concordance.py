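"""Orchestration and reporting: overlap, stratified tables, cohort comparison.

The reporting layer mirrors the study's result structure:

* an **overlap summary** of the documented union — how many cases each
  source found and what share of the union both found;
* **stratified tables** of each characteristic across the three
  concordance strata (both sources / specialist only / primary care
  only), with Wilson CIs per cell, missing categories excluded from
  percentage denominators, and a chi-squared test on the non-missing
  table;
* a **cohort comparison** of the two overlapping samples — everyone
  documented by the specialist source versus everyone documented by
  primary-care codes — as prevalence ratios with Katz log-method CIs;
* a **missingness report** over the full cohort.

:func:`run_pipeline` chains ascertainment, covariate derivation and all
reports from a single config, writing delimited tables, a markdown
report and a JSON run manifest; output is byte-identical for identical
inputs and config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from .codelib import load_codelist
from .covariates import derive_covariates, prevalence_denominator
from .phenotype import RestrictionMode, Stratum, StudyWindow, apply_restrictions, build_cohort
from .stats import (
    ChiSquareResult,
    PrevalenceRatioResult,
    chi_squared,
    format_percent,
    format_ratio,
    prevalence_ratio,
    wilson_ci,
)

STRATA = [Stratum.BOTH.value, Stratum.SPECIALIST_ONLY.value, Stratum.PRIMARY_ONLY.value]

#: categorical variables known to stratified_table, with the category
#: treated as missing (excluded from percentage denominators), if any
TABLE_VARIABLES: dict[str, Optional[str]] = {
    "age_group": None,
    "sex": None,
    "ethnicity6": "MISSING",
    "imd_q1": "MISSING",
    "smoking": "MISSING",
    "consult_cat": None,
    "care_home": None,
    "charlson_cat": None,
    "died_in_followup": None,
    "subtype": "UNSPECIFIED",
    "medicated": None,
}

#: Table-3-style dichotomisations: column and the value counted as positive;
#: the medication row uses the restricted full-follow-up denominator
COMPARISON_CHARACTERISTICS: dict[str, tuple[str, object]] = {
    "age_85_plus": ("age_group", "85_PLUS"),
    "female": ("sex", "F"),
    "white_british": ("ethnicity6", "WHITE_BRITISH"),
    "charlson_high": ("charlson_high", True),
    "consult_high": ("consult_cat", "ABOVE_AVERAGE"),
    "care_home": ("care_home", True),
    "died_in_followup": ("died_in_followup", True),
    "alzheimers_mixed": ("subtype", "ALZHEIMERS_MIXED"),
    "medicated": ("medicated", True),
}


@dataclass(frozen=True)
class OverlapSummary:
    n_primary: int
    n_specialist: int
    n_both: int
    n_union: int
    pct_both_of_union: Optional[float]
    pct_overlap_of_primary: Optional[float]
    pct_overlap_of_specialist: Optional[float]
    restriction: str = RestrictionMode.NONE.value


@dataclass
class StratifiedTable:
    variable: str
    counts: pd.DataFrame          # stratum x category, all categories
    percentages: pd.DataFrame     # stratum x category, missing excluded
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    flags: pd.DataFrame           # "+", "-" or "" per cell (vs BOTH stratum)
    chi2: Optional[ChiSquareResult]
    missing_category: Optional[str]


@dataclass(frozen=True)
class CohortComparisonRow:
    characteristic: str
    x1: int
    n1: int
    x2: int
    n2: int
    result: PrevalenceRatioResult


def overlap_from_counts(
    n_both: int,
    n_specialist_only: int,
    n_primary_only: int,
    restriction: str = RestrictionMode.NONE.value,
) -> OverlapSummary:
    """Overlap summary from stratum counts (source-marginal identities)."""
    n_primary = n_both + n_primary_only
    n_specialist = n_both + n_specialist_only
    n_union = n_both + n_specialist_only + n_primary_only
    if n_union == 0:
        return OverlapSummary(0, 0, 0, 0, None, None, None, restriction)
    return OverlapSummary(
        n_primary=n_primary,
        n_specialist=n_specialist,
        n_both=n_both,
        n_union=n_union,
        pct_both_of_union=100.0 * n_both / n_union,
        pct_overlap_of_primary=100.0 * n_both / n_primary if n_primary else None,
        pct_overlap_of_specialist=100.0 * n_both / n_specialist if n_specialist else None,
        restriction=restriction,
    )


def overlap_summary(cohort: pd.DataFrame, restriction: str = RestrictionMode.NONE.value) -> OverlapSummary:
    """Overlap summary of an ascertained cohort."""
    counts = cohort["stratum"].value_counts() if not cohort.empty else pd.Series(dtype=int)
    return overlap_from_counts(
        n_both=int(counts.get(Stratum.BOTH.value, 0)),
        n_specialist_only=int(counts.get(Stratum.SPECIALIST_ONLY.value, 0)),
        n_primary_only=int(counts.get(Stratum.PRIMARY_ONLY.value, 0)),
        restriction=restriction,
    )


def stratified_table(covariates: pd.DataFrame, variable: str, conf: float = 0.95) -> StratifiedTable:
    """Cross-tabulate one characteristic by concordance stratum.

    Missing categories are kept in the count table but excluded from the
    percentage denominators and from the chi-squared test. Each non-BOTH
    cell gets a ``+``/``-`` flag when its Wilson CI excludes the
    BOTH-stratum point estimate.
    """
    if variable not in TABLE_VARIABLES:
        raise ValueError(f"unknown table variable {variable!r}; valid: {sorted(TABLE_VARIABLES)}")
    missing_cat = TABLE_VARIABLES[variable]
    col = covariates[variable].astype(str)
    for stratum in STRATA:
        if not (covariates["stratum"] == stratum).any():
            raise ValueError(f"stratum {stratum} has no members")
    counts = (
        pd.crosstab(covariates["stratum"], col)
        .reindex(index=STRATA, fill_value=0)
        .sort_index(axis=1)
    )
    nonmiss = counts.drop(columns=[missing_cat], errors="ignore")
    denom = nonmiss.sum(axis=1)
    pct = 100.0 * nonmiss.div(denom, axis=0)
    lo = pd.DataFrame(index=nonmiss.index, columns=nonmiss.columns, dtype=float)
    hi = pd.DataFrame(index=nonmiss.index, columns=nonmiss.columns, dtype=float)
    for stratum in nonmiss.index:
        n = int(denom[stratum])
        for cat in nonmiss.columns:
            ci = wilson_ci(int(nonmiss.loc[stratum, cat]), max(n, 1), conf)
            lo.loc[stratum, cat] = 100.0 * ci.lo
            hi.loc[stratum, cat] = 100.0 * ci.hi
    flags = pd.DataFrame("", index=nonmiss.index, columns=nonmiss.columns)
    for cat in nonmiss.columns:
        p_both = pct.loc[Stratum.BOTH.value, cat]
        for stratum in (Stratum.SPECIALIST_ONLY.value, Stratum.PRIMARY_ONLY.value):
            if lo.loc[stratum, cat] > p_both:
                flags.loc[stratum, cat] = "+"
            elif hi.loc[stratum, cat] < p_both:
                flags.loc[stratum, cat] = "-"
    chi2 = None
    if nonmiss.shape[1] >= 2 and (nonmiss.sum(axis=0) > 0).all():
        chi2 = chi_squared(nonmiss.to_numpy())
    else:
        warnings.warn(f"{variable}: single observed category, chi-squared skipped")
    return StratifiedTable(
        variable=variable,
        counts=counts,
        percentages=pct,
        ci_low=lo,
        ci_high=hi,
        flags=flags,
        chi2=chi2,
        missing_category=missing_cat,
    )


def cohort_comparison(
    covariates: pd.DataFrame, characteristic: str, conf: float = 0.95
) -> CohortComparisonRow:
    """One Table-3-style row: specialist sample vs primary-care sample.

    The specialist sample combines the BOTH and SPECIALIST_ONLY strata;
    the primary-care sample combines BOTH and PRIMARY_ONLY. The
    medication row restricts both denominators to members with a full
    4-year follow-up window before the censor date.
    """
    if characteristic not in COMPARISON_CHARACTERISTICS:
        raise ValueError(
            f"unknown characteristic {characteristic!r}; valid: {sorted(COMPARISON_CHARACTERISTICS)}"
        )
    col, positive = COMPARISON_CHARACTERISTICS[characteristic]
    df = covariates
    if characteristic == "medicated" and "full_followup" in df:
        df = df[df["full_followup"]]
    in_spec = df["stratum"].isin([Stratum.BOTH.value, Stratum.SPECIALIST_ONLY.value])
    in_prim = df["stratum"].isin([Stratum.BOTH.value, Stratum.PRIMARY_ONLY.value])
    pos = df[col] == positive
    x1, n1 = int((pos & in_spec).sum()), int(in_spec.sum())
    x2, n2 = int((pos & in_prim).sum()), int(in_prim.sum())
    return CohortComparisonRow(
        characteristic=characteristic,
        x1=x1,
        n1=n1,
        x2=x2,
        n2=n2,
        result=prevalence_ratio(x1, n1, x2, n2, conf),
    )


def missingness_report(covariates: pd.DataFrame) -> pd.DataFrame:
    """Missing-data counts over the full cohort for the affected variables."""
    n = len(covariates)
    rows = []
    for variable, label in [("ethnicity6", "ethnicity"), ("smoking", "smoking"), ("imd_q1", "lsoa_address")]:
        miss = int((covariates[variable].astype(str) == "MISSING").sum())
        rows.append(
            {
                "variable": label,
                "n_missing": miss,
                "pct_missing": format_percent(miss / n) if n else "—",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    patients: str
    events: str
    consultations: str
    prescriptions: str
    codelist: str
    imd_lookup: Optional[str] = None
    window_start: str = "2007-01-01"
    window_end: str = "2019-05-31"
    min_age: int = 65
    first_date_rule: str = "earliest_code"
    restriction: str = "NONE"
    median_override: Optional[int] = None
    care_home_lookback: str = "2y"  # "2y" or "unlimited"
    confidence: float = 0.95
    seed: int = 0
    prevalence_reference_date: str = "2013-05-24"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def window(self) -> StudyWindow:
        return StudyWindow(
            start=date.fromisoformat(self.window_start),
            end=date.fromisoformat(self.window_end),
            min_age=self.min_age,
        )


@dataclass
class ReportBundle:
    overlap: OverlapSummary
    tables: dict[str, StratifiedTable]
    comparison: list[CohortComparisonRow]
    missingness: pd.DataFrame
    cohort: pd.DataFrame
    covariates: pd.DataFrame
    consult_median: int
    prevalence_denominator: int
    manifest: dict


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute ascertainment, covariate derivation and every report."""
    for name in ("patients", "events", "consultations", "prescriptions", "codelist"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline config: {name} file not found: {path}")
    codelist = load_codelist(config.codelist)
    patients = io_mod.read_patients(config.patients)
    events = io_mod.read_events(config.events)
    consultations = io_mod.read_consultations(config.consultations)
    prescriptions = io_mod.read_prescriptions(config.prescriptions)
    imd = io_mod.read_imd_lookup(config.imd_lookup) if config.imd_lookup else {}
    window = config.window()

    cohort = build_cohort(patients, events, codelist, window, first_date_rule=config.first_date_rule)
    cohort = apply_restrictions(cohort, patients, consultations, RestrictionMode(config.restriction))
    lookback = None if config.care_home_lookback == "unlimited" else 2
    cov = derive_covariates(
        cohort,
        patients,
        events,
        consultations,
        prescriptions,
        codelist,
        imd_lookup=imd,
        median_override=config.median_override,
        care_home_lookback_years=lookback,
    )
    median = int(cov.attrs.get("consult_median", 0)) if not cov.empty else 0
    overlap = overlap_summary(cohort, restriction=config.restriction)
    tables = {}
    for variable in TABLE_VARIABLES:
        try:
            tables[variable] = stratified_table(cov, variable, conf=config.confidence)
        except ValueError as err:
            raise ValueError(f"stratified table for {variable!r} failed: {err}") from err
    comparison = [
        cohort_comparison(cov, c, conf=config.confidence) for c in COMPARISON_CHARACTERISTICS
    ]
    missing = missingness_report(cov)
    manifest = {
        "config": asdict(config),
        "codelist": {"name": codelist.name, "version": codelist.version, "entries": len(codelist)},
        "cohort_size": int(len(cohort)),
        "consult_median": median,
        "care_home_lookback": config.care_home_lookback,
        "first_date_rule": config.first_date_rule,
    }
    bundle = ReportBundle(
        overlap=overlap,
        tables=tables,
        comparison=comparison,
        missingness=missing,
        cohort=cohort,
        covariates=cov,
        consult_median=median,
        prevalence_denominator=prevalence_denominator(
            patients, date.fromisoformat(config.prevalence_reference_date)
        ),
        manifest=manifest,
    )
    if out_dir is not None:
        write_reports(bundle, out_dir)
    return bundle


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write machine-readable tables, a markdown report and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ov = bundle.overlap
    pd.DataFrame([asdict(ov)]).to_csv(out / "overlap.csv", index=False)
    for name, table in bundle.tables.items():
        stacked = []
        for stratum in table.counts.index:
            for cat in table.counts.columns:
                is_missing = cat == table.missing_category
                stacked.append(
                    {
                        "variable": name,
                        "stratum": stratum,
                        "category": cat,
                        "count": int(table.counts.loc[stratum, cat]),
                        "pct": "" if is_missing else f"{table.percentages.loc[stratum, cat]:.6f}",
                        "ci_low": "" if is_missing else f"{table.ci_low.loc[stratum, cat]:.6f}",
                        "ci_high": "" if is_missing else f"{table.ci_high.loc[stratum, cat]:.6f}",
                        "flag": "" if is_missing else table.flags.loc[stratum, cat] if stratum != "BOTH" else "",
                    }
                )
        pd.DataFrame(stacked).to_csv(out / f"table_{name}.csv", index=False)
    comp = pd.DataFrame(
        [
            {
                "characteristic": row.characteristic,
                "x1": row.x1,
                "n1": row.n1,
                "x2": row.x2,
                "n2": row.n2,
                "pr": f"{row.result.pr:.6f}",
                "ci_low": f"{row.result.lo:.6f}",
                "ci_high": f"{row.result.hi:.6f}",
            }
            for row in bundle.comparison
        ]
    )
    comp.to_csv(out / "comparison.csv", index=False)
    bundle.missingness.to_csv(out / "missingness.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(render_report(bundle))


def render_report(bundle: ReportBundle) -> str:
    """Human-readable markdown report; raw counts always shown."""
    ov = bundle.overlap
    lines = ["# Dual-source dementia ascertainment report", ""]
    lines.append("## Overlap")
    lines.append("")
    lines.append(f"- primary-care documented: {ov.n_primary}")
    lines.append(f"- specialist documented: {ov.n_specialist}")
    lines.append(f"- both sources: {ov.n_both}")
    lines.append(f"- union: {ov.n_union}")
    if ov.n_union:
        lines.append(f"- both as share of union: {format_percent(ov.n_both / ov.n_union)}")
        lines.append(f"- primary also in specialist: {format_percent(ov.n_both / ov.n_primary)}")
        lines.append(f"- specialist also in primary: {format_percent(ov.n_both / ov.n_specialist)}")
    else:
        lines.append("- percentages: —")
    lines.append("")
    lines.append(f"Population denominator aged 65+ at reference date: {bundle.prevalence_denominator}")
    lines.append(f"Consultation median used for categorisation: {bundle.consult_median}")
    lines.append("")
    lines.append("## Stratified characteristics")
    for name, table in bundle.tables.items():
        lines.append("")
        lines.append(f"### {name}")
        lines.append("")
        header = "| category | " + " | ".join(table.counts.index) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(table.counts.index) + 1))
        for cat in table.counts.columns:
            cells = []
            for stratum in table.counts.index:
                cnt = int(table.counts.loc[stratum, cat])
                if cat == table.missing_category:
                    cells.append(f"{cnt} (omitted)")
                else:
                    pct = table.percentages.loc[stratum, cat] / 100.0
                    flag = table.flags.loc[stratum, cat] if stratum != "BOTH" else ""
                    cells.append(
                        f"{cnt} ({format_percent(pct)}, "
                        f"{format_percent(table.ci_low.loc[stratum, cat] / 100)}–"
                        f"{format_percent(table.ci_high.loc[stratum, cat] / 100)}){flag}"
                    )
            lines.append(f"| {cat} | " + " | ".join(cells) + " |")
        if table.chi2 is not None:
            p = "< 0.001" if table.chi2.p_value < 0.001 else f"= {table.chi2.p_value:.3f}"
            lines.append("")
            lines.append(
                f"Chi-squared = {table.chi2.statistic:.2f}, df = {table.chi2.df}, P {p}"
            )
    lines.append("")
    lines.append("## Overlapping-cohort comparison (specialist : primary care)")
    lines.append("")
    lines.append("| characteristic | specialist x/n | primary x/n | PR (CI) |")
    lines.append("|---|---|---|---|")
    for row in bundle.comparison:
        r = row.result
        lines.append(
            f"| {row.characteristic} | {row.x1}/{row.n1} | {row.x2}/{row.n2} | "
            f"{format_ratio(r.pr)} ({format_ratio(r.lo)}–{format_ratio(r.hi)}) |"
        )
    lines.append("")
    lines.append("## Missing data")
    lines.append("")
    for rec in bundle.missingness.itertuples(index=False):
        lines.append(f"- {rec.variable}: {rec.n_missing} ({rec.pct_missing})")
    lines.append("")
    lines.append(
        "Footnote: a stratified-table cell is flagged + or - when its Wilson CI "
        "excludes the both-sources stratum point estimate."
    )
    lines.append("")
    return "\n".join(lines)
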
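"""Sensitivity analysis, round summaries and result writers.

The mortality-source sensitivity reruns the whole pipeline with only the
baseline NMR/MMR substituted (IGME is the default source when present);
round summaries reproduce the inclusion bookkeeping a multi-round exercise
reports (countries, analyses, projects analysed vs reported, completeness
of achieved data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import CountryProfile, InterventionSpec, LivesSavedResult, ValidationError
from .protocol import (
    ACHIEVED,
    AnalysisUnit,
    PipelineResult,
    ProjectRecord,
    run_country_analysis,
)

DEFAULT_SOURCE = "IGME"
#: outcomes reported in the mortality-source sensitivity range
SENSITIVITY_OUTCOMES = ("maternal_total", "newborn_primary")


@dataclass(frozen=True)
class MortalityEstimate:
    """One mortality source's NMR/MMR pair for a country."""

    country_id: str
    source_label: str
    nmr: float
    mmr: float


@dataclass
class SensitivityRange:
    """Totals per mortality source, with the range and the default."""

    by_source: Dict[str, Dict[str, float]]  # outcome -> {source: total}
    default_source: str

    def minimum(self, outcome: str) -> float:
        return min(self.by_source[outcome].values())

    def maximum(self, outcome: str) -> float:
        return max(self.by_source[outcome].values())

    def default(self, outcome: str) -> float:
        return self.by_source[outcome][self.default_source]


@dataclass
class RoundSummary:
    """One analysis round's inclusion and completeness counts."""

    round_label: str
    countries_reporting: int
    analyses: int
    projects_analysed: int
    projects_reported: int
    percent_analysed: int
    countries_with_achieved: int
    percent_with_achieved: int

    def __post_init__(self) -> None:
        if self.projects_analysed > self.projects_reported:
            raise ValidationError(
                "more projects analysed than reported")
        for pct in (self.percent_analysed, self.percent_with_achieved):
            if not 0 <= pct <= 100:
                raise ValidationError(f"percentage {pct} outside [0, 100]")


def percent_analysed(n_analysed: int, n_reported: int) -> int:
    """Integer inclusion percentage, rounded half away from zero."""
    if n_reported <= 0:
        raise ValidationError("n_reported must be positive")
    if not 0 <= n_analysed <= n_reported:
        raise ValidationError("n_analysed must lie in [0, n_reported]")
    return int(math.floor(100.0 * n_analysed / n_reported + 0.5))


def run_mortality_sensitivity(
        register: Sequence[ProjectRecord],
        profile: CountryProfile,
        specs: Mapping[str, InterventionSpec],
        sources: Sequence[MortalityEstimate],
        mode: str,
        behaviour_conversion: float = 1.0) -> SensitivityRange:
    """Rerun the pipeline once per mortality source, NMR/MMR substituted.

    With coverage trajectories unchanged, totals scale exactly linearly
    with the substituted baseline rate.
    """
    if not sources:
        raise ValidationError("sensitivity analysis needs at least one source")
    labels = [s.source_label for s in sources]
    default_source = DEFAULT_SOURCE if DEFAULT_SOURCE in labels else labels[0]
    by_source: Dict[str, Dict[str, float]] = {
        outcome: {} for outcome in SENSITIVITY_OUTCOMES}
    for source in sources:
        varied = replace(profile, nmr0=source.nmr, mmr0=source.mmr,
                         mortality_source=source.source_label)
        result = run_country_analysis(register, varied, specs, mode,
                                      behaviour_conversion)
        totals = result.totals
        for outcome in SENSITIVITY_OUTCOMES:
            by_source[outcome][source.source_label] = totals[outcome]
    return SensitivityRange(by_source=by_source,
                            default_source=default_source)


def _countries_with_achieved(register: Sequence[ProjectRecord]) -> List[str]:
    out = set()
    for project in register:
        for entry in project.entries:
            if entry.years_with(ACHIEVED):
                out.add(project.country_id)
                break
    return sorted(out)


def completeness_summary(
        register: Sequence[ProjectRecord]) -> Tuple[int, int, int]:
    """(countries with any achieved value, countries reporting, percent)."""
    countries = sorted({p.country_id for p in register})
    with_achieved = _countries_with_achieved(register)
    pct = percent_analysed(len(with_achieved), len(countries))
    return len(with_achieved), len(countries), pct


def summarize_round(register: Sequence[ProjectRecord],
                    units: Sequence[AnalysisUnit],
                    eligible: Sequence[ProjectRecord],
                    round_label: str = "") -> RoundSummary:
    """Table-style round summary; a pure function of register + screening."""
    reported_ids = {p.project_id for p in register}
    analysed_ids = {p.project_id for p in eligible}
    n_with, n_countries, pct_with = completeness_summary(register)
    return RoundSummary(
        round_label=round_label,
        countries_reporting=len({p.country_id for p in register}),
        analyses=len(units),
        projects_analysed=len(analysed_ids),
        projects_reported=len(reported_ids),
        percent_analysed=percent_analysed(len(analysed_ids),
                                          len(reported_ids)),
        countries_with_achieved=n_with,
        percent_with_achieved=pct_with,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _annual_frame(country_results: Mapping[str, LivesSavedResult],
                  global_result: LivesSavedResult) -> pd.DataFrame:
    rows = []
    items = [(cid, country_results[cid]) for cid in sorted(country_results)]
    items.append(("global", global_result))
    for cid, result in items:
        for series in LivesSavedResult.SERIES:
            for year in sorted(result.series(series)):
                rows.append({"country_id": cid, "year": year,
                             "series": series,
                             "value": result.series(series)[year]})
    frame = pd.DataFrame(rows, columns=["country_id", "year", "series",
                                        "value"])
    return frame.sort_values(["country_id", "year", "series"],
                             kind="mergesort").reset_index(drop=True)


def _per_intervention_frame(
        country_results: Mapping[str, LivesSavedResult],
        global_result: LivesSavedResult) -> pd.DataFrame:
    rows = []
    items = [(cid, country_results[cid]) for cid in sorted(country_results)]
    items.append(("global", global_result))
    for cid, result in items:
        for iid in sorted(result.per_intervention):
            rows.append({"country_id": cid, "intervention_id": iid,
                         "total_lives_saved": result.per_intervention[iid]})
    return pd.DataFrame(rows, columns=["country_id", "intervention_id",
                                       "total_lives_saved"])


def write_results(out_dir: str | Path,
                  country_results: Mapping[str, LivesSavedResult],
                  global_result: LivesSavedResult,
                  sensitivity: Optional[Mapping[str, SensitivityRange]] = None,
                  round_summary: Optional[RoundSummary] = None) -> List[Path]:
    """Write deterministic CSV outputs; re-reading reproduces the values.

    Files: ``annual_lives_saved.csv`` (country, year, series, value),
    ``per_intervention.csv``, optionally ``sensitivity.csv`` (country,
    source, outcome, total) and ``round_summary.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    annual = out / "annual_lives_saved.csv"
    _annual_frame(country_results, global_result).to_csv(
        annual, index=False)
    written.append(annual)

    per_int = out / "per_intervention.csv"
    _per_intervention_frame(country_results, global_result).to_csv(
        per_int, index=False)
    written.append(per_int)

    if sensitivity is not None:
        rows = []
        for cid in sorted(sensitivity):
            srange = sensitivity[cid]
            for outcome in SENSITIVITY_OUTCOMES:
                for label in sorted(srange.by_source[outcome]):
                    rows.append({"country_id": cid, "source_label": label,
                                 "outcome": outcome,
                                 "total": srange.by_source[outcome][label]})
        path = out / "sensitivity.csv"
        pd.DataFrame(rows, columns=["country_id", "source_label", "outcome",
                                    "total"]).to_csv(
            path, index=False)
        written.append(path)

    if round_summary is not None:
        path = out / "round_summary.csv"
        pd.DataFrame([round_summary.__dict__]).to_csv(path, index=False)
        written.append(path)
    return written
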
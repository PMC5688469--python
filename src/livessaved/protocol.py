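"""Register protocol: from raw project reports to lives-saved results.

Implements the analysis sequence a donor's country-office template feeds:
screen projects (bilateral only, modelable, with data), group them into
geographic analysis units, convert heterogeneous indicators to coverage,
resolve achieved-vs-forecast precedence, de-duplicate overlapping reports,
build the without-funder counterfactual from attribution fractions, and run
the cohort engine per unit before aggregating to country and global totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .model import (
    CountryProfile,
    CoverageTrajectory,
    InterventionSpec,
    LivesSavedResult,
    Scenario,
    ScenarioPair,
    ValidationError,
    analyze_pair,
    sum_results,
)

logger = logging.getLogger(__name__)

INDICATOR_TYPES = ("coverage", "services_delivered", "commodities",
                   "message_exposure", "milestone")
#: indicator types converted to coverage by dividing by a target population
RATIO_TYPES = ("services_delivered", "commodities", "message_exposure")
MANAGEMENT_TYPES = ("bilateral", "central_multicountry", "multilateral")
PROVENANCES = ("achieved", "forecast")
ACHIEVED, FORECAST = PROVENANCES
MODES = ("achieved", "forecast")
NATIONAL = "national"

_TOL = 1e-9


class UnusableUnitError(ValidationError):
    """An analysis unit has no usable coverage data under the run mode."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class YearValue:
    """Reported value for one year, possibly both achieved and forecast."""

    achieved: Optional[float] = None
    forecast: Optional[float] = None

    @property
    def empty(self) -> bool:
        return self.achieved is None and self.forecast is None


@dataclass
class InterventionEntry:
    """One intervention's annual indicator values within a project."""

    intervention_id: str
    indicator_type: str
    annual_values: Dict[int, YearValue]
    target_population: Optional[float] = None
    attribution_override: Optional[float] = None

    def __post_init__(self) -> None:
        _check(self.indicator_type in INDICATOR_TYPES,
               f"unknown indicator type {self.indicator_type!r}")
        _check(any(not yv.empty for yv in self.annual_values.values()),
               f"entry {self.intervention_id!r} has no annual values")
        if self.indicator_type in RATIO_TYPES:
            _check(self.target_population is not None
                   and self.target_population > 0,
                   f"entry {self.intervention_id!r} of type "
                   f"{self.indicator_type} requires a positive "
                   "target_population")
        for year, yv in self.annual_values.items():
            for value in (yv.achieved, yv.forecast):
                if value is None:
                    continue
                _check(value >= 0, f"negative value for "
                       f"{self.intervention_id!r} in {year}")
                if self.indicator_type == "coverage":
                    _check(value <= 1.0, f"coverage value for "
                           f"{self.intervention_id!r} in {year} exceeds 1")
                if self.indicator_type == "milestone":
                    _check(value in (0.0, 1.0),
                           f"milestone value for {self.intervention_id!r} "
                           f"in {year} must be 0 or 1")
        if self.attribution_override is not None:
            _check(0.0 <= self.attribution_override <= 1.0,
                   "attribution override must lie in [0, 1]")

    def years_with(self, provenance: str) -> List[int]:
        attr = provenance
        return sorted(year for year, yv in self.annual_values.items()
                      if getattr(yv, attr) is not None)


@dataclass
class ProjectRecord:
    """One funded project from the register template."""

    project_id: str
    country_id: str
    management: str
    start_year: int
    end_year: int
    total_funding: float
    attribution: float
    geography_id: str
    population_share: float
    entries: List[InterventionEntry] = field(default_factory=list)
    modelable: Optional[bool] = None

    def __post_init__(self) -> None:
        _check(self.management in MANAGEMENT_TYPES,
               f"unknown management type {self.management!r}")
        _check(self.start_year <= self.end_year,
               f"project {self.project_id!r}: start_year after end_year")
        _check(0.0 <= self.attribution <= 1.0,
               f"project {self.project_id!r}: attribution outside [0, 1]")
        _check(0.0 < self.population_share <= 1.0,
               f"project {self.project_id!r}: population_share outside (0, 1]")
        _check(self.total_funding >= 0,
               f"project {self.project_id!r}: negative funding")

    @property
    def has_data(self) -> bool:
        return any(not yv.empty for e in self.entries
                   for yv in e.annual_values.values())


@dataclass
class MergedValue:
    """De-duplicated with/without coverage for one (intervention, year)."""

    coverage: float
    counterfactual: float
    provenance: str
    n_fragments: int = 1


@dataclass
class AnalysisUnit:
    """Geographically co-located projects modelled with one scenario pair."""

    country_id: str
    geography_ids: frozenset
    population_share: float
    projects: List[ProjectRecord]
    merged_entries: Optional[Dict[str, Dict[int, MergedValue]]] = None
    milestones: Dict[str, List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(0.0 < self.population_share <= 1.0,
               "population_share must lie in (0, 1]")


# ---------------------------------------------------------------------------
# screening and grouping
# ---------------------------------------------------------------------------


def screen_projects(
        register: Sequence[ProjectRecord],
        specs: Mapping[str, InterventionSpec],
) -> Tuple[List[ProjectRecord], List[Tuple[str, str]]]:
    """Partition a register into eligible projects and exclusions.

    Excludes centrally managed / multilateral projects (double-counting
    risk), projects with no reported values, and projects none of whose
    interventions map to the effectiveness library (e.g. training or
    empowerment programmes).  Never hard-fails: every project lands in
    exactly one of the two outputs.
    """
    eligible: List[ProjectRecord] = []
    excluded: List[Tuple[str, str]] = []
    for project in register:
        if project.management != "bilateral":
            project.modelable = False
            excluded.append((project.project_id, "central/multilateral"))
        elif not project.has_data:
            project.modelable = False
            excluded.append((project.project_id, "no data"))
        elif not any(e.intervention_id in specs for e in project.entries):
            project.modelable = False
            excluded.append((project.project_id, "not modelable"))
        else:
            project.modelable = True
            eligible.append(project)
    return eligible, excluded


def group_analysis_units(
        eligible: Sequence[ProjectRecord]) -> List[AnalysisUnit]:
    """Group eligible projects by shared geography within each country.

    Projects labelled ``national`` form one national unit per country with
    population share 1; each subnational geography label forms its own unit
    with its stated share.  Conflicting shares for one geography are an
    error.
    """
    grouped: Dict[Tuple[str, str], List[ProjectRecord]] = {}
    for project in eligible:
        key = (project.country_id, project.geography_id)
        grouped.setdefault(key, []).append(project)
    units: List[AnalysisUnit] = []
    for (country_id, geography_id) in sorted(grouped):
        projects = grouped[(country_id, geography_id)]
        if geography_id == NATIONAL:
            share = 1.0
        else:
            shares = {round(p.population_share, 9) for p in projects}
            if len(shares) > 1:
                raise ValidationError(
                    f"conflicting population shares for geography "
                    f"{geography_id!r} in {country_id!r}: {sorted(shares)}")
            share = projects[0].population_share
        units.append(AnalysisUnit(country_id=country_id,
                                  geography_ids=frozenset({geography_id}),
                                  population_share=share,
                                  projects=projects))
    return units


# ---------------------------------------------------------------------------
# indicator conversion, precedence, merging, counterfactual
# ---------------------------------------------------------------------------


def resolve_value(achieved: Optional[float],
                  forecast: Optional[float]) -> Tuple[float, str]:
    """Achieved values win whenever present; forecasts fill the gaps."""
    if achieved is not None:
        return achieved, ACHIEVED
    if forecast is not None:
        return forecast, FORECAST
    raise ValidationError("neither achieved nor forecast value present")


def indicator_to_coverage(
        entry: InterventionEntry,
        behaviour_conversion: float = 1.0,
) -> Dict[int, Tuple[float, str]]:
    """Convert an indicator entry to annual coverage with provenance.

    Coverage passes through; services-delivered and commodities divide by
    the target population (assuming all supplies reach their targets),
    clipped to [0, 1] with a warning; message-exposure additionally applies
    the behaviour-change conversion factor; milestones carry no coverage
    and are reported only.
    """
    if entry.indicator_type == "milestone":
        return {}
    out: Dict[int, Tuple[float, str]] = {}
    for year in sorted(entry.annual_values):
        yv = entry.annual_values[year]
        if yv.empty:
            continue
        value, provenance = resolve_value(yv.achieved, yv.forecast)
        if entry.indicator_type == "coverage":
            coverage = value
        else:
            if entry.target_population is None or entry.target_population <= 0:
                raise ValidationError(
                    f"entry {entry.intervention_id!r}: ratio indicator "
                    "without a target_population")
            coverage = value / entry.target_population
            if entry.indicator_type == "message_exposure":
                coverage *= behaviour_conversion
            if coverage > 1.0:
                logger.warning(
                    "clipping %s coverage %.3f to 1.0 for %r in %d",
                    entry.indicator_type, coverage, entry.intervention_id,
                    year)
                coverage = 1.0
        out[year] = (coverage, provenance)
    return out


def merge_coverage(fragments: Sequence[float],
                   intervention_id: str = "",
                   year: Optional[int] = None) -> float:
    """De-duplicate overlapping reports of one activity: take the maximum.

    The maximum (never the sum) is conservative against double-counting a
    single activity reported by several projects.
    """
    _check(len(fragments) > 0, "merge_coverage needs at least one fragment")
    if len(fragments) > 1:
        logger.info("de-duplicated %d overlapping reports for %r year %s "
                    "(max rule)", len(fragments), intervention_id, year)
    return max(fragments)


def counterfactual_value(coverage: float, baseline: float,
                         attribution: float) -> float:
    """Remove the funder's share of the coverage increment over baseline."""
    return baseline + (1.0 - attribution) * (coverage - baseline)


def build_counterfactual(traj: CoverageTrajectory,
                         baseline: CoverageTrajectory,
                         attribution: float) -> CoverageTrajectory:
    """Without-funder trajectory: scale increments over baseline by 1-a.

    cov_cf,t = cov_0 + (1 - attribution) * (cov_t - cov_0), identically for
    contraceptive prevalence.  Attribution 0 reproduces the actual
    trajectory; attribution 1 reproduces the baseline.
    """
    _check(0.0 <= attribution <= 1.0, "attribution must lie in [0, 1]")
    values = {}
    for (iid, year), cov in traj.values.items():
        key = (iid, year)
        if key not in baseline.values:
            raise ValidationError(
                f"baseline trajectory missing {iid!r} for year {year}")
        values[key] = counterfactual_value(cov, baseline.values[key],
                                           attribution)
    cp = {}
    for year, u in traj.cp.items():
        if year not in baseline.cp:
            raise ValidationError(
                f"baseline trajectory missing prevalence for year {year}")
        cp[year] = counterfactual_value(u, baseline.cp[year], attribution)
    return CoverageTrajectory(values=values, cp=cp)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------


def _entry_baseline(profile: CountryProfile, spec: InterventionSpec) -> float:
    if spec.is_family_planning:
        return profile.cp0
    return profile.baseline_coverage.get(spec.intervention_id, 0.0)


def _achieved_horizon(unit: AnalysisUnit,
                      profile: CountryProfile,
                      specs: Mapping[str, InterventionSpec]) -> Optional[int]:
    years = [year
             for project in unit.projects
             for entry in project.entries
             if entry.intervention_id in specs
             for year in entry.years_with(ACHIEVED)
             if profile.baseline_year < year <= profile.horizon_year]
    return max(years) if years else None


def assemble_scenarios(unit: AnalysisUnit,
                       profile: CountryProfile,
                       specs: Mapping[str, InterventionSpec],
                       mode: str,
                       behaviour_conversion: float = 1.0) -> ScenarioPair:
    """Build the primary and health-only scenario pairs for one unit.

    Achieved mode truncates the horizon at the latest year with any
    achieved value; forecast mode extends to the profile horizon using
    forecasts where achieved values are absent.  Per project fragment the
    counterfactual removes that project's attributed share of the coverage
    increment; overlapping fragments are then merged by the maximum.
    Trajectories are made dense by carrying the last reported value
    forward (baseline coverage before the first report).
    """
    _check(mode in MODES, f"unknown mode {mode!r}")
    baseline_year = profile.baseline_year

    if mode == "achieved":
        horizon = _achieved_horizon(unit, profile, specs)
        if horizon is None:
            raise UnusableUnitError(
                f"unit {sorted(unit.geography_ids)} in "
                f"{unit.country_id!r}: no achieved values — zero usable "
                "years in achieved mode")
    else:
        horizon = profile.horizon_year

    # per-project fragments: (iid, year) -> list of (coverage, cf, provenance)
    fragments: Dict[Tuple[str, int], List[Tuple[float, float, str]]] = {}
    milestones: Dict[str, List[int]] = {}
    for project in unit.projects:
        for entry in project.entries:
            iid = entry.intervention_id
            if iid not in specs:
                continue
            spec = specs[iid]
            if entry.indicator_type == "milestone":
                flagged = [year for year, yv in entry.annual_values.items()
                           if (yv.achieved or yv.forecast)]
                milestones.setdefault(iid, []).extend(flagged)
                continue
            try:
                converted = indicator_to_coverage(entry, behaviour_conversion)
            except ValidationError as err:
                raise ValidationError(
                    f"project {project.project_id!r}, intervention "
                    f"{iid!r}: {err}") from err
            attribution = (entry.attribution_override
                           if entry.attribution_override is not None
                           else project.attribution)
            base = _entry_baseline(profile, spec)
            for year, (coverage, provenance) in converted.items():
                if not baseline_year < year <= horizon:
                    continue
                cf = counterfactual_value(coverage, base, attribution)
                fragments.setdefault((iid, year), []).append(
                    (coverage, cf, provenance))

    if not fragments and not milestones:
        raise UnusableUnitError(
            f"unit {sorted(unit.geography_ids)} in {unit.country_id!r}: "
            "zero usable years")

    merged: Dict[str, Dict[int, MergedValue]] = {}
    for (iid, year), frags in sorted(fragments.items()):
        coverage = merge_coverage([f[0] for f in frags], iid, year)
        counterfactual = max(f[1] for f in frags)
        provenance = (ACHIEVED if any(f[2] == ACHIEVED for f in frags)
                      else FORECAST)
        merged.setdefault(iid, {})[year] = MergedValue(
            coverage=coverage, counterfactual=counterfactual,
            provenance=provenance, n_fragments=len(frags))
    unit.merged_entries = merged
    unit.milestones = {iid: sorted(set(years))
                       for iid, years in milestones.items()}

    # dense trajectories via forward fill from baseline
    years = list(range(baseline_year, horizon + 1))
    values_with: Dict[Tuple[str, int], float] = {}
    values_without: Dict[Tuple[str, int], float] = {}
    fp_iids = sorted(iid for iid in merged if specs[iid].is_family_planning)
    for iid in sorted(merged):
        base = _entry_baseline(profile, specs[iid])
        level_with, level_without = base, base
        for year in years:
            if year in merged[iid]:
                level_with = merged[iid][year].coverage
                level_without = merged[iid][year].counterfactual
            values_with[(iid, year)] = level_with
            values_without[(iid, year)] = level_without

    if fp_iids:
        cp_with = {year: max(values_with[(iid, year)] for iid in fp_iids)
                   for year in years}
        cp_without = {year: max(values_without[(iid, year)]
                                for iid in fp_iids)
                      for year in years}
    else:
        cp_with = {year: profile.cp0 for year in years}
        cp_without = dict(cp_with)

    # health-only pair: prevalence (and FP coverage) held at with-funder
    # values in both members
    values_health_without = dict(values_without)
    for iid in fp_iids:
        for year in years:
            values_health_without[(iid, year)] = values_with[(iid, year)]

    share = unit.population_share
    traj_with = CoverageTrajectory(values=values_with, cp=cp_with)
    traj_without = CoverageTrajectory(values=values_without, cp=cp_without)
    traj_health_without = CoverageTrajectory(values=values_health_without,
                                             cp=dict(cp_with))
    return ScenarioPair(
        with_funder=Scenario(profile, traj_with, "with_funder", share),
        without_funder=Scenario(profile, traj_without, "without_funder",
                                share),
        health_only_with=Scenario(profile,
                                  CoverageTrajectory(dict(values_with),
                                                     dict(cp_with)),
                                  "with_funder", share),
        health_only_without=Scenario(profile, traj_health_without,
                                     "without_funder", share),
    )


# ---------------------------------------------------------------------------
# country and global analysis
# ---------------------------------------------------------------------------


def run_country_analysis(register: Sequence[ProjectRecord],
                         profile: CountryProfile,
                         specs: Mapping[str, InterventionSpec],
                         mode: str,
                         behaviour_conversion: float = 1.0) -> LivesSavedResult:
    """Screen, group, assemble and model one country's register.

    Units with zero usable years under the run mode (e.g. all-forecast
    units in achieved mode) are logged and skipped; a country can report
    projects without any being analysable.
    """
    eligible, _excluded = screen_projects(register, specs)
    units = group_analysis_units(eligible)
    results: List[LivesSavedResult] = []
    for unit in units:
        try:
            pair = assemble_scenarios(unit, profile, specs, mode,
                                      behaviour_conversion)
        except UnusableUnitError as err:
            logger.warning("skipping unit: %s", err)
            continue
        results.append(analyze_pair(pair, specs))
    if not results:
        return LivesSavedResult(country_id=profile.country_id,
                                baseline_year=profile.baseline_year)
    return sum_results(results, country_id=profile.country_id)


def aggregate_global(
        country_results: Mapping[str, LivesSavedResult]) -> LivesSavedResult:
    """Elementwise sum of country results into a global estimate."""
    if not country_results:
        raise ValidationError("no country results to aggregate")
    return sum_results([country_results[c] for c in sorted(country_results)],
                       country_id="global")


@dataclass
class PipelineResult:
    """Full register run: screening output, units and all results."""

    mode: str
    eligible: List[ProjectRecord]
    excluded: List[Tuple[str, str]]
    units: List[AnalysisUnit]
    country_results: Dict[str, LivesSavedResult]
    global_result: LivesSavedResult


def run_register(register: Sequence[ProjectRecord],
                 profiles: Mapping[str, CountryProfile],
                 specs: Mapping[str, InterventionSpec],
                 mode: str,
                 behaviour_conversion: float = 1.0) -> PipelineResult:
    """Run the full protocol over a multi-country register."""
    eligible, excluded = screen_projects(register, specs)
    units = group_analysis_units(eligible)
    country_results: Dict[str, LivesSavedResult] = {}
    for country_id in sorted({p.country_id for p in register}):
        if country_id not in profiles:
            raise ValidationError(f"no profile for country {country_id!r}")
        profile = profiles[country_id]
        unit_results: List[LivesSavedResult] = []
        for unit in units:
            if unit.country_id != country_id:
                continue
            try:
                pair = assemble_scenarios(unit, profile, specs, mode,
                                          behaviour_conversion)
            except UnusableUnitError as err:
                logger.warning("skipping unit: %s", err)
                continue
            unit_results.append(analyze_pair(pair, specs))
        if unit_results:
            country_results[country_id] = sum_results(
                unit_results, country_id=country_id)
        else:
            country_results[country_id] = LivesSavedResult(
                country_id=country_id, baseline_year=profile.baseline_year)
    return PipelineResult(mode=mode, eligible=eligible, excluded=excluded,
                          units=units, country_results=country_results,
                          global_result=aggregate_global(country_results))
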
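"""Independent closed-form re-derivation of the full pipeline output.

This module recomputes expected lives saved for a register by direct
evaluation of the stated formulas in plain, explicit loops.  It reuses the
package's *data containers* only — none of the engine or protocol
computation code — so equality between the pipeline and this module is a
genuine two-implementation cross-check, not a tautology.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .model import CountryProfile, InterventionSpec, LivesSavedResult
from .protocol import ProjectRecord

_OVERLAP = 1.08
_SPAN = 35.0
_CLAMP = 1e-12

_SERIES = ("maternal_total", "maternal_fp", "maternal_health",
           "newborn_primary", "newborn_fertility")


def _convert(entry, year, behaviour_conversion: float):
    """Resolve provenance and convert one indicator value to coverage."""
    yv = entry.annual_values[year]
    if yv.achieved is not None:
        value, provenance = yv.achieved, "achieved"
    elif yv.forecast is not None:
        value, provenance = yv.forecast, "forecast"
    else:
        return None
    kind = entry.indicator_type
    if kind == "coverage":
        coverage = value
    else:
        coverage = value / entry.target_population
        if kind == "message_exposure":
            coverage = coverage * behaviour_conversion
        if coverage > 1.0:
            coverage = 1.0
    return coverage, provenance


def _unit_truth(projects: Sequence[ProjectRecord],
                profile: CountryProfile,
                library: Mapping[str, InterventionSpec],
                mode: str,
                share: float,
                behaviour_conversion: float) -> Optional[dict]:
    """Expected series and attribution for one analysis unit, or None."""
    base_year = profile.baseline_year

    # achieved-mode horizon: latest year with any achieved value
    if mode == "achieved":
        horizon = None
        for project in projects:
            for entry in project.entries:
                if entry.intervention_id not in library:
                    continue
                for year, yv in entry.annual_values.items():
                    if (yv.achieved is not None
                            and base_year < year <= profile.horizon_year):
                        if horizon is None or year > horizon:
                            horizon = year
        if horizon is None:
            return None
    else:
        horizon = profile.horizon_year

    # per-fragment coverage and counterfactual, then max-merge
    merged: Dict[Tuple[str, int], List[float]] = {}
    merged_cf: Dict[Tuple[str, int], List[float]] = {}
    any_fragment = False
    for project in projects:
        for entry in project.entries:
            iid = entry.intervention_id
            if iid not in library or entry.indicator_type == "milestone":
                continue
            spec = library[iid]
            if spec.is_family_planning:
                base = profile.cp0
            else:
                base = profile.baseline_coverage.get(iid, 0.0)
            attribution = project.attribution
            if entry.attribution_override is not None:
                attribution = entry.attribution_override
            for year in entry.annual_values:
                if not base_year < year <= horizon:
                    continue
                converted = _convert(entry, year, behaviour_conversion)
                if converted is None:
                    continue
                coverage, _prov = converted
                cf = base + (1.0 - attribution) * (coverage - base)
                merged.setdefault((iid, year), []).append(coverage)
                merged_cf.setdefault((iid, year), []).append(cf)
                any_fragment = True
    if not any_fragment:
        return None

    iids = sorted({iid for iid, _ in merged})
    years = list(range(base_year, horizon + 1))

    cov_with: Dict[str, Dict[int, float]] = {}
    cov_without: Dict[str, Dict[int, float]] = {}
    for iid in iids:
        if library[iid].is_family_planning:
            base = profile.cp0
        else:
            base = profile.baseline_coverage.get(iid, 0.0)
        level_w, level_c = base, base
        cov_with[iid], cov_without[iid] = {}, {}
        for year in years:
            if (iid, year) in merged:
                level_w = max(merged[(iid, year)])
                level_c = max(merged_cf[(iid, year)])
            cov_with[iid][year] = level_w
            cov_without[iid][year] = level_c

    fp_iids = [iid for iid in iids if library[iid].is_family_planning]
    if fp_iids:
        cp_with = {y: max(cov_with[i][y] for i in fp_iids) for y in years}
        cp_without = {y: max(cov_without[i][y] for i in fp_iids)
                      for y in years}
    else:
        cp_with = {y: profile.cp0 for y in years}
        cp_without = dict(cp_with)

    # health-only counterfactual: non-FP at counterfactual coverage,
    # FP held at with-funder values, prevalence at with-funder values
    cov_health_without = {iid: (dict(cov_with[iid]) if iid in fp_iids
                                else dict(cov_without[iid]))
                          for iid in iids}

    eff = profile.contraceptive_effectiveness
    c_base = 1.0 - _OVERLAP * profile.cp0 * eff
    cohort0 = profile.women_reproductive_age * profile.tfr0 / _SPAN

    def births_for(cp: Mapping[int, float]) -> Dict[int, float]:
        return {y: cohort0 * (1.0 - _OVERLAP * cp[y] * eff) / c_base * share
                for y in years}

    group_tables = (("neonatal", profile.neonatal_cause_fractions,
                     profile.nmr0 / 1000.0),
                    ("maternal", profile.maternal_cause_fractions,
                     profile.mmr0 / 100000.0))

    def deaths_for(cov: Mapping[str, Mapping[int, float]],
                   cp: Mapping[int, float]) -> Dict[str, Dict[Tuple[int, str], float]]:
        births = births_for(cp)
        out: Dict[str, Dict[Tuple[int, str], float]] = {"neonatal": {},
                                                        "maternal": {}}
        for group, fractions, rate in group_tables:
            for cause, frac in fractions.items():
                denom = 1.0
                for iid in iids:
                    base_cov = profile.baseline_coverage.get(iid, 0.0)
                    for e in library[iid].effects:
                        if e.target_group == group and e.cause == cause:
                            denom *= (1.0 - e.effectiveness
                                      * e.affected_fraction * base_cov)
                for year in years:
                    numer = 1.0
                    for iid in iids:
                        c = cov[iid][year]
                        for e in library[iid].effects:
                            if e.target_group == group and e.cause == cause:
                                numer *= (1.0 - e.effectiveness
                                          * e.affected_fraction * c)
                    out[group][(year, cause)] = (births[year] * rate * frac
                                                 * numer / denom)
        return out

    d_with = deaths_for(cov_with, cp_with)
    d_without = deaths_for(cov_without, cp_without)
    d_hwith = deaths_for(cov_with, cp_with)
    d_hwithout = deaths_for(cov_health_without, cp_with)

    def annual_diff(a, b, group) -> Dict[int, float]:
        out = {y: 0.0 for y in years}
        for (year, cause), count in b[group].items():
            out[year] += count - a[group][(year, cause)]
        return out

    full_m = annual_diff(d_with, d_without, "maternal")
    health_m = annual_diff(d_hwith, d_hwithout, "maternal")
    full_n = annual_diff(d_with, d_without, "neonatal")
    health_n = annual_diff(d_hwith, d_hwithout, "neonatal")

    series = {
        "maternal_total": {y: full_m[y] for y in years if y > base_year},
        "maternal_health": {y: health_m[y] for y in years if y > base_year},
        "maternal_fp": {y: full_m[y] - health_m[y] for y in years
                        if y > base_year},
        "newborn_primary": {y: health_n[y] for y in years if y > base_year},
        "newborn_fertility": {y: full_n[y] - health_n[y] for y in years
                              if y > base_year},
    }

    # per-intervention attribution: log-residual shares of the direct
    # health component, fertility-mediated maternal savings to FP specs
    per_intervention: Dict[str, float] = {iid: 0.0 for iid in iids}
    for group, fractions, _rate in group_tables:
        for cause in fractions:
            for year in years:
                averted = (d_hwithout[group][(year, cause)]
                           - d_hwith[group][(year, cause)])
                if averted == 0.0:
                    continue
                weights: Dict[str, float] = {}
                for iid in iids:
                    w = 0.0
                    for e in library[iid].effects:
                        if e.target_group == group and e.cause == cause:
                            x = e.effectiveness * e.affected_fraction
                            fw = max(1.0 - x * cov_with[iid][year], _CLAMP)
                            fwo = max(1.0 - x * cov_health_without[iid][year],
                                      _CLAMP)
                            w += math.log(fwo) - math.log(fw)
                    if w != 0.0:
                        weights[iid] = w
                total_w = sum(weights.values())
                if not weights or total_w == 0.0:
                    touching = [iid for iid in iids
                                if any(e.target_group == group
                                       and e.cause == cause
                                       for e in library[iid].effects)]
                    for iid in touching:
                        per_intervention[iid] += averted / len(touching)
                    continue
                for iid, w in weights.items():
                    per_intervention[iid] += averted * w / total_w
    fp_total = sum(full_m[y] - health_m[y] for y in years)
    if fp_iids:
        for iid in fp_iids:
            per_intervention[iid] += fp_total / len(fp_iids)
    elif abs(fp_total) > 1e-9:
        per_intervention["<unattributed_fertility>"] = fp_total

    return {"series": series, "per_intervention": per_intervention}


def closed_form_truth(register: Sequence[ProjectRecord],
                      profiles: Mapping[str, CountryProfile],
                      library: Mapping[str, InterventionSpec],
                      mode: str,
                      behaviour_conversion: float = 1.0,
                      ) -> Dict[str, LivesSavedResult]:
    """Expected per-country and global lives saved for a register.

    Returns a map country_id -> LivesSavedResult plus a ``"global"`` entry.
    """
    countries = sorted({p.country_id for p in register})
    results: Dict[str, LivesSavedResult] = {}
    for cid in countries:
        profile = profiles[cid]
        # screening: bilateral, has data, maps to the library
        eligible = []
        for project in register:
            if project.country_id != cid:
                continue
            if project.management != "bilateral":
                continue
            has_data = any(yv.achieved is not None or yv.forecast is not None
                           for e in project.entries
                           for yv in e.annual_values.values())
            if not has_data:
                continue
            if not any(e.intervention_id in library for e in project.entries):
                continue
            eligible.append(project)
        # grouping by geography label; national units take share 1
        by_geo: Dict[str, List[ProjectRecord]] = {}
        for project in eligible:
            by_geo.setdefault(project.geography_id, []).append(project)

        result = LivesSavedResult(country_id=cid,
                                  baseline_year=profile.baseline_year)
        for geo in sorted(by_geo):
            projects = by_geo[geo]
            share = 1.0 if geo == "national" else projects[0].population_share
            unit = _unit_truth(projects, profile, library, mode, share,
                               behaviour_conversion)
            if unit is None:
                continue
            for name in _SERIES:
                target = result.series(name)
                for year, v in unit["series"][name].items():
                    target[year] = target.get(year, 0.0) + v
            for iid, v in unit["per_intervention"].items():
                result.per_intervention[iid] = (
                    result.per_intervention.get(iid, 0.0) + v)
        results[cid] = result

    total = LivesSavedResult(
        country_id="global",
        baseline_year=min(profiles[c].baseline_year for c in countries))
    for cid in countries:
        for name in _SERIES:
            target = total.series(name)
            for year, v in results[cid].series(name).items():
                target[year] = target.get(year, 0.0) + v
        for iid, v in results[cid].per_intervention.items():
            total.per_intervention[iid] = (
                total.per_intervention.get(iid, 0.0) + v)
    results["global"] = total
    return results
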
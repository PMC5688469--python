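"""Readers and writers for the register CSV, profiles and libraries.

Register CSV: one row per (project, intervention, year) with columns
``project_id, country_id, management, start_year, end_year, total_funding,
attribution, geography_id, population_share, intervention_id,
indicator_type, year, value, provenance, target_population`` plus an
optional ``entry_attribution`` override.  A project with no data appears as
a single row with blank value/provenance.  Profiles and intervention
libraries are YAML (or JSON) documents mirroring the dataclass fields.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import CountryProfile, Effect, InterventionSpec, ValidationError
from .protocol import InterventionEntry, ProjectRecord, YearValue
from .reporting import MortalityEstimate

REGISTER_COLUMNS = [
    "project_id", "country_id", "management", "start_year", "end_year",
    "total_funding", "attribution", "geography_id", "population_share",
    "intervention_id", "indicator_type", "year", "value", "provenance",
    "target_population",
]


def _isnan(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def load_register(path: str | Path) -> List[ProjectRecord]:
    """Parse a register CSV into project records."""
    frame = pd.read_csv(path)
    missing = [c for c in REGISTER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"register is missing columns: {missing}")
    has_override = "entry_attribution" in frame.columns

    projects: List[ProjectRecord] = []
    for project_id, rows in frame.groupby("project_id", sort=True):
        head = rows.iloc[0]
        entries: Dict[str, InterventionEntry] = {}
        order: List[str] = []
        # accumulate values per (intervention, year, provenance)
        raw: Dict[str, dict] = {}
        for _, row in rows.iterrows():
            if _isnan(row["value"]) or _isnan(row["intervention_id"]):
                continue
            iid = str(row["intervention_id"])
            if iid not in raw:
                target = (None if _isnan(row["target_population"])
                          else float(row["target_population"]))
                override = None
                if has_override and not _isnan(row.get("entry_attribution")):
                    override = float(row["entry_attribution"])
                raw[iid] = {"indicator_type": str(row["indicator_type"]),
                            "target_population": target,
                            "attribution_override": override,
                            "annual": {}}
                order.append(iid)
            provenance = str(row["provenance"])
            if provenance not in ("achieved", "forecast"):
                raise ValidationError(
                    f"project {project_id!r}: bad provenance {provenance!r}")
            year = int(row["year"])
            yv = raw[iid]["annual"].setdefault(year, YearValue())
            value = float(row["value"])
            previous = getattr(yv, provenance)
            # duplicate rows for one provenance-year keep the maximum
            setattr(yv, provenance,
                    value if previous is None else max(previous, value))
        for iid in order:
            spec = raw[iid]
            entries[iid] = InterventionEntry(
                intervention_id=iid,
                indicator_type=spec["indicator_type"],
                annual_values=spec["annual"],
                target_population=spec["target_population"],
                attribution_override=spec["attribution_override"])
        projects.append(ProjectRecord(
            project_id=str(project_id),
            country_id=str(head["country_id"]),
            management=str(head["management"]),
            start_year=int(head["start_year"]),
            end_year=int(head["end_year"]),
            total_funding=float(head["total_funding"]),
            attribution=float(head["attribution"]),
            geography_id=str(head["geography_id"]),
            population_share=float(head["population_share"]),
            entries=list(entries.values())))
    return projects


def write_register(register: Sequence[ProjectRecord],
                   path: str | Path) -> Path:
    """Write project records to the register CSV template."""
    rows = []
    for project in register:
        base = {
            "project_id": project.project_id,
            "country_id": project.country_id,
            "management": project.management,
            "start_year": project.start_year,
            "end_year": project.end_year,
            "total_funding": project.total_funding,
            "attribution": project.attribution,
            "geography_id": project.geography_id,
            "population_share": project.population_share,
        }
        wrote_any = False
        for entry in project.entries:
            for year in sorted(entry.annual_values):
                yv = entry.annual_values[year]
                for provenance in ("achieved", "forecast"):
                    value = getattr(yv, provenance)
                    if value is None:
                        continue
                    rows.append({**base,
                                 "intervention_id": entry.intervention_id,
                                 "indicator_type": entry.indicator_type,
                                 "year": year, "value": value,
                                 "provenance": provenance,
                                 "target_population": entry.target_population,
                                 "entry_attribution":
                                     entry.attribution_override})
                    wrote_any = True
        if not wrote_any:
            rows.append({**base, "intervention_id": None,
                         "indicator_type": None, "year": None, "value": None,
                         "provenance": None, "target_population": None,
                         "entry_attribution": None})
    frame = pd.DataFrame(rows, columns=REGISTER_COLUMNS
                         + ["entry_attribution"])
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# profiles and libraries (YAML / JSON)
# ---------------------------------------------------------------------------


def profile_to_dict(profile: CountryProfile) -> dict:
    return {
        "country_id": profile.country_id,
        "baseline_year": profile.baseline_year,
        "horizon_year": profile.horizon_year,
        "tfr0": profile.tfr0,
        "women_reproductive_age": profile.women_reproductive_age,
        "nmr0": profile.nmr0,
        "mmr0": profile.mmr0,
        "neonatal_cause_fractions": dict(profile.neonatal_cause_fractions),
        "maternal_cause_fractions": dict(profile.maternal_cause_fractions),
        "baseline_coverage": dict(profile.baseline_coverage),
        "cp0": profile.cp0,
        "contraceptive_effectiveness": profile.contraceptive_effectiveness,
        "mortality_source": profile.mortality_source,
    }


def profile_from_dict(data: Mapping) -> CountryProfile:
    return CountryProfile(**data)


def load_profile(path: str | Path) -> CountryProfile:
    with open(path) as handle:
        return profile_from_dict(yaml.safe_load(handle))


def write_profile(profile: CountryProfile, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        yaml.safe_dump(profile_to_dict(profile), handle, sort_keys=True)
    return path


def load_profiles(directory: str | Path) -> Dict[str, CountryProfile]:
    """Load every ``*.yaml``/``*.yml``/``*.json`` profile in a directory."""
    directory = Path(directory)
    profiles: Dict[str, CountryProfile] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in (".yaml", ".yml", ".json"):
            profile = load_profile(path)
            profiles[profile.country_id] = profile
    if not profiles:
        raise ValidationError(f"no profiles found in {directory}")
    return profiles


def library_to_list(specs: Mapping[str, InterventionSpec]) -> list:
    out = []
    for iid in sorted(specs):
        spec = specs[iid]
        out.append({
            "intervention_id": spec.intervention_id,
            "name": spec.name,
            "period": spec.period,
            "category": spec.category,
            "is_family_planning": spec.is_family_planning,
            "effects": [{"target_group": e.target_group, "cause": e.cause,
                         "effectiveness": e.effectiveness,
                         "affected_fraction": e.affected_fraction}
                        for e in spec.effects],
        })
    return out


def library_from_list(data: Sequence[Mapping]) -> Dict[str, InterventionSpec]:
    specs: Dict[str, InterventionSpec] = {}
    for item in data:
        effects = tuple(
            Effect(target_group=e["target_group"], cause=e["cause"],
                   effectiveness=e["effectiveness"],
                   affected_fraction=e.get("affected_fraction", 1.0))
            for e in item.get("effects", []))
        spec = InterventionSpec(
            intervention_id=item["intervention_id"],
            name=item.get("name", item["intervention_id"]),
            period=item["period"],
            category=item["category"],
            effects=effects,
            is_family_planning=item.get("is_family_planning", False))
        specs[spec.intervention_id] = spec
    if not specs:
        raise ValidationError("intervention library is empty")
    return specs


def load_library(path: str | Path) -> Dict[str, InterventionSpec]:
    with open(path) as handle:
        return library_from_list(yaml.safe_load(handle))


def write_library(specs: Mapping[str, InterventionSpec],
                  path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        yaml.safe_dump(library_to_list(specs), handle, sort_keys=False)
    return path


def load_mortality_sources(path: str | Path) -> List[MortalityEstimate]:
    """CSV with columns country_id, source_label, nmr, mmr."""
    frame = pd.read_csv(path)
    needed = ["country_id", "source_label", "nmr", "mmr"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValidationError(f"mortality table missing columns: {missing}")
    return [MortalityEstimate(country_id=str(r.country_id),
                              source_label=str(r.source_label),
                              nmr=float(r.nmr), mmr=float(r.mmr))
            for r in frame.itertuples()]


def write_mortality_sources(sources: Sequence[MortalityEstimate],
                            path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([s.__dict__ for s in sources]).to_csv(path, index=False)
    return path
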
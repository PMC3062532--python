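"""Packaged parameter fixtures and CSV/YAML I/O.

Two parameter sets ship with the package:

* ``baseline_coverage.csv`` — published 2010 baseline coverage (percent) for
  the nine non-breastfeeding interventions in the 68 high-burden priority
  countries, plus each country's region (which drives the region-specific
  ambitious safe-water target).  The sentinel ``na`` in the vitamin A column
  marks countries not considered vitamin-A deficient; they are excluded from
  the vitamin A intervention entirely, which is different from zero coverage.
* ``intervention_parameters.yaml`` — effectiveness, affected fraction, age
  range and WASH/treatment flags per intervention; scenario coverage targets;
  breastfeeding relative risks and practice targets.

All other inputs (country profiles, breastfeeding baselines, cost inputs) are
user- or generator-supplied files in the dialects read and written here.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from .domain import (
    AGE_BANDS,
    BF_BANDS,
    BF_CATEGORIES,
    START_YEAR,
    YEARS,
    BreastfeedingState,
    CountryProfile,
    CoverageRecord,
    InterventionSpec,
    ScenarioSpec,
)

#: Canonical order of the nine non-breastfeeding interventions (fixture
#: column order).  Breastfeeding is modeled separately via relative risks.
INTERVENTION_IDS = (
    "improved_water",
    "treated_water",
    "improved_sanitation",
    "handwashing",
    "ors",
    "antibiotics_dysentery",
    "zinc",
    "rotavirus",
    "vitamin_a",
)

SCENARIO_NAMES = ("baseline", "ambitious", "universal")

_EXCLUDED_SENTINEL = "na"


class FixtureError(ValueError):
    """A fixture or input file failed to parse or validate."""


def _packaged(name: str) -> Path:
    return Path(resources.files("diascale").joinpath("data", name))


# ---------------------------------------------------------------------------
# Coverage tables (wide CSV: one row per country, one column per intervention)
# ---------------------------------------------------------------------------

def read_coverage_csv(
    path: Union[str, Path],
) -> Tuple[List[CoverageRecord], Dict[str, str]]:
    """Read a wide-format baseline coverage table.

    Returns the coverage records (year 2010, percent; vitamin A ``na`` rows
    become excluded records) and the country -> region map.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"country", "region", *INTERVENTION_IDS}
    missing = required - set(df.columns)
    if missing:
        raise FixtureError(f"{path.name}: missing columns {sorted(missing)}")
    records: List[CoverageRecord] = []
    regions: Dict[str, str] = {}
    for idx, row in df.iterrows():
        country = row["country"]
        regions[country] = row["region"]
        for iid in INTERVENTION_IDS:
            raw = row[iid]
            if isinstance(raw, str):
                raw = raw.strip()
            if iid == "vitamin_a" and raw == _EXCLUDED_SENTINEL:
                records.append(
                    CoverageRecord(
                        country_id=country, intervention_id=iid, excluded=True
                    )
                )
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise FixtureError(
                    f"{path.name}: row {idx + 2} ({country}), column {iid!r}: "
                    f"cannot parse coverage value {raw!r}"
                ) from None
            if not 0 <= value <= 100:
                raise FixtureError(
                    f"{path.name}: row {idx + 2} ({country}), column {iid!r}: "
                    f"coverage {value} outside [0, 100]"
                )
            records.append(
                CoverageRecord(
                    country_id=country,
                    intervention_id=iid,
                    coverage=value,
                    year=START_YEAR,
                )
            )
    return records, regions


def write_coverage_csv(
    path: Union[str, Path],
    records: List[CoverageRecord],
    regions: Dict[str, str],
) -> None:
    """Write coverage records in the wide dialect :func:`read_coverage_csv`
    reads; round-trips exactly (values formatted with repr-round float)."""
    by_country: Dict[str, Dict[str, str]] = {}
    for rec in records:
        cell = _EXCLUDED_SENTINEL if rec.excluded else _format_number(rec.coverage)
        by_country.setdefault(rec.country_id, {})[rec.intervention_id] = cell
    rows = []
    for country, cells in by_country.items():
        row = {"country": country, "region": regions[country]}
        row.update({iid: cells[iid] for iid in INTERVENTION_IDS})
        rows.append(row)
    pd.DataFrame(rows, columns=["country", "region", *INTERVENTION_IDS]).to_csv(
        path, index=False
    )


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def load_table1_fixture() -> Tuple[List[CoverageRecord], Dict[str, str]]:
    """The packaged published baseline coverage table (68 countries)."""
    return read_coverage_csv(_packaged("baseline_coverage.csv"))


# ---------------------------------------------------------------------------
# Intervention parameters and scenarios
# ---------------------------------------------------------------------------

def _load_parameters() -> dict:
    with open(_packaged("intervention_parameters.yaml")) as fh:
        return yaml.safe_load(fh)


def load_intervention_specs() -> Dict[str, InterventionSpec]:
    params = _load_parameters()
    specs = {}
    for iid, p in params["interventions"].items():
        specs[iid] = InterventionSpec(
            intervention_id=iid,
            effectiveness=p["effectiveness"],
            affected_fraction=p["affected_fraction"],
            age_min_months=p["age_min_months"],
            age_max_months=p["age_max_months"],
            is_wash=p["is_wash"],
            is_treatment=p["is_treatment"],
        )
    return specs


def load_table2_fixture(
    scenario_name: str,
) -> Tuple[ScenarioSpec, Dict[str, InterventionSpec]]:
    """Scenario targets plus intervention specs for one scale-up plan.

    ``baseline`` yields a scenario with no targets (coverage held at 2010
    values).  The ambitious safe-water target resolves per region.
    """
    if scenario_name not in SCENARIO_NAMES:
        raise FixtureError(
            f"unknown scenario {scenario_name!r}; expected one of {SCENARIO_NAMES}"
        )
    params = _load_parameters()
    specs = load_intervention_specs()
    if scenario_name == "baseline":
        return ScenarioSpec(name="baseline"), specs
    targets: Dict[str, float] = {}
    regional: Dict[str, Dict[str, float]] = {}
    for iid, p in params["interventions"].items():
        if scenario_name in p.get("targets", {}):
            targets[iid] = float(p["targets"][scenario_name])
        if scenario_name in p.get("regional_targets", {}):
            regional[iid] = {
                region: float(v)
                for region, v in p["regional_targets"][scenario_name].items()
            }
    bf_targets = {
        band: {cat: float(v) for cat, v in cats.items()}
        for band, cats in params["breastfeeding_targets"][scenario_name].items()
    }
    scenario = ScenarioSpec(
        name=scenario_name,
        target_coverage=targets,
        regional_targets=regional,
        breastfeeding_targets=bf_targets,
    )
    return scenario, specs


def load_breastfeeding_rr() -> Dict[str, Dict[str, float]]:
    """Relative risk of diarrhea mortality per practice category per band."""
    params = _load_parameters()
    return {
        band: {cat: float(v) for cat, v in cats.items()}
        for band, cats in params["breastfeeding_rr"].items()
    }


# ---------------------------------------------------------------------------
# Country profiles (tidy CSV: one row per country x year)
# ---------------------------------------------------------------------------

_SHARE_COLUMNS = {band: f"death_share_{band.replace('-', '_')}" for band in AGE_BANDS}


def read_profiles_csv(path: Union[str, Path]) -> List[CountryProfile]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {
        "country",
        "region",
        "year",
        "total_population",
        "under5_population",
        "baseline_diarrheal_deaths",
        "vitamin_a_deficient",
        *_SHARE_COLUMNS.values(),
    }
    missing = required - set(df.columns)
    if missing:
        raise FixtureError(f"{path.name}: missing columns {sorted(missing)}")
    profiles = []
    for country, grp in df.groupby("country", sort=False):
        first = grp.iloc[0]
        profiles.append(
            CountryProfile(
                country_id=str(country),
                region=first["region"],
                total_population={
                    int(r["year"]): float(r["total_population"]) for _, r in grp.iterrows()
                },
                under5_population={
                    int(r["year"]): float(r["under5_population"]) for _, r in grp.iterrows()
                },
                baseline_diarrheal_deaths=float(first["baseline_diarrheal_deaths"]),
                age_band_death_shares={
                    band: float(first[col]) for band, col in _SHARE_COLUMNS.items()
                },
                vitamin_a_deficient=bool(first["vitamin_a_deficient"]),
            )
        )
    return profiles


def write_profiles_csv(path: Union[str, Path], profiles: List[CountryProfile]) -> None:
    rows = []
    for p in profiles:
        for year in YEARS:
            row = {
                "country": p.country_id,
                "region": p.region,
                "year": year,
                "total_population": _format_number(p.total_population[year]),
                "under5_population": _format_number(p.under5_population[year]),
                "baseline_diarrheal_deaths": _format_number(p.baseline_diarrheal_deaths),
                "vitamin_a_deficient": p.vitamin_a_deficient,
            }
            for band, col in _SHARE_COLUMNS.items():
                row[col] = repr(p.age_band_death_shares[band])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Breastfeeding baselines (tidy CSV: country x band x category, percent)
# ---------------------------------------------------------------------------

def read_breastfeeding_csv(path: Union[str, Path]) -> Dict[str, BreastfeedingState]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"country", "age_band", "category", "prevalence_pct"}
    missing = required - set(df.columns)
    if missing:
        raise FixtureError(f"{path.name}: missing columns {sorted(missing)}")
    states = {}
    for country, grp in df.groupby("country", sort=False):
        prev: Dict[str, Dict[str, float]] = {b: {} for b in BF_BANDS}
        for _, row in grp.iterrows():
            band, cat = row["age_band"], row["category"]
            if band not in BF_BANDS or cat not in BF_CATEGORIES:
                raise FixtureError(
                    f"{path.name}: unknown band/category ({band!r}, {cat!r}) "
                    f"for {country}"
                )
            prev[band][cat] = float(row["prevalence_pct"]) / 100.0
        states[str(country)] = BreastfeedingState(prevalence=prev)
    return states


def write_breastfeeding_csv(
    path: Union[str, Path], states: Dict[str, BreastfeedingState]
) -> None:
    rows = [
        {
            "country": country,
            "age_band": band,
            "category": cat,
            "prevalence_pct": repr(state.prevalence[band][cat] * 100.0),
        }
        for country, state in states.items()
        for band in BF_BANDS
        for cat in BF_CATEGORIES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
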
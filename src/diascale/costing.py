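"""Ingredients-based costing of coverage maintenance and scale-up.

Each intervention's annual cost is ``population in need x coverage x unit
cost`` plus a per-country outreach/communication line.  The population in
need is children under 5 for individual-level prevention (vitamin A scaled to
the 6-59 mo share), households with children under 5 for the WASH
interventions, and diarrhea episodes for treatment (all episodes for ORS and
zinc, the dysentery fraction of episodes for antibiotics).  WASH and non-WASH
cost streams are kept separate throughout; capital and health-system
strengthening costs are out of scope.

Unit costs and incidence parameters are configurable with synthetic defaults:
the published analysis priced ingredients from supply-catalogue and salary
databases that are not reproduced here, so the defaults preserve the cost
structure (per child, per episode, per household) rather than any particular
price level.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .domain import START_YEAR, YEARS, CostResult, CountryProfile
from .scaleup import trajectory_lookup

#: Intervention id used for the breastfeeding-promotion cost line; its
#: coverage proxy is the exclusive-breastfeeding (0-5 mo) prevalence.
BREASTFEEDING_PROMOTION = "breastfeeding"


class CostInputs(BaseModel):
    """Unit costs and incidence assumptions (currency units per year).

    Defaults are synthetic, chosen to be order-of-magnitude plausible for
    low-income settings: commodity-level per-child and per-episode costs,
    infrastructure-level per-household costs for WASH.
    """

    model_config = ConfigDict(frozen=True)

    #: currency per child (in the eligible age range) per year
    per_child_costs: Dict[str, float] = Field(
        default_factory=lambda: {
            "vitamin_a": 0.60,
            "rotavirus": 5.00,
            BREASTFEEDING_PROMOTION: 1.00,
        }
    )
    #: currency per treated episode (drugs, supplies, personnel time)
    per_episode_costs: Dict[str, float] = Field(
        default_factory=lambda: {
            "ors": 0.50,
            "zinc": 0.40,
            "antibiotics_dysentery": 1.20,
        }
    )
    #: currency per household with under-5 children per year
    per_household_costs: Dict[str, float] = Field(
        default_factory=lambda: {
            "handwashing": 2.00,
            "improved_sanitation": 15.00,
            "improved_water": 20.00,
            "treated_water": 3.00,
        }
    )
    episodes_per_child_year: float = Field(default=2.9, ge=0)
    dysentery_episode_fraction: float = Field(default=0.10, ge=0, le=1)
    children_per_household: float = Field(default=1.8, gt=0)
    #: share of under-5 children aged 6-59 mo (vitamin A eligibility)
    under5_share_6_59mo: float = Field(default=0.9, ge=0, le=1)
    outreach_and_communication: float = Field(default=100_000.0, ge=0)
    currency: str = "USD"

    def unit_cost(self, intervention_id: str) -> float:
        for table in (self.per_child_costs, self.per_episode_costs, self.per_household_costs):
            if intervention_id in table:
                return table[intervention_id]
        raise KeyError(f"no unit cost configured for intervention {intervention_id!r}")


def read_cost_inputs(path: Union[str, Path]) -> CostInputs:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return CostInputs(**data)


def write_cost_inputs(path: Union[str, Path], inputs: CostInputs) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(inputs.model_dump(), fh, sort_keys=True)


def population_in_need(
    profile: CountryProfile,
    intervention_id: str,
    year: int,
    inputs: CostInputs,
) -> float:
    """Denominator for one intervention's cost: children, households, or
    episodes depending on the delivery channel."""
    under5 = profile.under5_population[year]
    if intervention_id in inputs.per_household_costs:
        return float(math.ceil(under5 / inputs.children_per_household))
    if intervention_id in inputs.per_episode_costs:
        episodes = under5 * inputs.episodes_per_child_year
        if intervention_id == "antibiotics_dysentery":
            return episodes * inputs.dysentery_episode_fraction
        return episodes
    if intervention_id in inputs.per_child_costs:
        if intervention_id == "vitamin_a":
            return under5 * inputs.under5_share_6_59mo
        return under5
    raise KeyError(f"unknown intervention {intervention_id!r}")


def scenario_cost(
    profile: CountryProfile,
    coverage: Mapping[str, Mapping[int, float]],
    inputs: CostInputs,
    year: int,
    wash_ids: Optional[set] = None,
) -> Dict[str, float]:
    """Cost components for one country-year at the given coverage levels.

    ``coverage`` maps intervention id -> year -> proportion (the same lookup
    shape the impact engine uses, optionally including a breastfeeding
    promotion series).  Returns ``{"non_wash": ..., "wash": ..., "total":
    ...}``; the outreach line sits in the non-WASH stream.
    """
    if wash_ids is None:
        wash_ids = set(inputs.per_household_costs)
    non_wash = inputs.outreach_and_communication
    wash = 0.0
    for iid, series in coverage.items():
        cost = (
            population_in_need(profile, iid, year, inputs)
            * series[year]
            * inputs.unit_cost(iid)
        )
        if iid in wash_ids:
            wash += cost
        else:
            non_wash += cost
    return {"non_wash": non_wash, "wash": wash, "total": non_wash + wash}


def per_capita_additional(
    scenario_total: float, baseline_total: float, total_population: float
) -> float:
    """Additional cost per head of total population for one year."""
    if total_population <= 0:
        raise ValueError("total population must be > 0")
    return (scenario_total - baseline_total) / total_population


def cost_all(
    profiles: List[CountryProfile],
    trajectories: pd.DataFrame,
    inputs: CostInputs,
    scenario_name: str,
    bf_promotion: Optional[Mapping[str, Mapping[int, float]]] = None,
) -> CostResult:
    """Per-country annual cost streams for one scenario's trajectories.

    ``bf_promotion`` maps country id -> year -> proportion covered by
    breastfeeding promotion (exclusive 0-5 mo prevalence proxy); omitted
    countries carry no breastfeeding cost line.
    """
    rows = []
    for profile in sorted(profiles, key=lambda p: p.country_id):
        coverage = dict(trajectory_lookup(trajectories, profile.country_id))
        if bf_promotion and profile.country_id in bf_promotion:
            coverage[BREASTFEEDING_PROMOTION] = bf_promotion[profile.country_id]
        for year in YEARS:
            parts = scenario_cost(profile, coverage, inputs, year)
            rows.append(
                {
                    "country_id": profile.country_id,
                    "year": year,
                    "scenario": scenario_name,
                    "non_wash_cost": parts["non_wash"],
                    "wash_cost": parts["wash"],
                    "total_cost": parts["total"],
                }
            )
    return CostResult(costs=pd.DataFrame(rows), currency=inputs.currency)


def per_capita_table(
    baseline: CostResult,
    scaleups: Mapping[str, CostResult],
    profiles: List[CountryProfile],
) -> pd.DataFrame:
    """Per-capita cost table: baseline cost per capita plus each scale-up
    scenario's additional non-WASH and WASH cost per capita, by year
    2011-2015 with a cumulative row summed from unrounded yearly values.
    """
    pop_by_year = {
        year: sum(p.total_population[year] for p in profiles) for year in YEARS
    }
    base_totals = baseline.costs.groupby("year")[["non_wash_cost", "wash_cost", "total_cost"]].sum()
    rows = []
    post_years = [y for y in YEARS if y > START_YEAR]
    for year in post_years:
        row: Dict[str, object] = {
            "year": str(year),
            "baseline_per_capita": base_totals.loc[year, "total_cost"] / pop_by_year[year],
        }
        for name, result in scaleups.items():
            totals = result.costs.groupby("year")[["non_wash_cost", "wash_cost"]].sum()
            row[f"{name}_additional_non_wash"] = per_capita_additional(
                totals.loc[year, "non_wash_cost"],
                base_totals.loc[year, "non_wash_cost"],
                pop_by_year[year],
            )
            row[f"{name}_additional_wash"] = per_capita_additional(
                totals.loc[year, "wash_cost"],
                base_totals.loc[year, "wash_cost"],
                pop_by_year[year],
            )
        rows.append(row)
    cumulative: Dict[str, object] = {"year": f"{post_years[0]}-{post_years[-1]}"}
    for key in rows[0]:
        if key == "year":
            continue
        cumulative[key] = sum(r[key] for r in rows)
    rows.append(cumulative)
    return pd.DataFrame(rows)
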
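"""Coverage trajectories: linear scale-up from baseline to scenario target.

Coverage of every intervention rises linearly from its 2010 baseline to the
scenario's 2015 target.  A country that already exceeds a target maintains
its achieved coverage (the trajectory is constant); the baseline scenario
holds every coverage at its 2010 value.  This is the single point where
percent values from the I/O boundary become proportions in [0, 1].
"""

from __future__ import annotations

from typing import Dict, List, Optional

import pandas as pd

from .domain import (
    BF_BANDS,
    BF_CATEGORIES,
    END_YEAR,
    START_YEAR,
    YEARS,
    BreastfeedingState,
    CoverageRecord,
    ScenarioSpec,
)


def interpolate_linear(baseline: float, target: float, year: int) -> float:
    """Coverage (proportion) in ``year`` on the linear path from the 2010
    baseline to the 2015 target."""
    if not START_YEAR <= year <= END_YEAR:
        raise ValueError(f"year {year} outside projection horizon {START_YEAR}-{END_YEAR}")
    if target == baseline:  # constant trajectory, exact at every year
        return baseline
    frac = (year - START_YEAR) / (END_YEAR - START_YEAR)
    # convex combination: exact at both endpoints, never outside [baseline, target]
    return baseline * (1.0 - frac) + target * frac


def apply_maintenance_rule(baseline: float, target: float) -> float:
    """Effective target: a country that has already attained the modeled
    coverage level maintains its achieved rate rather than regressing."""
    return max(baseline, target)


def build_trajectories(
    records: List[CoverageRecord],
    regions: Dict[str, str],
    scenario: ScenarioSpec,
) -> pd.DataFrame:
    """Per-year coverage proportions for every included country x intervention.

    Returns a tidy frame ``country_id, intervention_id, year, coverage`` with
    coverage as a proportion.  Excluded records (vitamin A in non-deficient
    countries) emit no trajectory.  Interventions without a target in the
    scenario — and everything under the baseline scenario — stay constant.
    """
    rows = []
    for rec in records:
        if rec.excluded:
            continue
        if rec.coverage is None:
            raise ValueError(
                f"missing baseline coverage for ({rec.country_id}, {rec.intervention_id})"
            )
        c0 = rec.coverage / 100.0
        target_pct = scenario.target_for(rec.intervention_id, regions[rec.country_id])
        if target_pct is None:
            effective = c0
        else:
            effective = apply_maintenance_rule(c0, target_pct / 100.0)
        for year in YEARS:
            rows.append(
                {
                    "country_id": rec.country_id,
                    "intervention_id": rec.intervention_id,
                    "year": year,
                    "coverage": interpolate_linear(c0, effective, year),
                }
            )
    return pd.DataFrame(rows, columns=["country_id", "intervention_id", "year", "coverage"])


def build_breastfeeding_trajectory(
    baseline: BreastfeedingState,
    targets: Dict[str, Dict[str, float]],
    year: int,
) -> BreastfeedingState:
    """Breastfeeding practice prevalences in ``year``.

    Each named category (exclusive, predominant, partial) is interpolated
    linearly from its baseline prevalence to its percent target; the ``none``
    category is the residual ``1 - sum(named)`` and is never targeted
    directly.  Empty ``targets`` (the baseline scenario) returns the baseline
    state unchanged.
    """
    if not targets or year == START_YEAR:
        return baseline
    prevalence: Dict[str, Dict[str, float]] = {}
    for band in BF_BANDS:
        p0 = baseline.prevalence[band]
        band_targets = targets.get(band, {})
        named = {}
        for cat in BF_CATEGORIES:
            if cat == "none":
                continue
            if cat in band_targets:
                named[cat] = interpolate_linear(p0[cat], band_targets[cat] / 100.0, year)
            else:
                named[cat] = p0[cat]
        total_named = sum(named.values())
        if total_named > 1.0 + 1e-9:
            raise ValueError(
                f"band {band}, year {year}: interpolated named categories sum to "
                f"{total_named} > 1"
            )
        named["none"] = max(0.0, 1.0 - total_named)
        prevalence[band] = named
    return BreastfeedingState(prevalence=prevalence)


def trajectory_lookup(
    trajectories: pd.DataFrame, country_id: Optional[str] = None
) -> Dict[str, Dict[int, float]]:
    """Index a trajectory frame as ``intervention -> year -> coverage`` for
    one country (or for the whole frame when it holds a single country)."""
    df = trajectories
    if country_id is not None:
        df = df[df["country_id"] == country_id]
    out: Dict[str, Dict[int, float]] = {}
    for iid, grp in df.groupby("intervention_id"):
        out[iid] = dict(zip(grp["year"].astype(int), grp["coverage"].astype(float)))
    return out
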
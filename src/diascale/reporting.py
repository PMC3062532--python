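"""Report tables, summaries and the optional trajectory chart.

Rounding happens only here: deaths to whole persons, per-capita costs to
cents, shares to one decimal.  Everything upstream stays unrounded so that
cumulative rows equal sums of unrounded yearly values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import pandas as pd

from .domain import START_YEAR, CostResult, CountryProfile, ProjectionResult
from .engine import aggregate_results


def sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path, seed: Optional[int], inputs: Mapping[str, Union[str, Path]]
) -> Path:
    """Machine-readable run manifest: seed and input checksums."""
    manifest = {
        "seed": seed,
        "inputs": {name: sha256_file(p) for name, p in sorted(inputs.items())},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def deaths_csv(result: ProjectionResult, path: Union[str, Path]) -> None:
    df = result.deaths.copy()
    df["deaths"] = df["deaths"].round(0).astype(int)
    df["deaths_averted"] = df["deaths_averted"].round(0).astype(int)
    df.to_csv(path, index=False)


def proportions_csv(results: Mapping[str, ProjectionResult], path: Union[str, Path]) -> None:
    """Proportion-of-baseline series per scenario (trajectory-figure shape)."""
    frames = [r.proportion_of_baseline() for r in results.values()]
    df = pd.concat(frames, ignore_index=True)
    df["deaths"] = df["deaths"].round(0).astype(int)
    # full precision: downstream checks recompute scalars from this series
    df.to_csv(path, index=False)


def summary_json(
    results: Mapping[str, ProjectionResult], path: Union[str, Path], top_k: int = 5
) -> dict:
    summary = {}
    for name, result in results.items():
        agg = aggregate_results(result, top_k=top_k)
        prop = result.proportion_of_baseline()
        final = prop[prop["year"] == prop["year"].max()]
        summary[name] = {
            "deaths_by_year": {y: round(v) for y, v in agg["totals_by_year"].items()},
            "averted_by_year": {y: round(v) for y, v in agg["averted_by_year"].items()},
            "cumulative_averted": round(agg["cumulative_averted"]),
            "final_year_proportion_of_baseline": round(
                float(final["proportion_of_baseline"].iloc[0]), 6
            ),
            "top_k": agg["top_k"],
            "top_k_countries": agg["top_k_countries"],
            "top_k_share_pct": round(agg["top_k_share_pct"], 1),
        }
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def country_shares_table(
    result: ProjectionResult, top_k: int = 5
) -> pd.DataFrame:
    """Countries ranked by cumulative averted deaths with percent shares
    (deterministic: ties broken by country id)."""
    agg = aggregate_results(result, top_k=top_k)
    df = agg["country_shares"].copy()
    df["deaths_averted"] = df["deaths_averted"].round(0).astype(int)
    df["share_pct"] = df["share_pct"].round(1)
    df["cumulative_share_pct"] = df["share_pct"].cumsum().round(1)
    return df


def per_capita_costs_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    df = table.copy()
    for col in df.columns:
        if col != "year":
            df[col] = df[col].round(2)
    df.to_csv(path, index=False)


def plot_trajectories(
    results: Mapping[str, ProjectionResult], path: Union[str, Path]
) -> None:
    """Two-panel line chart: annual deaths and proportion of baseline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for name, result in results.items():
        prop = result.proportion_of_baseline()
        ax1.plot(prop["year"], prop["deaths"], marker="o", label=name)
        ax2.plot(prop["year"], prop["proportion_of_baseline"], marker="o", label=name)
    ax1.set_ylabel("diarrheal deaths")
    ax2.set_ylabel("proportion of baseline")
    for ax in (ax1, ax2):
        ax.set_xlabel("year")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
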
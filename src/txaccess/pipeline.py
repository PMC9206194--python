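"""End-to-end orchestration: bundle files in, table/figure analogues out.

Stages (each also exposed as a CLI subcommand) read and write plain files
so they are independently testable: dedupe -> membership -> catchment +
law overlay -> access records -> composition tables, odds ratios, state
summaries, and the interrupted-time-series check of the breakpoint.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import (
    classify_access,
    records_to_geojson,
    state_percent_without_access,
    states_exceeding,
    youth_at_risk,
)
from .catchment import RoadNetwork, travel_time_to_nearest
from .laws import protective_states, read_laws_csv
from .roster import (
    chi_square_test,
    classify_membership,
    deduplicate_roster,
    net_loss,
    read_roster_csv,
    tabulate_characteristics,
)
from .stats import (
    exclude_for_or_analysis,
    or_results_frame,
    quartile_bin,
    segmented_regression,
    univariate_or,
)

log = logging.getLogger("txaccess")

#: continuous tract covariates binned into quartiles for the OR analysis
QUARTILE_COVARIATES = (
    "svi_percentile",
    "pct_black",
    "pct_hispanic",
    "birth_rate",
    "prop_under18",
)


@dataclass
class RunConfig:
    """Paths and switches for one pipeline run."""

    input_dir: str
    output_dir: str
    mode: str = "primary"  # primary | catchment_only | expanded_law
    threshold_minutes: float = 30.0
    snap_minutes_per_unit: float = 6.0
    breakpoint_year: int = 2019
    seed: int = 0

    def __post_init__(self):
        if self.threshold_minutes <= 0:
            raise ValueError("threshold_minutes must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over a bundle directory; returns the result summary
    dict that is also written to ``run_summary.json``."""
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    r2018 = read_roster_csv(_require(indir / "clinics_2018.csv"), epoch="2018")
    r2020 = read_roster_csv(_require(indir / "clinics_2020.csv"), epoch="2020")
    tracts = pd.read_csv(_require(indir / "tracts.csv"))
    laws = read_laws_csv(_require(indir / "state_laws.csv"))
    net = RoadNetwork.from_frames(
        pd.read_csv(_require(indir / "road_nodes.csv")),
        pd.read_csv(_require(indir / "road_edges.csv")),
    )
    counts_df = pd.read_csv(_require(indir / "annual_counts.csv"))
    annual_counts = {int(r.year): float(r.n_clinics) for r in counts_df.itertuples(index=False)}

    # rosters: dedupe, difference, tabulate
    d2018, dup18 = deduplicate_roster(r2018)
    d2020, dup20 = deduplicate_roster(r2020)
    labelled = classify_membership(d2018, d2020)
    labelled.to_csv(outdir / "clinics_labelled.csv", index=False)

    protective = protective_states(laws, "primary")
    protective_exp = protective_states(laws, "expanded")
    table1_parts = []
    chi2 = {}
    for strat in ("affiliation", "urban_rural", "region", "law_status"):
        try:
            tab = tabulate_characteristics(labelled, strat, protective)
        except KeyError:
            continue
        part = tab.to_frame().reset_index().rename(columns={strat: "stratum"})
        part.insert(0, "stratifier", strat)
        table1_parts.append(part)
        cells = tab.counts[["n_2018", "n_2020"]].to_numpy()
        cells = cells[(cells > 0).all(axis=1)]
        if len(cells) >= 2:
            stat, df_, p = chi_square_test(cells)
            chi2[strat] = {"statistic": stat, "df": df_, "p": p}
    table1 = pd.concat(table1_parts, ignore_index=True)
    table1.to_csv(outdir / "table1_composition.csv", index=False)

    # catchment decisions per epoch
    origins = tracts[["cx", "cy"]].to_numpy()
    t18 = travel_time_to_nearest(
        net, origins, d2018[["lon", "lat"]].to_numpy(), config.snap_minutes_per_unit
    )
    t20 = travel_time_to_nearest(
        net, origins, d2020[["lon", "lat"]].to_numpy(), config.snap_minutes_per_unit
    )
    pd.DataFrame(
        {"tract_id": tracts["tract_id"], "minutes_2018": t18, "minutes_2020": t20}
    ).to_csv(outdir / "travel_times.csv", index=False)
    in18 = t18 <= config.threshold_minutes
    in20 = t20 <= config.threshold_minutes

    records = classify_access(tracts, in18, in20, protective, protective_exp, config.mode)
    records.to_csv(outdir / "access_records.csv", index=False)
    records_to_geojson(
        records,
        {r.tract_id: (r.cx, r.cy) for r in tracts.itertuples(index=False)},
        outdir / "access_categories.geojson",
    )

    summary = youth_at_risk(records)
    state18 = state_percent_without_access(records, "2018")
    state20 = state_percent_without_access(records, "2020")
    pd.concat([state18, state20], ignore_index=True).to_csv(
        outdir / "state_summary.csv", index=False
    )

    # odds-ratio analysis on lost vs maintained
    analysis = records.merge(
        tracts[["tract_id", "rucc", "region", *QUARTILE_COVARIATES]], on="tract_id"
    )
    analysis["urban_rural"] = pd.Categorical(
        np.where(analysis["rucc"].astype(int) <= 3, "Urban", "Rural"),
        categories=["Urban", "Rural"],
    )
    analysis["region"] = pd.Categorical(
        analysis["region"], categories=["Northeast", "Midwest", "South", "West"]
    )
    cutpoints = {}
    for cov in QUARTILE_COVARIATES:
        if analysis[cov].notna().sum() >= 4 and analysis[cov].nunique() > 1:
            analysis[f"{cov}_q"], cuts = quartile_bin(analysis[cov])
            cutpoints[cov] = [float(c) for c in cuts]
    subset = exclude_for_or_analysis(analysis)
    or_results = []
    for pred in ("urban_rural", "region", *[f"{c}_q" for c in QUARTILE_COVARIATES]):
        if pred not in subset.columns:
            continue
        try:
            or_results.extend(univariate_or(subset, pred))
        except ValueError as exc:  # a zero cell in a small scenario
            log.warning("skipping odds ratio for %s: %s", pred, exc)
    table2 = or_results_frame(or_results)
    table2.to_csv(outdir / "table2_odds_ratios.csv", index=False)

    its = segmented_regression(annual_counts, config.breakpoint_year)

    result = {
        "config": asdict(config),
        "version": __version__,
        "python": platform.python_version(),
        "n_clinics_2018": int(len(d2018)),
        "n_clinics_2020": int(len(d2020)),
        "n_duplicates_2018": int(len(dup18)),
        "n_duplicates_2020": int(len(dup20)),
        "net_loss": net_loss(labelled),
        "chi_square": chi2,
        "n_tracts": summary.n_tracts,
        "category_counts": summary.category_counts,
        "category_pct": summary.category_pct,
        "youth_at_risk": summary.youth_at_risk,
        "medicaid_at_risk": summary.medicaid_at_risk,
        "non_medicaid_at_risk": summary.non_medicaid_at_risk,
        "non_medicaid_pct": summary.non_medicaid_pct,
        "states_over_25pct_2018": states_exceeding(state18, 25.0),
        "states_over_25pct_2020": states_exceeding(state20, 25.0),
        "quartile_cutpoints": cutpoints,
        "its": {
            "breakpoint_year": its.breakpoint_year,
            "pre_slope": its.pre_slope,
            "pre_ci": list(its.pre_ci),
            "post_slope": its.post_slope,
            "post_ci": list(its.post_ci),
        },
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(result, fh, indent=2)
    with open(outdir / "its_report.txt", "w") as fh:
        fh.write(its.summary() + "\n")
    log.info(
        "pipeline done: %d tracts, %d lost (%.1f%%), net clinic loss %d",
        summary.n_tracts,
        summary.category_counts["lost"],
        summary.category_pct["lost"],
        result["net_loss"],
    )
    return result
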
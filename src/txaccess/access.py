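"""Per-tract access classification and youth-at-risk accounting.

A tract's minors have legally protected access to confidential family
planning in an epoch when either (1) at least one funded clinic lies within
the drive-time threshold of the tract's population-weighted centroid, or
(2) the tract sits in a state whose law protects minor consent and
confidentiality.  Crossing the two epochs gives a 4-category change label:
lost, maintained, gained, or never.

Modes:

* ``primary``        — catchment OR protective state (main definition);
* ``catchment_only`` — the drive-time criterion alone, irrespective of state
  law (sensitivity: protective-state tracts that lost their only clinic);
* ``expanded_law``   — catchment OR expanded-protective state (sensitivity:
  physician-discretion states folded into the protective set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import catchment as cm
from .roster import round_half_up

MODES = ("primary", "catchment_only", "expanded_law")
CATEGORIES = ("lost", "maintained", "gained", "never")


def change_category(access_2018: bool, access_2020: bool) -> str:
    """Truth table: (T,F)->lost, (T,T)->maintained, (F,T)->gained, (F,F)->never."""
    if access_2018:
        return "maintained" if access_2020 else "lost"
    return "gained" if access_2020 else "never"


def estimate_medicaid_15_17(medicaid_minors: int, prop_minors_15_17: float) -> int:
    """Medicaid-enrolled 15-17-year-olds: enrolled minors times the tract's
    proportion of minors aged 15-17, rounded half-up to a whole person."""
    if medicaid_minors < 0:
        raise ValueError("medicaid_minors must be non-negative")
    if not 0.0 <= prop_minors_15_17 <= 1.0:
        raise ValueError("prop_minors_15_17 must lie in [0, 1]")
    return int(round_half_up(medicaid_minors * prop_minors_15_17, 0))


def tract_access(
    in_catchment: bool,
    law_status_primary: str,
    law_status_expanded: str | None = None,
    mode: str = "primary",
) -> bool:
    """Combine a catchment decision with the tract's state-law status."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "catchment_only":
        return bool(in_catchment)
    if mode == "expanded_law":
        if law_status_expanded is None:
            raise ValueError("expanded_law mode needs the expanded law status")
        return bool(in_catchment) or law_status_expanded == "protective"
    return bool(in_catchment) or law_status_primary == "protective"


def classify_access(
    tracts: pd.DataFrame,
    in_range_2018: np.ndarray,
    in_range_2020: np.ndarray,
    protective: set[str],
    protective_expanded: set[str] | None = None,
    mode: str = "primary",
) -> pd.DataFrame:
    """Build the per-tract access table.

    ``tracts`` needs columns ``tract_id, state, pop_15_17, medicaid_minors,
    prop_minors_15_17``; ``in_range_*`` are boolean catchment decisions
    aligned with its rows.  Returns one row per tract with both epoch
    booleans, the change category, and the youth-at-risk splits.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    exp = protective_expanded if protective_expanded is not None else protective
    is_prot = tracts["state"].isin(list(protective)).to_numpy()
    is_prot_exp = tracts["state"].isin(list(exp)).to_numpy()
    in18 = np.asarray(in_range_2018, bool)
    in20 = np.asarray(in_range_2020, bool)
    if mode == "catchment_only":
        a18, a20 = in18, in20
    elif mode == "expanded_law":
        a18, a20 = in18 | is_prot_exp, in20 | is_prot_exp
    else:
        a18, a20 = in18 | is_prot, in20 | is_prot
    out = pd.DataFrame(
        {
            "tract_id": tracts["tract_id"].to_numpy(),
            "state": tracts["state"].to_numpy(),
            "access_2018": a18,
            "access_2020": a20,
        }
    )
    out["category"] = pd.Categorical(
        [change_category(x, y) for x, y in zip(a18, a20)], categories=CATEGORIES
    )
    out["pop_15_17"] = tracts["pop_15_17"].to_numpy()
    med = [
        estimate_medicaid_15_17(m, p)
        for m, p in zip(tracts["medicaid_minors"], tracts["prop_minors_15_17"])
    ]
    out["medicaid_15_17_est"] = np.minimum(med, out["pop_15_17"])
    out["non_medicaid_15_17_est"] = out["pop_15_17"] - out["medicaid_15_17_est"]
    return out


@dataclass
class YouthAtRiskSummary:
    """Category composition of evaluated tracts plus the youth totals in
    tracts that lost access, split by Medicaid enrollment."""

    n_tracts: int
    category_counts: dict
    category_pct: dict  # of all evaluated tracts, half-up to 1 decimal
    youth_at_risk: int  # pop 15-17 in lost tracts
    medicaid_at_risk: int
    non_medicaid_at_risk: int
    non_medicaid_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.category_counts),
                "n_tracts": list(self.category_counts.values()),
                "pct_tracts": [self.category_pct[c] for c in self.category_counts],
            }
        )


def youth_at_risk(records: pd.DataFrame) -> YouthAtRiskSummary:
    """Summarise the access table: tract counts/percentages per category
    (denominator = all evaluated tracts) and youth 15-17 living in tracts
    that lost access, stratified by estimated Medicaid enrollment."""
    n = len(records)
    counts = {c: int((records["category"] == c).sum()) for c in CATEGORIES}
    pct = {c: (round_half_up(100.0 * k / n, 1) if n else float("nan")) for c, k in counts.items()}
    lost = records[records["category"] == "lost"]
    at_risk = int(lost["pop_15_17"].sum())
    med = int(lost["medicaid_15_17_est"].sum())
    non_med = int(lost["non_medicaid_15_17_est"].sum())
    return YouthAtRiskSummary(
        n_tracts=n,
        category_counts=counts,
        category_pct=pct,
        youth_at_risk=at_risk,
        medicaid_at_risk=med,
        non_medicaid_at_risk=non_med,
        non_medicaid_pct=round_half_up(100.0 * non_med / at_risk, 1) if at_risk else float("nan"),
    )


def state_percent_without_access(records: pd.DataFrame, epoch: str) -> pd.DataFrame:
    """Per-state percentage of youth 15-17 living in tracts without access in
    ``epoch`` ('2018' or '2020'), plus a flag column helper.

    A state with zero 15-17 population gets NaN and ``undefined=True``.
    """
    col = {"2018": "access_2018", "2020": "access_2020"}[str(epoch)]
    grp = records.groupby("state", sort=True)
    rows = []
    for state, g in grp:
        tot = int(g["pop_15_17"].sum())
        no_acc = int(g.loc[~g[col], "pop_15_17"].sum())
        rows.append(
            {
                "state": state,
                "epoch": epoch,
                "youth_total": tot,
                "youth_without_access": no_acc,
                "pct_without_access": 100.0 * no_acc / tot if tot else float("nan"),
                "undefined": tot == 0,
            }
        )
    return pd.DataFrame(rows)


def states_exceeding(summary: pd.DataFrame, threshold_pct: float = 25.0) -> int:
    """How many states have more than ``threshold_pct`` of youth without access."""
    return int((summary["pct_without_access"] > threshold_pct).sum())


def records_to_geojson(records: pd.DataFrame, tract_points: dict, path) -> None:
    """Write the category map as a GeoJSON FeatureCollection of tract points
    (choropleth-style rendering input)."""
    import json

    from shapely.geometry import Point, mapping

    feats = []
    for row in records.itertuples(index=False):
        x, y = tract_points[row.tract_id]
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(float(x), float(y))),
                "properties": {
                    "tract_id": str(row.tract_id),
                    "state": str(row.state),
                    "category": str(row.category),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
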
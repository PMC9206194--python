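"""Two-epoch clinic roster handling: deduplication, membership differencing,
affiliation and urban/rural classification, and composition tables.

Rosters are pandas DataFrames with columns ``id, name, lon, lat, state,
rucc`` (plus optional ``region``, ``fqhc_flag``, ``affiliation``, ``epoch``).
Clinic identity across documents is keyed on a normalized name plus rounded
coordinates, because ids are not stable between source documents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

AFFILIATIONS = ("CrisisPregnancyCenter", "PlannedParenthood", "FQHC", "Other")
MEMBERSHIPS = ("left", "joined", "stayed")

ROSTER_COLUMNS = ["id", "name", "lon", "lat", "state", "rucc"]

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    s = _PUNCT.sub(" ", str(name).casefold())
    return _WS.sub(" ", s).strip()


def match_key(name, lon, lat, decimals: int = 4) -> tuple:
    """Duplicate/identity key: normalized name + coordinates rounded to
    ``decimals`` places (~11 m at the equator for 4 decimals)."""
    return (normalize_name(name), round(float(lon), decimals), round(float(lat), decimals))


def _keys(df: pd.DataFrame, decimals: int = 4) -> pd.Series:
    return pd.Series(
        [match_key(n, x, y, decimals) for n, x, y in zip(df["name"], df["lon"], df["lat"])],
        index=df.index,
    )


def deduplicate_roster(
    roster: pd.DataFrame, decimals: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records sharing a match key; keep the first occurrence in input order.

    Returns ``(deduplicated, duplicates)``;
    ``len(roster) == len(deduplicated) + len(duplicates)``.
    """
    if roster.empty:
        return roster.copy(), roster.copy()
    keys = _keys(roster, decimals)
    dup_mask = keys.duplicated(keep="first")
    return roster.loc[~dup_mask].copy(), roster.loc[dup_mask].copy()


def classify_membership(
    r2018: pd.DataFrame, r2020: pd.DataFrame, decimals: int = 4
) -> pd.DataFrame:
    """Partition clinics into left / joined / stayed across the two epochs.

    Input rosters must be deduplicated.  Output has one row per unique
    clinic; for clinics present in both epochs the 2020 attributes win (the
    later document is taken as the corrected record).
    """
    k18, k20 = set(_keys(r2018, decimals)), set(_keys(r2020, decimals))
    rows = []
    keys18 = _keys(r2018, decimals)
    for (_, rec), key in zip(r2018.iterrows(), keys18):
        if key not in k20:
            rows.append({**rec.to_dict(), "membership": "left"})
    keys20 = _keys(r2020, decimals)
    for (_, rec), key in zip(r2020.iterrows(), keys20):
        rows.append({**rec.to_dict(), "membership": "joined" if key not in k18 else "stayed"})
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["membership"] = pd.Categorical(out["membership"], categories=MEMBERSHIPS)
    return out


def net_loss(labelled: pd.DataFrame) -> int:
    """Clinics that left minus clinics that joined."""
    counts = labelled["membership"].value_counts()
    return int(counts.get("left", 0) - counts.get("joined", 0))


def classify_affiliation(
    name: str,
    clinic_id=None,
    fqhc_registry: set | None = None,
    cpc_registry: set | None = None,
    fqhc_flag: bool = False,
) -> str:
    """Assign exactly one affiliation.

    Precedence CrisisPregnancyCenter > PlannedParenthood > FQHC > Other:
    CPC and Planned Parenthood identification is name/registry based and, in
    practice, disjoint from FQHC designation; anything unmatched is Other.
    """
    norm = normalize_name(name)
    if cpc_registry and (clinic_id in cpc_registry or norm in cpc_registry):
        return "CrisisPregnancyCenter"
    if "planned parenthood" in norm:
        return "PlannedParenthood"
    if fqhc_flag or (fqhc_registry and (clinic_id in fqhc_registry or norm in fqhc_registry)):
        return "FQHC"
    return "Other"


def add_affiliation(
    roster: pd.DataFrame,
    fqhc_registry: set | None = None,
    cpc_registry: set | None = None,
) -> pd.DataFrame:
    """Vectorised affiliation column; keeps an existing one if present."""
    out = roster.copy()
    if "affiliation" in out.columns and out["affiliation"].notna().all():
        return out
    flags = out["fqhc_flag"].astype(bool) if "fqhc_flag" in out.columns else [False] * len(out)
    out["affiliation"] = [
        classify_affiliation(n, i, fqhc_registry, cpc_registry, f)
        for n, i, f in zip(out["name"], out["id"], flags)
    ]
    return out


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up, matching how printed tables round percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _stratum(df: pd.DataFrame, stratifier: str, protective: set[str] | None) -> pd.Series:
    if stratifier == "affiliation":
        return df["affiliation"]
    if stratifier == "urban_rural":
        return pd.Series(
            np.where(df["rucc"].astype(int) <= 3, "Urban", "Rural"), index=df.index
        )
    if stratifier == "region":
        return df["region"]
    if stratifier == "law_status":
        if protective is None:
            raise ValueError("law_status stratifier needs the protective-state set")
        return pd.Series(
            np.where(df["state"].isin(list(protective)), "Protective", "NotProtective"),
            index=df.index,
        )
    raise ValueError(
        f"unknown stratifier {stratifier!r}; expected affiliation, urban_rural, region or law_status"
    )


@dataclass
class ContingencyTable:
    """Composition table: counts per stratum for each epoch, net change, and
    column percentages rounded half-up to one decimal."""

    stratifier: str
    counts: pd.DataFrame  # index strata; columns n_2018, n_2020, net_change
    percentages: pd.DataFrame  # pct_2018, pct_2020, pct_change_of_2018

    def to_frame(self) -> pd.DataFrame:
        return self.counts.join(self.percentages)


def tabulate_characteristics(
    labelled: pd.DataFrame,
    stratifier: str,
    protective_states: set[str] | None = None,
) -> ContingencyTable:
    """Table-1 style composition: epoch membership (2018 = left+stayed,
    2020 = stayed+joined) crossed with a clinic stratifier."""
    in18 = labelled[labelled["membership"].isin(["left", "stayed"])]
    in20 = labelled[labelled["membership"].isin(["stayed", "joined"])]
    s18 = _stratum(in18, stratifier, protective_states).value_counts()
    s20 = _stratum(in20, stratifier, protective_states).value_counts()
    strata = sorted(set(s18.index) | set(s20.index), key=str)
    counts = pd.DataFrame(
        {
            "n_2018": [int(s18.get(s, 0)) for s in strata],
            "n_2020": [int(s20.get(s, 0)) for s in strata],
        },
        index=pd.Index(strata, name=stratifier),
    )
    counts["net_change"] = counts["n_2020"] - counts["n_2018"]
    tot18, tot20 = counts["n_2018"].sum(), counts["n_2020"].sum()
    pct = pd.DataFrame(index=counts.index)
    pct["pct_2018"] = [round_half_up(100.0 * n / tot18, 1) if tot18 else np.nan for n in counts["n_2018"]]
    pct["pct_2020"] = [round_half_up(100.0 * n / tot20, 1) if tot20 else np.nan for n in counts["n_2020"]]
    # percent change relative to the 2018 stratum size, as printed alongside net change
    pct["pct_change_of_2018"] = [
        round_half_up(100.0 * abs(c) / n18, 1) if n18 else np.nan
        for c, n18 in zip(counts["net_change"], counts["n_2018"])
    ]
    return ContingencyTable(stratifier, counts, pct)


def chi_square_test(cells) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on an r x c table.

    Returns (statistic, df, p).  A zero expected cell is an error naming the
    cell, since the statistic is undefined there.
    """
    table = np.asarray(cells, float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("need a 2-D table of non-negative counts")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    zeros = np.argwhere(expected == 0)
    if len(zeros):
        raise ValueError(f"expected count is zero in cell {tuple(zeros[0])}")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def read_roster_csv(path, epoch: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"roster {path} missing columns: {sorted(missing)}")
    if epoch is not None:
        df["epoch"] = epoch
    return df
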
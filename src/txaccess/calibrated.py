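"""Study-calibrated synthetic fixtures.

These builders construct rosters and tract tables whose *marginal counts*
match the published composition of the Title X evaluation (clinic exits,
affiliation/urban/region/law margins, per-category tract counts, Table-2
contingency cells, youth totals), so the tabulation, classification and
odds-ratio machinery can be exercised against the printed arithmetic.
Geography, names and joint attribute combinations are synthetic: only the
margins are calibrated.

Default counts are the published ones; every count is a parameter so the
builders are reusable at other sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .laws import StateLaw

# ---------------------------------------------------------------------------
# rosters
# ---------------------------------------------------------------------------

#: membership-block attribute margins (stayed / left / joined) chosen so the
#: per-epoch margins reproduce the published Table-1 columns:
#: 2018 = stayed + left, 2020 = stayed + joined
_DEFAULT_ROSTER = dict(
    stayed=2600,
    left=1743,
    joined=494,
    dup_2018=123,
    dup_2020=14,
    affiliation=dict(
        stayed={"PlannedParenthood": 5, "FQHC": 1051, "Other": 1544, "CrisisPregnancyCenter": 0},
        left={"PlannedParenthood": 481, "FQHC": 324, "Other": 938, "CrisisPregnancyCenter": 0},
        joined={"PlannedParenthood": 0, "FQHC": 100, "Other": 386, "CrisisPregnancyCenter": 8},
    ),
    urban=dict(stayed=1700, left=1093, joined=170),  # 2018: 2793 urban / 1550 rural
    region=dict(
        stayed={"Northeast": 250, "Midwest": 400, "South": 1500, "West": 450},
        left={"Northeast": 531, "Midwest": 316, "South": 361, "West": 535},
        joined={"Northeast": 63, "Midwest": 99, "South": 188, "West": 144},
    ),
    protective=dict(stayed=1200, left=1014, joined=398),  # 2018: 2214 / 2129
)


def _expand(margins: dict[str, int], order=None) -> list[str]:
    out = []
    for k in order or margins:
        out.extend([k] * int(margins[k]))
    return out


def calibrated_rosters(spec: dict | None = None):
    """Build (roster_2018, roster_2020, laws) matching published margins.

    The 2018 roster contains ``stayed + left`` unique clinics plus
    ``dup_2018`` exact-copy duplicate records; the 2020 roster contains
    ``stayed + joined`` plus ``dup_2020`` duplicates.  Stayed clinics share
    name + coordinates across epochs (ids differ, as in the source
    documents).  Affiliation, urban/rural, region and law-state attributes
    are assigned independently within each membership block so every
    published per-epoch margin is exact.
    """
    m = {**_DEFAULT_ROSTER, **(spec or {})}
    blocks = {}
    idx = 0
    for block in ("stayed", "left", "joined"):
        n = int(m[block])
        aff = _expand(m["affiliation"][block])
        if len(aff) != n:
            raise ValueError(f"{block}: affiliation margins sum to {len(aff)}, expected {n}")
        urban = [True] * int(m["urban"][block]) + [False] * (n - int(m["urban"][block]))
        region = _expand(m["region"][block])
        if len(region) != n:
            raise ValueError(f"{block}: region margins sum to {len(region)}, expected {n}")
        n_prot = int(m["protective"][block])
        state = ["PROT"] * n_prot + ["NOPR"] * (n - n_prot)
        rows = []
        for i in range(n):
            k = idx + i
            rows.append(
                {
                    "name": f"{aff[i]} clinic {k}",
                    "lon": float(k),
                    "lat": 0.0,
                    "state": state[i],
                    "region": region[i],
                    "rucc": 1 if urban[i] else 5,
                    "affiliation": aff[i],
                    "fqhc_flag": int(aff[i] == "FQHC"),
                }
            )
        blocks[block] = pd.DataFrame(rows)
        idx += n

    def _with_ids(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        df = df.copy()
        df.insert(0, "id", [f"{prefix}{i:05d}" for i in range(len(df))])
        return df

    r2018 = pd.concat([blocks["stayed"], blocks["left"]], ignore_index=True)
    r2020 = pd.concat([blocks["stayed"], blocks["joined"]], ignore_index=True)
    r2018 = _with_ids(r2018, "A")
    r2020 = _with_ids(r2020, "B")
    # duplicate records: exact name+coordinate copies under fresh ids
    d18 = r2018.head(int(m["dup_2018"])).copy()
    d18["id"] = [f"AD{i:05d}" for i in range(len(d18))]
    d20 = r2020.head(int(m["dup_2020"])).copy()
    d20["id"] = [f"BD{i:05d}" for i in range(len(d20))]
    r2018 = pd.concat([r2018, d18], ignore_index=True)
    r2020 = pd.concat([r2020, d20], ignore_index=True)
    laws = [
        StateLaw("PROT", True, True, False, False),
        StateLaw("NOPR", False, False, False, True),
    ]
    return r2018, r2020, laws


# ---------------------------------------------------------------------------
# tracts
# ---------------------------------------------------------------------------

#: per-category tract counts and Table-2 contingency cells; cells need not
#: sum to the block totals (the remainder is assigned missing, mirroring the
#: <1% missing-data exclusion)
_DEFAULT_TRACTS = dict(
    maintained=61_063,
    lost=6_299,
    gained=729,
    never=4_669,
    youth_lost=933_649,
    medicaid_youth_lost=290_799,
    youth_never=878_169,
    rural=dict(maintained=8_139, lost=1_028),
    region=dict(
        maintained={"Northeast": 12_069, "Midwest": 11_740, "South": 23_241, "West": 14_013},
        lost={"Northeast": 1_153, "Midwest": 2_706, "South": 1_003, "West": 1_437},
    ),
    svi_q=dict(
        maintained={"Q1": 14_824, "Q2": 14_708, "Q3": 15_063, "Q4": 15_978},
        lost={"Q1": 2_049, "Q2": 1_700, "Q3": 1_394, "Q4": 1_127},
    ),
    pct_black_q=dict(
        maintained={"Q1": 13_025, "Q2": 15_033, "Q3": 16_046, "Q4": 16_682},
        lost={"Q1": 2_248, "Q2": 1_824, "Q3": 1_230, "Q4": 976},
    ),
    pct_hispanic_q=dict(
        maintained={"Q1": 14_287, "Q2": 14_759, "Q3": 15_441, "Q4": 16_299},
        lost={"Q1": 1_778, "Q2": 1_965, "Q3": 1_615, "Q4": 920},
    ),
    birth_rate_q=dict(
        maintained={"Q1": 15_286, "Q2": 14_804, "Q3": 15_464, "Q4": 15_232},
        lost={"Q1": 1_472, "Q2": 1_659, "Q3": 1_674, "Q4": 1_473},
    ),
    prop_under18_q=dict(
        maintained={"Q1": 15_403, "Q2": 15_045, "Q3": 14_947, "Q4": 15_391},
        lost={"Q1": 1_525, "Q2": 1_686, "Q3": 1_591, "Q4": 1_476},
    ),
    protective_maintained=34_452,  # remaining maintained tracts are non-protective
)

QUARTILE_COLUMNS = ("svi_q", "pct_black_q", "pct_hispanic_q", "birth_rate_q", "prop_under18_q")


def _distribute(total: int, n: int) -> np.ndarray:
    """Split ``total`` into ``n`` integers differing by at most 1."""
    if n == 0:
        return np.zeros(0, int)
    base, rem = divmod(int(total), n)
    out = np.full(n, base, int)
    out[:rem] += 1
    return out


def _assign_levels(n: int, margins: dict[str, int]) -> list:
    """Level labels per margins; rows beyond the margin total get NA."""
    out = _expand(margins)
    if len(out) > n:
        raise ValueError(f"margins sum {len(out)} exceeds block size {n}")
    return out + [pd.NA] * (n - len(out))


def calibrated_tracts(spec: dict | None = None) -> pd.DataFrame:
    """Access-record table with published per-category counts and cells.

    One row per tract with ``access_2018/access_2020`` booleans, the change
    category, youth counts whose block sums hit the published totals, and
    categorical covariate columns matching every Table-2 contingency cell
    (rows beyond a cell total carry NA, mirroring missing covariates).
    """
    m = {**_DEFAULT_TRACTS, **(spec or {})}
    frames = []
    bools = {"maintained": (True, True), "lost": (True, False), "gained": (False, True), "never": (False, False)}
    for cat in ("maintained", "lost", "gained", "never"):
        n = int(m[cat])
        a18, a20 = bools[cat]
        df = pd.DataFrame(
            {
                "tract_id": [f"{cat[:1].upper()}{i:05d}" for i in range(n)],
                "category": cat,
                "access_2018": a18,
                "access_2020": a20,
            }
        )
        if cat == "lost":
            df["pop_15_17"] = _distribute(m["youth_lost"], n)
            med = _distribute(m["medicaid_youth_lost"], n)
            # medicaid_minors * prop = exact integer target per tract
            df["medicaid_minors"] = med * 2
            df["prop_minors_15_17"] = 0.5
            df["rucc"] = np.where(np.arange(n) < n - int(m["rural"]["lost"]), 1, 5)
            df["region"] = _assign_levels(n, m["region"]["lost"])
            for col in QUARTILE_COLUMNS:
                df[col] = _assign_levels(n, m[col]["lost"])
            df["state"] = "NOPR"
        elif cat == "maintained":
            df["pop_15_17"] = 0
            df["medicaid_minors"] = 0
            df["prop_minors_15_17"] = 0.0
            df["rucc"] = np.where(np.arange(n) < n - int(m["rural"]["maintained"]), 1, 5)
            df["region"] = _assign_levels(n, m["region"]["maintained"])
            for col in QUARTILE_COLUMNS:
                df[col] = _assign_levels(n, m[col]["maintained"])
            n_prot = int(m["protective_maintained"])
            df["state"] = np.where(np.arange(n) < n_prot, "PROT", "NOPR")
        else:
            df["pop_15_17"] = _distribute(m["youth_never"], n) if cat == "never" else 0
            df["medicaid_minors"] = 0
            df["prop_minors_15_17"] = 0.0
            df["rucc"] = 1
            df["region"] = pd.NA
            for col in QUARTILE_COLUMNS:
                df[col] = pd.NA
            df["state"] = "NOPR"
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["category"] = pd.Categorical(out["category"], categories=["lost", "maintained", "gained", "never"])
    out["medicaid_15_17_est"] = (out["medicaid_minors"] * out["prop_minors_15_17"]).round().astype(int)
    out["non_medicaid_15_17_est"] = out["pop_15_17"] - out["medicaid_15_17_est"]
    for col in ("region", *QUARTILE_COLUMNS):
        cats = ["Northeast", "Midwest", "South", "West"] if col == "region" else ["Q1", "Q2", "Q3", "Q4"]
        out[col] = pd.Categorical(out[col], categories=cats, ordered=col != "region")
    out["urban_rural"] = pd.Categorical(
        np.where(out["rucc"] <= 3, "Urban", "Rural"), categories=["Urban", "Rural"]
    )
    return out


def calibrated_annual_counts(
    seed: int = 0,
    start_year: int = 2006,
    end_year: int = 2020,
    breakpoint_year: int = 2019,
    base_count: float = 6000.0,
    pre_slope: float = -68.2,
    post_slope: float = -918.8,
    noise_sd: float = 10.0,
) -> dict[int, int]:
    """Annual clinic-count series with the published segment slopes planted
    (the real 2006-2020 series is not published; this stands in for it)."""
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    pre_end = base_count + pre_slope * (breakpoint_year - 1 - start_year)
    mu = np.where(
        years < breakpoint_year,
        base_count + pre_slope * (years - start_year),
        pre_end + post_slope * (years - (breakpoint_year - 1)),
    )
    counts = np.maximum(0, np.round(mu + rng.normal(0, noise_sd, len(years)))).astype(int)
    return {int(y): int(c) for y, c in zip(years, counts)}
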
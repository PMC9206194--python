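"""Seed-reproducible synthetic scenarios for the access pipeline.

A scenario emulates the joint structure of the study inputs without any
real data: states laid out as square blocks on a plane, tracts nested in
states (each with 1-9 population-weighted sub-unit points), a two-epoch
clinic roster whose exit/entry behaviour varies by affiliation (and
optionally region), a road network over all tract centroids and clinic
sites, a one-record-per-state law table, and an annual clinic-count series
with a policy breakpoint.

Planted effects
---------------
Access loss is produced *mechanically*: clinics exit, catchments shrink,
and a tract in a non-protective state that had an in-range clinic in the
first epoch but none in the second has lost access.  Covariates named in
``planted_or`` are then sampled conditionally on that realised loss
indicator so that the downstream lost-vs-maintained contingency odds
ratios converge to the planted values: binary/categorical covariates get
level probabilities whose odds differ by the planted OR, and continuous
covariates get a top-vs-bottom-quartile OR with a geometric gradient
across quartiles (Q_k odds multiplier = OR^((k-1)/3)).  Covariates not
named are drawn from their base distributions independent of loss.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, drawn in a fixed documented order, so equal configs give equal
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .catchment import RoadNetwork, travel_time_to_nearest
from .laws import StateLaw, protective_states

REGIONS = ("Northeast", "Midwest", "South", "West")

AFFILIATION_KEYS = ("FQHC", "PlannedParenthood", "CrisisPregnancyCenter", "Other")

#: continuous covariates that can carry a planted quartile OR, with the base
#: quantile function used to materialise values inside an assigned quartile
_CONTINUOUS_BASES = {
    "svi_percentile": lambda u: u,
    "pct_black": lambda u: sps.beta(0.6, 4.0).ppf(u) * 100.0,
    "pct_hispanic": lambda u: sps.beta(0.7, 4.0).ppf(u) * 100.0,
    "birth_rate": lambda u: sps.lognorm(s=0.9, scale=45.0).ppf(u),
    "prop_under18": lambda u: sps.beta(15.0, 50.0).ppf(u),
}

_PLANTABLE = {"rural", "midwest", "south", "west", *_CONTINUOUS_BASES}


class ConfigurationError(ValueError):
    """Invalid scenario configuration."""


class GenerationError(RuntimeError):
    """Degenerate inputs made generation impossible."""


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic world; defaults echo the study's magnitudes
    (clinic density ~0.06 per tract, ~40% of the roster exiting, ~11%
    entering, 99% of Planned Parenthood sites exiting, 40% of states
    protective)."""

    n_states: int = 20
    states_protective_fraction: float = 0.4
    n_tracts_per_state: int = 50
    region_labels: Sequence[str] = REGIONS
    clinic_density: float = 0.06
    exit_prob_by_affiliation: Mapping[str, float] = field(
        default_factory=lambda: {
            "FQHC": 0.25,
            "PlannedParenthood": 0.99,
            "CrisisPregnancyCenter": 0.0,
            "Other": 0.36,
        }
    )
    entry_rate: float = 0.11
    duplicate_rate: float = 0.0
    planted_or: Mapping[str, float] = field(default_factory=dict)
    road_speed_minutes_per_unit: float = 6.0
    seed: int = 0
    # secondary knobs
    affiliation_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "FQHC": 0.317,
            "PlannedParenthood": 0.112,
            "CrisisPregnancyCenter": 0.0,
            "Other": 0.571,
        }
    )
    entry_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "FQHC": 0.45,
            "PlannedParenthood": 0.0,
            "CrisisPregnancyCenter": 0.02,
            "Other": 0.53,
        }
    )
    exit_multiplier_by_region: Mapping[str, float] = field(default_factory=dict)
    rural_base_rate: float = 0.15
    region_base_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "Northeast": 0.20,
            "Midwest": 0.19,
            "South": 0.38,
            "West": 0.23,
        }
    )
    threshold_minutes: float = 30.0
    knn_neighbors: int = 4
    # annual-count (interrupted time series) series
    its_start_year: int = 2006
    its_end_year: int = 2020
    its_breakpoint: int = 2019
    its_base_count: float = 6000.0
    its_pre_slope: float = -68.2
    its_post_slope: float = -918.8
    its_noise_sd: float = 10.0

    def __post_init__(self):
        if self.n_states < 1 or self.n_tracts_per_state < 1:
            raise ConfigurationError("n_states and n_tracts_per_state must be >= 1")
        probs = {
            "states_protective_fraction": self.states_protective_fraction,
            "entry_rate": self.entry_rate,
            "duplicate_rate": self.duplicate_rate,
            "rural_base_rate": self.rural_base_rate,
            **{f"exit[{k}]": v for k, v in self.exit_prob_by_affiliation.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0,1], got {p}")
        for k, v in self.planted_or.items():
            if k not in _PLANTABLE:
                raise ConfigurationError(
                    f"cannot plant an OR on {k!r}; plantable: {sorted(_PLANTABLE)}"
                )
            if not float(v) > 0:
                raise ConfigurationError(f"planted OR for {k!r} must be > 0, got {v}")
        if not self.road_speed_minutes_per_unit > 0:
            raise ConfigurationError("road_speed_minutes_per_unit must be positive")
        if not self.clinic_density > 0:
            raise ConfigurationError("clinic_density must be positive")


@dataclass
class ScenarioBundle:
    """Everything one scenario produces."""

    config: ScenarioConfig
    tracts: pd.DataFrame
    subunits: pd.DataFrame  # tract_id, x, y, weight
    clinics_2018: pd.DataFrame
    clinics_2020: pd.DataFrame
    road_network: RoadNetwork
    state_laws: list[StateLaw]
    annual_counts: dict[int, int]

    @property
    def tract_points(self) -> dict:
        return {r.tract_id: (r.cx, r.cy) for r in self.tracts.itertuples(index=False)}


def _knn_mst_edges(points: np.ndarray, k: int) -> list[tuple[int, int, float]]:
    """k-nearest-neighbour edges plus a Euclidean MST (via Delaunay) so the
    network is connected; returns (i, j, distance) with i < j."""
    n = len(points)
    if n < 2:
        raise GenerationError("need at least 2 points for a road network")
    if np.allclose(points, points[0]):
        raise GenerationError("all points coincide; cannot build a road network")
    pairs: set[tuple[int, int]] = set()
    if n <= 3:
        pairs.update((i, j) for i in range(n) for j in range(i + 1, n))
    else:
        tree = cKDTree(points)
        _, idx = tree.query(points, k=min(k + 1, n))
        for i in range(n):
            for j in idx[i, 1:]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                if a != b:
                    pairs.add((a, b))
        try:
            tri = Delaunay(points)
            dpairs = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        u, v = sorted((int(simplex[a]), int(simplex[b])))
                        dpairs.add((u, v))
            rows = np.array([p[0] for p in dpairs])
            cols = np.array([p[1] for p in dpairs])
            d = np.linalg.norm(points[rows] - points[cols], axis=1)
            g = sparse.coo_matrix((d, (rows, cols)), shape=(n, n))
            mst = minimum_spanning_tree(g).tocoo()
            pairs.update(
                (min(int(u), int(v)), max(int(u), int(v)))
                for u, v in zip(mst.row, mst.col)
            )
        except QhullError:
            # collinear layouts: chain consecutive points instead
            order = np.lexsort((points[:, 1], points[:, 0]))
            pairs.update(
                (min(int(a), int(b)), max(int(a), int(b)))
                for a, b in zip(order[:-1], order[1:])
            )
    out = []
    for i, j in sorted(pairs):
        d = float(np.linalg.norm(points[i] - points[j]))
        if d > 0:
            out.append((i, j, d))
    return out


def generate_road_network(
    config: ScenarioConfig, tract_centroids, clinic_points
) -> RoadNetwork:
    """Connected road network over tract centroids + clinic sites.

    Nodes sit at every supplied point; edges are k-nearest-neighbour links
    augmented with a Euclidean minimum spanning tree; edge weight is
    Euclidean length times ``road_speed_minutes_per_unit``.
    """
    cent = np.asarray(list(tract_centroids), float)
    clin = np.asarray(list(clinic_points), float).reshape(-1, 2)
    points = cent if len(clin) == 0 else np.vstack([cent, clin])
    edges = _knn_mst_edges(points, config.knn_neighbors)
    nodes = {i: tuple(points[i]) for i in range(len(points))}
    return RoadNetwork(
        nodes,
        [(i, j, d * config.road_speed_minutes_per_unit) for i, j, d in edges],
        geographic=False,
    )


def grid_network(nx_: int, ny_: int, spacing: float = 1.0, minutes_per_unit: float = 1.0) -> RoadNetwork:
    """Rectangular grid network (test utility): shortest-path time between
    any two grid nodes equals Manhattan distance x minutes-per-unit."""
    nodes = {(i, j): (i * spacing, j * spacing) for i in range(nx_) for j in range(ny_)}
    edges = []
    for i in range(nx_):
        for j in range(ny_):
            if i + 1 < nx_:
                edges.append(((i, j), (i + 1, j), spacing * minutes_per_unit))
            if j + 1 < ny_:
                edges.append(((i, j), (i, j + 1), spacing * minutes_per_unit))
    return RoadNetwork(nodes, edges)


_NAME_STEMS = {
    "FQHC": "Community Health Center",
    "PlannedParenthood": "Planned Parenthood Health Center",
    "CrisisPregnancyCenter": "Caring Pregnancy Resource Center",
    "Other": "Family Planning Clinic",
}


def _draw_affiliations(rng, n, mix: Mapping[str, float]) -> np.ndarray:
    keys = list(AFFILIATION_KEYS)
    p = np.array([float(mix.get(k, 0.0)) for k in keys])
    if p.sum() <= 0:
        raise ConfigurationError("affiliation mix must have positive total mass")
    return rng.choice(keys, size=n, p=p / p.sum())


def _conditional_u(rng, lost: np.ndarray, theta: float) -> np.ndarray:
    """Quantile draws u in [0,1): uniform for kept tracts, quartile-tilted
    (odds multiplier theta^((k-1)/3) for quartile k) for lost tracts."""
    n = len(lost)
    u = rng.random(n)
    n_lost = int(lost.sum())
    if n_lost:
        mult = np.array([theta ** (k / 3.0) for k in range(4)])
        probs = mult / mult.sum()
        q = rng.choice(4, size=n_lost, p=probs)
        u[lost] = (q + rng.random(n_lost)) / 4.0
    return u


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate one complete scenario from a config (single RNG stream).

    Draw order: state laws/regions -> tract layout and sub-units -> 2018
    clinics -> exits/entries -> duplicates -> road network -> internal
    catchment run -> loss-conditional covariates -> annual counts.
    """
    rng = np.random.default_rng(config.seed)
    regions = list(config.region_labels)

    # --- states, laws, regions ---------------------------------------------
    n_prot = int(round(config.n_states * config.states_protective_fraction))
    prot_flags = np.zeros(config.n_states, bool)
    prot_flags[rng.permutation(config.n_states)[:n_prot]] = True
    state_ids = [f"S{i:02d}" for i in range(config.n_states)]
    state_region = {
        s: regions[i % len(regions)] for i, s in enumerate(state_ids)
    }
    laws = []
    for i, s in enumerate(state_ids):
        if prot_flags[i]:
            laws.append(StateLaw(s, True, True, False, False))
        else:
            kind = rng.integers(0, 3)
            laws.append(
                StateLaw(
                    s,
                    consent_all_minors=kind == 2,
                    confidentiality_guaranteed=False,
                    physician_discretion_disclosure=kind == 2,
                    limited_categories_only=kind == 1,
                )
            )
    protective = protective_states(laws, "primary")

    # --- tract layout: each state is a square block side sqrt(tracts) ------
    side = float(np.sqrt(config.n_tracts_per_state))
    n_tracts = config.n_states * config.n_tracts_per_state
    tract_state = np.repeat(np.arange(config.n_states), config.n_tracts_per_state)
    offsets = tract_state * (side + 1.0)  # 1-unit gap between state blocks
    cx = offsets + rng.random(n_tracts) * side
    cy = rng.random(n_tracts) * side
    tract_ids = [f"T{i:05d}" for i in range(n_tracts)]

    n_sub = rng.integers(1, 10, size=n_tracts)
    sub_rows = []
    centroids = np.empty((n_tracts, 2))
    for i in range(n_tracts):
        k = int(n_sub[i])
        pts = np.column_stack(
            [cx[i] + rng.normal(0, 0.15, k), cy[i] + rng.normal(0, 0.15, k)]
        )
        w = rng.lognormal(5.0, 0.8, k)
        centroids[i] = (pts[:, 0] @ w / w.sum(), pts[:, 1] @ w / w.sum())
        for (x, y), ww in zip(pts, w):
            sub_rows.append((tract_ids[i], x, y, ww))
    subunits = pd.DataFrame(sub_rows, columns=["tract_id", "x", "y", "weight"])

    # --- 2018 clinics -------------------------------------------------------
    n_clinics = max(1, int(round(config.clinic_density * n_tracts)))
    host = rng.integers(0, n_tracts, size=n_clinics)
    clin_xy = centroids[host] + rng.normal(0, 0.3, (n_clinics, 2))
    affil = _draw_affiliations(rng, n_clinics, config.affiliation_mix)
    counters: dict[str, int] = {}
    names, ruccs = [], []
    for a in affil:
        counters[a] = counters.get(a, 0) + 1
        names.append(f"{_NAME_STEMS[a]} {counters[a]}")
    ruccs = np.where(rng.random(n_clinics) < 0.65, rng.integers(1, 4, n_clinics), rng.integers(4, 10, n_clinics))
    clin_states = [state_ids[tract_state[h]] for h in host]
    clinics_2018 = pd.DataFrame(
        {
            "id": [f"C{i:05d}" for i in range(n_clinics)],
            "name": names,
            "lon": clin_xy[:, 0],
            "lat": clin_xy[:, 1],
            "state": clin_states,
            "region": [state_region[s] for s in clin_states],
            "rucc": ruccs,
            "affiliation": affil,
            "fqhc_flag": (affil == "FQHC").astype(int),
        }
    )

    # --- exits and entries --------------------------------------------------
    exit_p = np.array(
        [
            min(
                1.0,
                float(config.exit_prob_by_affiliation.get(a, 0.0))
                * float(config.exit_multiplier_by_region.get(r, 1.0)),
            )
            for a, r in zip(affil, clinics_2018["region"])
        ]
    )
    exited = rng.random(n_clinics) < exit_p
    survivors = clinics_2018.loc[~exited].copy()

    n_entry = rng.binomial(n_clinics, config.entry_rate)
    ent_host = rng.integers(0, n_tracts, size=n_entry)
    ent_xy = centroids[ent_host] + rng.normal(0, 0.3, (n_entry, 2))
    ent_aff = _draw_affiliations(rng, n_entry, config.entry_mix) if n_entry else np.array([], dtype=object)
    ent_names = []
    for a in ent_aff:
        counters[a] = counters.get(a, 0) + 1
        ent_names.append(f"{_NAME_STEMS[a]} {counters[a]}")
    ent_rucc = np.where(rng.random(n_entry) < 0.65, rng.integers(1, 4, n_entry), rng.integers(4, 10, n_entry))
    ent_states = [state_ids[tract_state[h]] for h in ent_host]
    entrants = pd.DataFrame(
        {
            "id": [f"E{i:05d}" for i in range(n_entry)],
            "name": ent_names,
            "lon": ent_xy[:, 0] if n_entry else np.empty(0),
            "lat": ent_xy[:, 1] if n_entry else np.empty(0),
            "state": ent_states,
            "region": [state_region[s] for s in ent_states],
            "rucc": ent_rucc,
            "affiliation": ent_aff,
            "fqhc_flag": (ent_aff == "FQHC").astype(int) if n_entry else np.empty(0, int),
        }
    )
    clinics_2020 = pd.concat([survivors, entrants], ignore_index=True)

    def _inject_duplicates(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        dup = rng.random(len(df)) < config.duplicate_rate
        if not dup.any():
            return df.reset_index(drop=True)
        copies = df.loc[dup].copy()
        copies["id"] = [f"{prefix}{i:05d}" for i in range(len(copies))]
        return pd.concat([df, copies], ignore_index=True)

    clinics_2018_out = _inject_duplicates(clinics_2018, "D18-")
    clinics_2020_out = _inject_duplicates(clinics_2020, "D20-")

    # --- road network and the realised loss indicator -----------------------
    all_clinic_xy = np.vstack([clin_xy, ent_xy]) if n_entry else clin_xy
    net = generate_road_network(config, centroids, all_clinic_xy)
    snap = config.road_speed_minutes_per_unit
    t18 = travel_time_to_nearest(
        net, centroids, clinics_2018[["lon", "lat"]].to_numpy(), snap_minutes_per_unit=snap
    )
    t20 = travel_time_to_nearest(
        net, centroids, clinics_2020[["lon", "lat"]].to_numpy(), snap_minutes_per_unit=snap
    )
    in18 = t18 <= config.threshold_minutes
    in20 = t20 <= config.threshold_minutes
    state_col = np.array([state_ids[s] for s in tract_state])
    is_prot = np.isin(state_col, list(protective))
    a18, a20 = in18 | is_prot, in20 | is_prot
    lost = a18 & ~a20

    # --- covariates, conditional on loss where an OR is planted -------------
    planted = dict(config.planted_or)

    if "rural" in planted:
        p0 = config.rural_base_rate
        odds1 = planted["rural"] * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        p_rural = np.where(lost, p1, p0)
    else:
        p_rural = np.full(n_tracts, config.rural_base_rate)
    rural = rng.random(n_tracts) < p_rural
    tract_rucc = np.where(rural, rng.integers(4, 10, n_tracts), rng.integers(1, 4, n_tracts))

    region_keys = {"midwest": "Midwest", "south": "South", "west": "West"}
    if any(k in planted for k in region_keys):
        base = np.array([float(config.region_base_shares.get(r, 0.0)) for r in REGIONS])
        base = base / base.sum()
        mult = np.array(
            [1.0]
            + [float(planted.get(k, 1.0)) for k in ("midwest", "south", "west")]
        )
        p_lost = base * mult
        p_lost = p_lost / p_lost.sum()
        reg_idx = np.where(
            lost,
            rng.choice(4, size=n_tracts, p=p_lost),
            rng.choice(4, size=n_tracts, p=base),
        )
        tract_region = np.array(REGIONS, dtype=object)[reg_idx]
    else:
        tract_region = np.array([state_region[s] for s in state_col], dtype=object)

    cont = {}
    for name, ppf in _CONTINUOUS_BASES.items():
        if name in planted:
            u = _conditional_u(rng, lost, float(planted[name]))
        else:
            u = rng.random(n_tracts)
        cont[name] = ppf(np.clip(u, 1e-9, 1 - 1e-9))

    population_total = np.maximum(50, rng.lognormal(8.3, 0.5, n_tracts).astype(int))
    minors = np.minimum(
        population_total, np.round(population_total * cont["prop_under18"]).astype(int)
    )
    prop_15_17 = np.clip(rng.normal(0.17, 0.03, n_tracts), 0.05, 0.4)
    pop_15_17 = np.minimum(minors, np.round(minors * prop_15_17).astype(int))
    medicaid_minors = rng.binomial(minors, np.clip(rng.beta(2.0, 4.0, n_tracts), 0, 1))
    prop_minors_15_17 = np.divide(
        pop_15_17, minors, out=np.zeros(n_tracts), where=minors > 0
    ).clip(0.0, 1.0)

    tracts = pd.DataFrame(
        {
            "tract_id": tract_ids,
            "state": state_col,
            "region": tract_region,
            "rucc": tract_rucc,
            "cx": centroids[:, 0],
            "cy": centroids[:, 1],
            "population_total": population_total,
            "pop_15_17": pop_15_17,
            "medicaid_minors": medicaid_minors,
            "prop_minors_15_17": prop_minors_15_17,
            "pct_black": cont["pct_black"],
            "pct_hispanic": cont["pct_hispanic"],
            "svi_percentile": cont["svi_percentile"],
            "birth_rate": cont["birth_rate"],
            "prop_under18": cont["prop_under18"],
        }
    )

    # --- annual count series -----------------------------------------------
    years = np.arange(config.its_start_year, config.its_end_year + 1)
    b = config.its_breakpoint
    pre_end = config.its_base_count + config.its_pre_slope * (b - 1 - config.its_start_year)
    mu = np.where(
        years < b,
        config.its_base_count + config.its_pre_slope * (years - config.its_start_year),
        pre_end + config.its_post_slope * (years - (b - 1)),
    )
    counts = np.maximum(0, np.round(mu + rng.normal(0, config.its_noise_sd, len(years)))).astype(int)
    annual_counts = {int(y): int(c) for y, c in zip(years, counts)}

    return ScenarioBundle(
        config=config,
        tracts=tracts,
        subunits=subunits,
        clinics_2018=clinics_2018_out,
        clinics_2020=clinics_2020_out,
        road_network=net,
        state_laws=laws,
        annual_counts=annual_counts,
    )


# ---------------------------------------------------------------------------
# bundle I/O (plain CSV + GeoJSON)
# ---------------------------------------------------------------------------

def write_bundle(bundle: ScenarioBundle, outdir) -> None:
    """Write the bundle as plain files: per-epoch clinic CSVs, tract
    attribute + sub-unit CSVs, tract GeoJSON, road node/edge CSVs, state-law
    CSV and annual-count CSV."""
    import json
    from pathlib import Path

    from shapely.geometry import Point, mapping

    from .laws import write_laws_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.clinics_2018.to_csv(outdir / "clinics_2018.csv", index=False)
    bundle.clinics_2020.to_csv(outdir / "clinics_2020.csv", index=False)
    bundle.tracts.to_csv(outdir / "tracts.csv", index=False)
    bundle.subunits.to_csv(outdir / "subunits.csv", index=False)
    node_df, edge_df = bundle.road_network.to_frames()
    node_df.to_csv(outdir / "road_nodes.csv", index=False)
    edge_df.to_csv(outdir / "road_edges.csv", index=False)
    write_laws_csv(bundle.state_laws, outdir / "state_laws.csv")
    pd.DataFrame(
        {"year": list(bundle.annual_counts), "n_clinics": list(bundle.annual_counts.values())}
    ).to_csv(outdir / "annual_counts.csv", index=False)
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(Point(r.cx, r.cy)),
            "properties": {"tract_id": r.tract_id, "state": r.state},
        }
        for r in bundle.tracts.itertuples(index=False)
    ]
    with open(outdir / "tracts.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def load_bundle(indir, config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    from pathlib import Path

    from .laws import read_laws_csv

    indir = Path(indir)
    node_df = pd.read_csv(indir / "road_nodes.csv")
    edge_df = pd.read_csv(indir / "road_edges.csv")
    counts = pd.read_csv(indir / "annual_counts.csv")
    return ScenarioBundle(
        config=config or ScenarioConfig(),
        tracts=pd.read_csv(indir / "tracts.csv"),
        subunits=pd.read_csv(indir / "subunits.csv"),
        clinics_2018=pd.read_csv(indir / "clinics_2018.csv"),
        clinics_2020=pd.read_csv(indir / "clinics_2020.csv"),
        road_network=RoadNetwork.from_frames(node_df, edge_df),
        state_laws=read_laws_csv(indir / "state_laws.csv"),
        annual_counts={int(r.year): int(r.n_clinics) for r in counts.itertuples(index=False)},
    )
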
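"""Drive-time catchment decisions over a road network.

A tract has access in an epoch when at least one funded clinic lies within a
travel-time threshold (default 30 minutes, inclusive) of the tract's
population-weighted centroid.  Travel time is shortest-path cost over an
undirected road network whose edge weights are minutes; origins and clinics
are snapped to their nearest network node, and the off-network snap distance
is converted to minutes at a configured access speed.

Coordinates may be planar (synthetic mode; Euclidean distances in coordinate
units) or geographic lon/lat (haversine distances in kilometres).  A
network-free fallback converts straight-line distance to minutes directly at
a configured speed; on a complete graph whose edges encode straight-line
times the two modes agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

#: maximum reasonable travel time to care, after Medicaid network standards
DEFAULT_THRESHOLD_MINUTES = 30.0

#: off-network access speed: minutes per distance unit (planar unit or km)
DEFAULT_SNAP_MINUTES_PER_UNIT = 1.0

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _distance(p, q, geographic: bool) -> float:
    if geographic:
        return float(haversine_km(p[0], p[1], q[0], q[1]))
    return math.hypot(p[0] - q[0], p[1] - q[1])


def population_weighted_centroid(subunits) -> tuple[float, float]:
    """Population-weighted mean of sub-unit coordinates.

    ``subunits`` is a sequence of ``(x, y, weight)`` triples (or an (n, 3)
    array).  Weights must be non-negative with a positive sum; the result is
    invariant to uniform weight rescaling.
    """
    arr = np.asarray(list(subunits) if not isinstance(subunits, np.ndarray) else subunits, float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError("subunits must be a non-empty sequence of (x, y, weight)")
    w = arr[:, 2]
    if np.any(w < 0):
        raise ValueError("sub-unit weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total sub-unit weight must be positive")
    return (float(arr[:, 0] @ w / total), float(arr[:, 1] @ w / total))


class RoadNetwork:
    """Undirected road graph with located nodes and minute-weighted edges."""

    def __init__(
        self,
        nodes: Mapping[object, tuple[float, float]],
        edges: Iterable[tuple[object, object, float]],
        geographic: bool = False,
    ):
        if not nodes:
            raise ValueError("road network needs at least one node")
        self.coords: dict = {k: (float(x), float(y)) for k, (x, y) in nodes.items()}
        self.geographic = bool(geographic)
        g = nx.Graph()
        g.add_nodes_from(self.coords)
        for u, v, minutes in edges:
            if u not in self.coords or v not in self.coords:
                raise ValueError(f"edge ({u!r}, {v!r}) references an unknown node")
            minutes = float(minutes)
            if not minutes > 0:
                raise ValueError(f"edge ({u!r}, {v!r}) must have positive minutes, got {minutes}")
            # parallel edges collapse to the cheaper one
            if g.has_edge(u, v):
                minutes = min(minutes, g[u][v]["minutes"])
            g.add_edge(u, v, minutes=minutes)
        self.graph = g
        self._node_order = list(self.coords)
        self._tree = cKDTree(self._snap_space(np.array([self.coords[n] for n in self._node_order])))

    # nearest-node queries use Euclidean space directly for planar networks and
    # 3-D unit-sphere chords for lon/lat (chord order == great-circle order)
    def _snap_space(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        if not self.geographic:
            return pts
        lon, lat = np.radians(pts[:, 0]), np.radians(pts[:, 1])
        return np.column_stack(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        )

    def nearest_node(self, point) -> tuple[object, float]:
        """Nearest node id and its distance (planar units or km) from ``point``."""
        _, idx = self._tree.query(self._snap_space(np.asarray(point, float))[0])
        node = self._node_order[int(idx)]
        return node, _distance(tuple(point), self.coords[node], self.geographic)

    @classmethod
    def from_frames(cls, node_df, edge_df, geographic: bool = False) -> "RoadNetwork":
        """Build from node (id, x, y) and edge (u, v, minutes) tables."""
        nodes = {r.id: (r.x, r.y) for r in node_df.itertuples(index=False)}
        edges = [(r.u, r.v, r.minutes) for r in edge_df.itertuples(index=False)]
        return cls(nodes, edges, geographic=geographic)

    def to_frames(self):
        import pandas as pd

        node_df = pd.DataFrame(
            [(n, x, y) for n, (x, y) in self.coords.items()], columns=["id", "x", "y"]
        )
        edge_df = pd.DataFrame(
            [(u, v, d["minutes"]) for u, v, d in self.graph.edges(data=True)],
            columns=["u", "v", "minutes"],
        )
        return node_df, edge_df


def shortest_travel_time(
    net: RoadNetwork,
    origin,
    targets: Sequence,
    snap_minutes_per_unit: float = DEFAULT_SNAP_MINUTES_PER_UNIT,
) -> np.ndarray:
    """Minutes from ``origin`` to each target point over the network.

    Both ends are snapped to their nearest node; snap distances are charged
    at ``snap_minutes_per_unit``.  Unreachable targets get ``inf``.  An empty
    target list returns an empty array.
    """
    targets = list(targets)
    if not targets:
        return np.empty(0)
    o_node, o_dist = net.nearest_node(origin)
    dist = nx.single_source_dijkstra_path_length(net.graph, o_node, weight="minutes")
    out = np.empty(len(targets))
    for i, t in enumerate(targets):
        t_node, t_dist = net.nearest_node(t)
        path = dist.get(t_node, math.inf)
        out[i] = path + (o_dist + t_dist) * snap_minutes_per_unit if math.isfinite(path) else math.inf
    return out


def travel_time_to_nearest(
    net: RoadNetwork,
    origins: Sequence,
    clinic_points: Sequence,
    snap_minutes_per_unit: float = DEFAULT_SNAP_MINUTES_PER_UNIT,
) -> np.ndarray:
    """For each origin, minutes to the closest clinic (multi-source Dijkstra).

    Equivalent to the row-wise minimum of :func:`shortest_travel_time` over
    clinics but computed in one pass: a virtual source is attached to every
    clinic's snapped node at the clinic's snap cost.
    """
    origins = list(origins)
    if not origins:
        return np.empty(0)
    if not list(clinic_points):
        return np.full(len(origins), math.inf)
    g = net.graph.copy()
    src = ("__virtual_source__",)
    for c in clinic_points:
        node, d = net.nearest_node(c)
        w = d * snap_minutes_per_unit
        if g.has_edge(src, node):
            w = min(w, g[src][node]["minutes"])
        # Dijkstra needs positive-ish weights; zero snap cost is fine for nx
        g.add_edge(src, node, minutes=w)
    dist = nx.single_source_dijkstra_path_length(g, src, weight="minutes")
    out = np.empty(len(origins))
    for i, o in enumerate(origins):
        node, d = net.nearest_node(o)
        path = dist.get(node, math.inf)
        out[i] = path + d * snap_minutes_per_unit if math.isfinite(path) else math.inf
    return out


def straight_line_minutes(
    origin,
    targets: Sequence,
    minutes_per_unit: float = DEFAULT_SNAP_MINUTES_PER_UNIT,
    geographic: bool = False,
) -> np.ndarray:
    """Network-free fallback: straight-line distance converted to minutes."""
    targets = list(targets)
    if not targets:
        return np.empty(0)
    return np.array(
        [_distance(tuple(origin), tuple(t), geographic) * minutes_per_unit for t in targets]
    )


@dataclass
class Tract:
    """A census tract: the unit of access.

    ``subunits`` are population-weighted points (block-group analogues) from
    which the centroid is derived; covariates mirror ACS/SVI-style tract
    attributes.
    """

    id: object
    state: str
    region: str | None = None
    rucc: int | None = None
    subunits: Sequence[tuple[float, float, float]] | None = None
    centroid: tuple[float, float] | None = None
    population_total: int = 0
    pop_15_17: int = 0
    medicaid_minors: int = 0
    prop_minors_15_17: float = float("nan")
    pct_black: float = float("nan")
    pct_hispanic: float = float("nan")
    svi_percentile: float = float("nan")
    birth_rate: float = float("nan")
    prop_under18: float = float("nan")

    def __post_init__(self):
        if self.centroid is None:
            if not self.subunits:
                raise ValueError(f"tract {self.id!r}: need subunits or an explicit centroid")
            self.centroid = population_weighted_centroid(self.subunits)
        if self.rucc is not None and not 1 <= int(self.rucc) <= 9:
            raise ValueError(f"tract {self.id!r}: RUCC must be 1..9, got {self.rucc}")
        if self.pop_15_17 > self.population_total:
            raise ValueError(f"tract {self.id!r}: pop_15_17 exceeds total population")

    @property
    def rural(self) -> bool:
        """RUCC 4-9 counts as rural, 1-3 as urban."""
        if self.rucc is None:
            raise ValueError(f"tract {self.id!r}: RUCC unset")
        return self.rucc >= 4


def tract_within_drive(
    net: RoadNetwork,
    tract: Tract,
    clinic_points: Sequence,
    threshold_minutes: float = DEFAULT_THRESHOLD_MINUTES,
    snap_minutes_per_unit: float = DEFAULT_SNAP_MINUTES_PER_UNIT,
) -> bool:
    """True iff some clinic is within ``threshold_minutes`` (inclusive) of the
    tract centroid.  An epoch with no clinics yields False, not an error."""
    clinic_points = list(clinic_points)
    if not clinic_points:
        return False
    times = shortest_travel_time(net, tract.centroid, clinic_points, snap_minutes_per_unit)
    return bool(np.min(times) <= threshold_minutes)
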
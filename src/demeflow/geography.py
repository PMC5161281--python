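"""Georeferenced deme networks, dispersal targets and founding layouts.

Demes are local communities placed at longitude/latitude coordinates.
Two demes are connected when their great-circle distance is at most a
threshold (650 km by default), permitting both short moves between
neighbouring communities and rarer long "leapfrog" dispersals. Mainland
source demes act as a perpetual reservoir of Asian-ancestry individuals.

A start distribution is the set of demes founded with Asian ancestry at
the beginning of a run (all others are founded Papuan); libraries of
start distributions are enumerated by sequentially adding blocks of
four demes per island to the mainland base, keeping only configurations
in which the Asian demes form a connected cluster containing every
source deme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, exp

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "DEFAULT_THRESHOLD_KM",
    "great_circle_km",
    "DemeNetwork",
    "build_network",
    "CapacitySchedule",
    "choose_destination",
    "StartDistribution",
    "enumerate_start_distributions",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_THRESHOLD_KM = 650.0

DEME_TABLE_COLUMNS = ("id", "lon", "lat", "island", "region", "is_source")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
            raise ValueError("coordinates out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


class DemeNetwork:
    """Demes, pairwise great-circle distances and threshold adjacency.

    Demes are indexed positionally 0..n-1 in table order; ``neighbors[i]``
    lists the demes within the threshold of deme i, sorted ascending by
    distance with ties broken by index.
    """

    def __init__(self, table: pd.DataFrame, threshold_km: float = DEFAULT_THRESHOLD_KM):
        if tuple(table.columns) != DEME_TABLE_COLUMNS:
            raise ValueError(
                f"deme table must have exactly the columns {list(DEME_TABLE_COLUMNS)}, "
                f"got {list(table.columns)}"
            )
        if len(table) < 1:
            raise ValueError("a deme network needs at least 1 deme")
        if table["id"].duplicated().any():
            raise ValueError("duplicate deme ids")
        self.table = table.reset_index(drop=True)
        self.threshold_km = float(threshold_km)
        self.ids = self.table["id"].to_numpy()
        self.lon = self.table["lon"].to_numpy(dtype=float)
        self.lat = self.table["lat"].to_numpy(dtype=float)
        self.island = self.table["island"].to_numpy()
        self.region = self.table["region"].to_numpy()
        self.is_source = self.table["is_source"].to_numpy(dtype=bool)
        self.n = len(self.table)
        self.dist = great_circle_km(
            self.lon[:, None], self.lat[:, None], self.lon[None, :], self.lat[None, :]
        )
        self.neighbors: list[np.ndarray] = []
        for i in range(self.n):
            within = np.flatnonzero((self.dist[i] <= self.threshold_km))
            within = within[within != i]
            order = np.lexsort((within, self.dist[i, within]))
            self.neighbors.append(within[order])
            if len(within) == 0 and not self.is_source[i]:
                warnings.warn(
                    f"deme {self.ids[i]!r} is isolated at threshold "
                    f"{self.threshold_km} km",
                    stacklevel=2,
                )

    @property
    def source_demes(self) -> np.ndarray:
        return np.flatnonzero(self.is_source)

    def index_of(self, deme_id) -> int:
        hits = np.flatnonzero(self.ids == deme_id)
        if len(hits) != 1:
            raise KeyError(f"unknown deme id {deme_id!r}")
        return int(hits[0])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i, nbrs in enumerate(self.neighbors):
            g.add_edges_from((i, int(j)) for j in nbrs if j > i)
        return g

    def is_connected_subset(self, demes) -> bool:
        demes = set(int(d) for d in demes)
        if not demes:
            return False
        sub = self.graph().subgraph(demes)
        return nx.is_connected(sub)


def build_network(table: pd.DataFrame, threshold_km: float = DEFAULT_THRESHOLD_KM) -> DemeNetwork:
    if len(table) < 2:
        raise ValueError("a deme network needs at least 2 demes")
    return DemeNetwork(table, threshold_km=threshold_km)


@dataclass(frozen=True)
class CapacitySchedule:
    """Carrying capacity K(t) = min(K_max, round(K0 * exp(rate * t)))."""

    k0: float = 150.0
    k_max: float = 500.0
    rate: float = np.log(2) / 4500.0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("capacity growth rate must be non-negative")
        if self.k0 <= 0 or self.k_max < self.k0:
            raise ValueError("need 0 < K0 <= K_max")

    def at(self, t: float) -> int:
        if t < 0:
            raise ValueError("t must be non-negative")
        return int(min(self.k_max, round(self.k0 * exp(self.rate * t))))


def choose_destination(
    origin: int,
    network: DemeNetwork,
    occupancy,
    capacity,
    rng,
    beta_params: tuple[float, float] = (1.0, 5.0),
    max_retries: int = 5,
) -> int | None:
    """Distance-rank destination draw.

    Candidates are the origin's neighbours sorted by distance; a draw
    v ~ Beta(a, b) selects rank floor(v * n) (clipped), so a near-biased
    Beta strongly favours close communities while its tail produces
    occasional leapfrog moves. A destination at carrying capacity is
    redrawn up to ``max_retries`` times, after which the move fails.
    """
    cands = network.neighbors[origin]
    if len(cands) == 0:
        return None
    a, b = beta_params
    n = len(cands)
    for _ in range(max_retries + 1):
        v = rng.beta(a, b)
        dest = int(cands[min(int(v * n), n - 1)])
        if occupancy[dest] < capacity[dest]:
            return dest
    return None


@dataclass(frozen=True)
class StartDistribution:
    """A founding configuration: the demes seeded with Asian ancestry."""

    id: str
    asian_demes: frozenset
    klass: str = "mainland"


def _blocks_of_four(island: str, demes) -> list[tuple[int, ...]]:
    demes = [int(d) for d in demes]
    if len(demes) % 4 != 0:
        raise ValueError(
            f"island {island!r} has {len(demes)} demes; start-distribution "
            "accretion requires blocks of four"
        )
    return [tuple(demes[k : k + 4]) for k in range(0, len(demes), 4)]


def _klass_of(touched, north_islands, west_islands) -> str:
    north = any(i in north_islands for i in touched)
    west = any(i in west_islands for i in touched)
    if north and west:
        return "north+west"
    if north:
        return "north"
    if west:
        return "west"
    return "mainland" if not touched else "expanded"


def enumerate_start_distributions(
    network: DemeNetwork,
    island_blocks: dict,
    orders,
    north_islands=(),
    west_islands=(),
) -> list[StartDistribution]:
    """Enumerate founding configurations by sequential four-deme accretion.

    ``island_blocks`` maps island label -> list of deme indices (a
    multiple of four per island); ``orders`` is a list of island-label
    sequences. For every order, islands' four-deme blocks are added
    cumulatively to the mainland base and each intermediate set is
    emitted. Sets whose Asian demes are not a connected cluster
    containing all source demes are discarded, and duplicates arising
    from different orders are merged.
    """
    blocks = {isl: _blocks_of_four(isl, demes) for isl, demes in island_blocks.items()}
    sources = frozenset(int(d) for d in network.source_demes)
    if not sources:
        raise ValueError("network has no source demes")

    seen: dict[frozenset, tuple] = {}
    seen[sources] = ((), "mainland")
    ordered_sets = [sources]
    for order in orders:
        current = set(sources)
        touched: list = []
        for isl in order:
            for block in blocks[isl]:
                current.update(block)
                if isl not in touched:
                    touched.append(isl)
                fs = frozenset(current)
                if fs in seen:
                    continue
                if not network.is_connected_subset(fs):
                    continue
                seen[fs] = (tuple(touched), _klass_of(touched, north_islands, west_islands))
                ordered_sets.append(fs)
    out = []
    for k, fs in enumerate(ordered_sets):
        _, klass = seen[fs]
        out.append(StartDistribution(id=f"D{k:03d}", asian_demes=fs, klass=klass))
    return out
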
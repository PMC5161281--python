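"""Ancestry summaries: deme and regional means, and spread rates.

The individual ancestry fraction of a marker system is the count of
Asian alleles over the alleles carried (autosomes pool both copies of
the 25 diploid markers; the X pools two copies in women and one in
men). Population ancestry is the unweighted mean of individual
fractions over a deme's occupants, and regional ancestry pools the
individuals of all demes mapped to the region (so larger demes weigh
more, exactly as merging the populations would).

The canonical summary vector used for inference interleaves, in a fixed
region order, the regional mean Asian ancestry on the autosomes and the
X chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ASIAN, FEMALE, MALE, N_AUTO_MARKERS, N_X_MARKERS, ancestry_fraction
from .geography import DemeNetwork, StartDistribution

__all__ = [
    "SYSTEMS",
    "population_ancestry",
    "agent_fractions",
    "deme_ancestry_table",
    "regional_summary_vector",
    "summary_to_frame",
    "SpreadRates",
    "spread_rates",
]

SYSTEMS = ("autosome", "x", "mt", "y")


def population_ancestry(genomes, system: str = "autosome") -> float:
    """Mean individual ancestry fraction over a collection of genomes.

    The y system averages over male carriers only. Raises on an empty
    population (the caller decides how to flag missing demes).
    """
    if system == "y":
        genomes = [g for g in genomes if g.sex == MALE]
    genomes = list(genomes)
    if not genomes:
        raise ValueError("cannot summarize an empty population")
    return float(np.mean([ancestry_fraction(g, system) for g in genomes]))


def agent_fractions(world, system: str) -> tuple[np.ndarray, np.ndarray]:
    """(indices, fractions) of all living carriers of a marker system."""
    idx = world.alive_indices()
    if system == "autosome":
        return idx, world.auto[idx].sum(axis=(1, 2)) / (2 * N_AUTO_MARKERS)
    if system == "x":
        ploidy = np.where(world.sex[idx] == FEMALE, 2, 1)
        return idx, world.x[idx].sum(axis=(1, 2)) / (N_X_MARKERS * ploidy)
    if system == "mt":
        return idx, world.mt[idx].astype(float)
    if system == "y":
        males = idx[world.sex[idx] == MALE]
        return males, world.y[males].astype(float)
    if system == "all":
        return idx, world.asian_cnt[idx] / world.tot_cnt[idx]
    raise ValueError(f"unknown marker system {system!r}")


def deme_ancestry_table(world) -> pd.DataFrame:
    """Per-deme mean Asian ancestry for every marker system.

    Returns columns (deme, system, mean_ancestry, n); empty demes (or
    demes with no males, for y) carry NaN.
    """
    nd = world.network.n
    rows = []
    for system in SYSTEMS:
        idx, frac = agent_fractions(world, system)
        counts = np.bincount(world.deme[idx], minlength=nd)
        sums = np.bincount(world.deme[idx], weights=frac, minlength=nd)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for d in range(nd):
            rows.append((world.network.ids[d], system, means[d], int(counts[d])))
    return pd.DataFrame(rows, columns=["deme", "system", "mean_ancestry", "n"])


def regional_summary_vector(
    world,
    region_of_deme: np.ndarray | None = None,
    regions: list | None = None,
    systems: tuple[str, ...] = ("autosome", "x"),
) -> pd.Series:
    """Individual-pooled regional mean ancestries, canonically ordered.

    ``region_of_deme`` defaults to the network's region labels; source
    demes (and demes labelled ``"mainland"``) are excluded from scoring.
    Returns a Series indexed by (region, system); a region with no
    occupants yields NaN with a warning and is excluded downstream.
    """
    net: DemeNetwork = world.network
    region_of_deme = net.region if region_of_deme is None else np.asarray(region_of_deme)
    scoring = ~net.is_source
    if regions is None:
        regions = sorted(set(region_of_deme[scoring]))
    values = {}
    for system in systems:
        idx, frac = agent_fractions(world, system)
        agent_region = region_of_deme[world.deme[idx]]
        agent_scoring = scoring[world.deme[idx]]
        for region in regions:
            sel = (agent_region == region) & agent_scoring
            if not sel.any():
                warnings.warn(f"region {region!r} has no occupants", stacklevel=2)
                values[(region, system)] = np.nan
            else:
                values[(region, system)] = float(frac[sel].mean())
    index = pd.MultiIndex.from_product([regions, systems], names=["region", "system"])
    return pd.Series([values[k] for k in index], index=index, name="ancestry")


def summary_to_frame(summary: pd.Series) -> pd.DataFrame:
    """Summary vector as a (region, system, ancestry) table."""
    df = summary.rename("ancestry").reset_index()
    return df[["region", "system", "ancestry"]]


@dataclass(frozen=True)
class SpreadRates:
    """Mean expansion speed, in km/year, of markers and of Asian agents."""

    marker_rate: float
    agent_rate: float
    n_marker: int
    n_agent: int
    n_unreached: int


def spread_rates(
    arrival_log: pd.DataFrame,
    network: DemeNetwork,
    start: StartDistribution | set,
    per_hop: bool = False,
    aggregate: str = "ratio",
) -> SpreadRates:
    """Expansion speed from per-deme first-arrival times.

    Each deme not founded Asian contributes its distance to the nearest
    initially Asian deme (or, with ``per_hop``, the shortest-path
    network distance) and its first-arrival time. The default
    ``"ratio"`` aggregation reports total distance over total time — the
    wavefront speed, robust to demes adjacent to the founding area whose
    tiny arrival times make the per-deme quotient explode;
    ``aggregate="deme_mean"`` reports the mean of per-deme
    distance/time quotients instead. Demes never reached are excluded
    and counted.
    """
    asian0 = sorted(
        set(int(d) for d in (start.asian_demes if isinstance(start, StartDistribution) else start))
        | set(int(d) for d in network.source_demes)
    )
    others = [d for d in range(network.n) if d not in asian0]
    if per_hop:
        import networkx as nx

        g = network.graph()
        for u, v in g.edges:
            g[u][v]["w"] = network.dist[u, v]
        lengths = nx.multi_source_dijkstra_path_length(g, asian0, weight="w")
        dist_to_source = np.array([lengths.get(d, np.inf) for d in range(network.n)])
    else:
        dist_to_source = network.dist[:, asian0].min(axis=1)

    if aggregate not in ("ratio", "deme_mean"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    log = arrival_log.set_index("deme")
    pairs = {"marker": [], "agent": []}
    unreached = 0
    for d in others:
        deme_id = network.ids[d]
        row = log.loc[deme_id]
        dist = dist_to_source[d]
        for kind, col in (("marker", "t_first_marker"), ("agent", "t_first_agent")):
            t = row[col]
            if t is None or t < 0 or not np.isfinite(dist):
                if kind == "marker":
                    unreached += 1
                continue
            pairs[kind].append((dist, max(float(t), 1.0)))

    def _agg(p):
        if not p:
            return np.nan
        d, t = np.asarray(p).T
        if aggregate == "ratio":
            return float(d.sum() / t.sum())
        return float(np.mean(d / t))

    return SpreadRates(
        marker_rate=_agg(pairs["marker"]),
        agent_rate=_agg(pairs["agent"]),
        n_marker=len(pairs["marker"]),
        n_agent=len(pairs["agent"]),
        n_unreached=unreached,
    )
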
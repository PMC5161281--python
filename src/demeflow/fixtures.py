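"""Synthetic archipelago geography and pseudo-observed reference data.

The real study system is a west-to-east chain of island groups between
mainland Asia and New Guinea, with mainland source demes at the western
end. The generator emulates that layout at configurable size: island
clusters of four coastal demes each, spaced so neighbouring clusters
stay within the 650-km movement radius (the network is connected), one
region per island, and two all-Asian source demes in the west. The
start-distribution library is enumerated by west-to-east accretion of
whole islands onto the mainland base.

Pseudo-observed data are produced by the simulator itself under known
parameters, giving ground truth for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .config import SimConfig
from .engine import ParameterSet, run_simulation
from .geography import (
    DemeNetwork,
    StartDistribution,
    build_network,
    enumerate_start_distributions,
)
from .summarize import regional_summary_vector, summary_to_frame

__all__ = [
    "Fixture",
    "generate_fixture_archipelago",
    "default_fixture",
    "generate_pseudo_observed",
    "build_reference_table",
]

KM_PER_DEG = 111.32  # at the equator


@dataclass
class Fixture:
    """A synthetic study system: geography plus founding-layout library."""

    table: pd.DataFrame
    network: DemeNetwork
    library: list[StartDistribution]

    def distribution(self, dist_id: str) -> StartDistribution:
        for d in self.library:
            if d.id == dist_id:
                return d
        raise KeyError(f"unknown start distribution {dist_id!r}")

    @property
    def regions(self) -> list:
        return sorted(set(self.network.region[~self.network.is_source]))


def generate_fixture_archipelago(
    n_islands: int = 12,
    demes_per_island: int = 4,
    seed: int = 0,
    island_spacing_deg: float = 4.2,
    island_radius_deg: float = 0.8,
    n_sources: int = 2,
    threshold_km: float = 650.0,
) -> pd.DataFrame:
    """Deme table of a west-to-east chain of island clusters.

    Geometry mimics the real region's scale: cluster centres ~470 km
    apart (so inter-island gaps stay under the movement threshold while
    intra-island demes sit 100-250 km apart) spanning several thousand
    km in total, with two mainland source demes at the western end.
    """
    if n_islands < 2:
        raise ValueError("need at least 2 islands")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sources):
        rows.append(
            {
                "id": f"SRC{s}",
                "lon": 96.0 + 0.9 * s,
                "lat": 2.0 + 1.4 * s,
                "island": "mainland",
                "region": "mainland",
                "is_source": 1,
            }
        )
    # deme offsets within an island: corners of a square plus jitter
    base_offsets = np.array([(-1, -1), (1, -1), (-1, 1), (1, 1)], dtype=float)
    for i in range(n_islands):
        cx = 100.0 + island_spacing_deg * i
        cy = 2.0 + 1.3 * (1 if i % 2 else -1)
        for k in range(demes_per_island):
            off = base_offsets[k % 4] * island_radius_deg
            jitter = rng.uniform(-0.15, 0.15, 2)
            rows.append(
                {
                    "id": f"I{i:02d}_{k}",
                    "lon": cx + off[0] + jitter[0] + (0.3 * (k // 4)),
                    "lat": cy + off[1] + jitter[1],
                    "island": f"I{i:02d}",
                    "region": f"R{i:02d}",
                    "is_source": 0,
                }
            )
    table = pd.DataFrame(rows, columns=["id", "lon", "lat", "island", "region", "is_source"])
    net = build_network(table, threshold_km=threshold_km)
    import networkx as nx

    if not nx.is_connected(net.graph()):
        raise RuntimeError("fixture archipelago is not connected; adjust spacing")
    return table


def default_fixture(
    n_islands: int = 12,
    demes_per_island: int = 4,
    seed: int = 0,
    threshold_km: float = 650.0,
    covered_fraction: float = 0.5,
    **kwargs,
) -> Fixture:
    """Archipelago plus its start-distribution library.

    The library contains the mainland-only layout and the west-to-east
    whole-island accretions over the westernmost ``covered_fraction`` of
    islands (the candidate pre-expansion Asian area).
    """
    table = generate_fixture_archipelago(
        n_islands=n_islands,
        demes_per_island=demes_per_island,
        seed=seed,
        threshold_km=threshold_km,
        **kwargs,
    )
    network = build_network(table, threshold_km=threshold_km)
    islands = [f"I{i:02d}" for i in range(n_islands)]
    blocks = {
        isl: [int(j) for j in np.flatnonzero(network.island == isl)] for isl in islands
    }
    n_cover = max(1, ceil(n_islands * covered_fraction))
    orders = [islands[:n_cover]]
    library = enumerate_start_distributions(
        network, {k: blocks[k] for k in islands[:n_cover]}, orders,
        west_islands=tuple(islands[:n_cover]),
    )
    return Fixture(table=table, network=network, library=library)


def generate_pseudo_observed(
    params: ParameterSet,
    fixture: Fixture,
    config: SimConfig,
    seed: int = 0,
    reps: int = 1,
) -> pd.DataFrame:
    """Observed-style regional ancestry table simulated at known parameters.

    Runs ``reps`` simulations and averages their regional summary
    vectors; the output schema matches the simulated summaries exactly,
    so recovery experiments can treat it as observed data.
    """
    start = fixture.distribution(params.start_distribution)
    vecs = []
    for r in range(reps):
        res = run_simulation(
            params, fixture.network, config, seed=seed + r, start=start
        )
        vecs.append(
            regional_summary_vector(res.world, regions=fixture.regions)
        )
    mean_vec = pd.concat(vecs, axis=1).mean(axis=1).rename("ancestry")
    return summary_to_frame(mean_vec)


def build_reference_table(
    n_sims: int,
    fixture: Fixture,
    config: SimConfig,
    seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Reference table of prior draws and their summary vectors.

    One row per completed simulation: the six parameters, the run seed,
    and one ``s__<region>__<system>`` column per summary statistic. Run
    seeds derive from the master seed by a counter, so the table is
    reproducible and extendable.
    """
    from .abc_infer import sample_prior

    rng = np.random.default_rng(seed)
    dist_ids = [d.id for d in fixture.library]
    priors = sample_prior(n_sims, rng, distribution_ids=dist_ids)
    regions = fixture.regions
    rows = []
    for i in range(n_sims):
        p = ParameterSet(**priors.iloc[i].to_dict())
        run_seed = seed * 1_000_003 % (2**31) + i + 1
        res = run_simulation(
            p, fixture.network, config, seed=run_seed,
            start=fixture.distribution(p.start_distribution),
        )
        vec = regional_summary_vector(res.world, regions=regions)
        row = priors.iloc[i].to_dict()
        row["seed"] = run_seed
        for (region, system), v in vec.items():
            row[f"s__{region}__{system}"] = v
        rows.append(row)
        if progress and (i + 1) % 100 == 0:
            print(f"  {i + 1}/{n_sims} simulations done")
    return pd.DataFrame(rows)
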
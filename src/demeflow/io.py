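"""CSV/JSON serialization with strict schemas.

All tabular artifacts are plain CSV with exact, validated column sets
(unknown or missing columns fail loudly), so simulated and observed
data are interchangeable and files round-trip bit-exactly. Run metadata
(parameters, seed, configuration hash, package version) is JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .engine import ParameterSet
from .geography import DEME_TABLE_COLUMNS, StartDistribution

__all__ = [
    "read_deme_table",
    "write_deme_table",
    "read_start_distributions",
    "write_start_distributions",
    "read_summary_table",
    "write_summary_table",
    "read_reference_table",
    "write_reference_table",
    "write_metadata",
]

SUMMARY_COLUMNS = ("region", "system", "ancestry")
DISTRIBUTION_COLUMNS = ("distribution_id", "deme_id", "class")


def _check_columns(df: pd.DataFrame, expected, path):
    if tuple(df.columns) != tuple(expected):
        raise ValueError(
            f"{path}: expected exactly the columns {list(expected)}, "
            f"got {list(df.columns)}"
        )


def read_deme_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DEME_TABLE_COLUMNS, path)
    bad = df.index[df["is_source"].isin((0, 1)) == False]  # noqa: E712
    if len(bad):
        raise ValueError(f"{path}: line {bad[0] + 2}: is_source must be 0 or 1")
    return df


def write_deme_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, DEME_TABLE_COLUMNS, path)
    df.to_csv(path, index=False)


def write_start_distributions(library, network, path) -> None:
    rows = [
        {"distribution_id": d.id, "deme_id": network.ids[deme], "class": d.klass}
        for d in library
        for deme in sorted(d.asian_demes)
    ]
    pd.DataFrame(rows, columns=DISTRIBUTION_COLUMNS).to_csv(path, index=False)


def read_start_distributions(path, network) -> list[StartDistribution]:
    df = pd.read_csv(path)
    _check_columns(df, DISTRIBUTION_COLUMNS, path)
    out = []
    for dist_id, grp in df.groupby("distribution_id", sort=False):
        demes = frozenset(network.index_of(i) for i in grp["deme_id"])
        out.append(
            StartDistribution(
                id=str(dist_id), asian_demes=demes, klass=str(grp["class"].iloc[0])
            )
        )
    return out


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SUMMARY_COLUMNS, path)
    return df


def write_summary_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, SUMMARY_COLUMNS, path)
    df.to_csv(path, index=False)


def summary_frame_to_vector(df: pd.DataFrame, regions, systems=("autosome", "x")):
    """Align a (region, system, ancestry) table to the canonical order."""
    idx = pd.MultiIndex.from_product([regions, systems], names=["region", "system"])
    ser = df.set_index(["region", "system"])["ancestry"]
    return ser.reindex(idx).to_numpy(dtype=float)


def write_reference_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_reference_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"m_a", "m_p", "f_a", "f_p", "marriage_weight", "start_distribution", "seed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reference table missing columns {sorted(missing)}")
    unknown = [
        c for c in df.columns if c not in required and not c.startswith("s__")
    ]
    if unknown:
        raise ValueError(f"{path}: unknown reference-table columns {unknown}")
    return df


def summary_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("s__")]


def write_metadata(path, params: ParameterSet | None, seed, config_digest, extra=None):
    payload = {
        "package": "demeflow",
        "version": __version__,
        "seed": seed,
        "config_digest": config_digest,
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
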
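"""Run configuration for the simulation engine."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .demography import (
    DEFAULT_AGE_CLASSES,
    AgeClassSpec,
    FertilitySchedule,
    MortalitySchedule,
    build_fertility_schedule,
    build_mortality_schedule,
)
from .genome import DEFAULT_X_MAP_LENGTH
from .geography import CapacitySchedule

__all__ = ["SimConfig", "scaled_config"]


@dataclass(frozen=True, eq=False)
class SimConfig:
    """All fixed (non-inferred) parameters of one simulation run.

    Defaults reproduce the full-scale study conditions: a 4500-year run
    with demes founded at 120 individuals, carrying capacity starting at
    150 and doubling exponentially over the run (capped at 500), a
    near-biased Beta(1, 5) dispersal-rank kernel within a 650-km
    movement radius, maturity at 18, a +/-6-year spousal age window and
    a 0.9 annual probability that an eligible unmarried adult attempts
    marriage rather than staying single.
    """

    steps: int = 4500
    founding_size: int = 120
    source_size: int = 120
    capacity: CapacitySchedule = field(default_factory=CapacitySchedule)
    beta_params: tuple[float, float] = (1.0, 5.0)
    x_map_length: float = DEFAULT_X_MAP_LENGTH
    p_marry: float = 0.9
    move_retries: int = 5
    maturity_age: int = 18
    max_age_gap: int = 6
    mortality: MortalitySchedule = field(default_factory=build_mortality_schedule)
    fertility: FertilitySchedule = field(default_factory=build_fertility_schedule)
    age_classes: AgeClassSpec = DEFAULT_AGE_CLASSES
    track_age_structure: bool = False
    track_demography: bool = False
    snapshot_every: int = 0  # 0 disables per-step deme snapshots

    def digest(self) -> str:
        """Stable hash of the configuration (for output metadata)."""
        payload: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (MortalitySchedule,)):
                v = v.hazard.tolist()
            elif isinstance(v, FertilitySchedule):
                v = v.rate.tolist()
            elif isinstance(v, CapacitySchedule):
                v = [v.k0, v.k_max, v.rate]
            elif isinstance(v, AgeClassSpec):
                v = [list(map(list, v.brackets)), list(v.proportions)]
            elif isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            payload[f.name] = v
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def scaled_config(pop_scale: float = 1.0, steps: int = 4500, **overrides) -> SimConfig:
    """A configuration with all population sizes scaled by ``pop_scale``.

    Used for reduced-scale experiments: founding size, source size and
    the carrying-capacity schedule shrink together so that the relative
    demography (growth headroom, capacity pressure) is preserved.
    """
    base = CapacitySchedule()
    cap = CapacitySchedule(
        k0=max(10.0, round(base.k0 * pop_scale)),
        k_max=max(10.0, round(base.k_max * pop_scale)),
        rate=np.log(2) / steps,
    )
    kwargs = dict(
        steps=steps,
        founding_size=max(8, round(120 * pop_scale)),
        source_size=max(8, round(120 * pop_scale)),
        capacity=cap,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
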
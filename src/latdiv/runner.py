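"""Replicate orchestration and trajectory aggregation.

Replicate ``k`` of a set with base seed ``s`` runs with seed
``(s + k) mod 2**31`` — a plain counter scheme, so any single replicate can
be reproduced in isolation from the base seed and its index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .simulate import SimulationResult, run_simulation

__all__ = ["ReplicateSet", "replicate_seed", "run_replicates", "aggregate_trajectories"]

_SCALARS = ("total_richness", "r_lat_rich", "r_time_rich", "mrd_slope", "beta")


def replicate_seed(base_seed: int, k: int) -> int:
    return (int(base_seed) + int(k)) % 2**31


@dataclass
class ReplicateSet:
    """Results and aggregate metric trajectories for n independent runs."""

    config: ScenarioConfig
    base_seed: int
    seeds: list[int]
    results: list[SimulationResult]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_completed(self) -> int:
        return len(self.results)

    def aggregate(self) -> pd.DataFrame:
        return aggregate_trajectories(self.results)


def run_replicates(
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    *,
    compute_metrics: bool = True,
) -> ReplicateSet:
    """Run ``n_replicates`` independent copies of one scenario.

    A replicate that raises is recorded as a failure and aggregation
    proceeds over the completed ones.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [replicate_seed(base_seed, k) for k in range(n_replicates)]
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds collide; use a smaller base seed")
    results, failures = [], []
    for k, seed in enumerate(seeds):
        try:
            results.append(
                run_simulation(config.with_seed(seed), compute_metrics=compute_metrics)
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            failures.append((k, f"{type(exc).__name__}: {exc}"))
    return ReplicateSet(
        config=config, base_seed=base_seed, seeds=seeds, results=results, failures=failures
    )


def aggregate_trajectories(results: list[SimulationResult]) -> pd.DataFrame:
    """Mean/min/max of each scalar metric per snapshot time, across runs.

    Aggregation aligns on the common snapshot grid; times reached by only a
    subset of replicates (early stops) aggregate over that subset.
    """
    if not results:
        raise ValueError("no completed replicates to aggregate")
    frames = []
    for j, res in enumerate(results):
        df = res.snapshots_dataframe()[["time", *_SCALARS]].copy()
        df["replicate"] = j
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    agg = long.groupby("time").agg(
        n_replicates=("replicate", "size"),
        **{
            f"{m}_{stat}": (m, stat)
            for m in _SCALARS
            for stat in ("mean", "min", "max")
        },
    )
    return agg.reset_index()
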
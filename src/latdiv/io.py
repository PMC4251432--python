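"""Run-directory output: CSV tables, Newick tree, config echo, log."""

from __future__ import annotations

import time as _time
from pathlib import Path

import pandas as pd

from . import metrics as _metrics
from . import phylo
from .config import save_config
from .simulate import SimulationResult

__all__ = ["write_run_dir", "read_occupancy"]

OCCUPANCY_COLUMNS = ("species_id", "region", "population", "colonization_time")


def write_run_dir(result: SimulationResult, out_dir) -> Path:
    """Write a completed run to ``out_dir``.

    Files: ``species.csv``, ``occupancy.csv`` (long format), ``events.csv``,
    ``metrics.csv`` (one row per snapshot), ``phylogeny_extant.nwk`` (absent
    when fewer than two species survive), ``config.used.yaml`` and
    ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.species.to_csv(out / "species.csv", index=False)
    result.occupancy.to_csv(out / "occupancy.csv", index=False)
    result.events.to_csv(out / "events.csv", index=False)
    result.snapshots_dataframe().to_csv(out / "metrics.csv", index=False)
    save_config(result.config.with_seed(result.seed_used), out / "config.used.yaml")
    try:
        tree = phylo.extant_tree(result.species, result.final_time)
        (out / "phylogeny_extant.nwk").write_text(phylo.to_newick(tree) + "\n")
    except phylo.PhyloError:
        tree = None
    lines = [
        f"# run completed (wall clock {_time.strftime('%Y-%m-%dT%H:%M:%S')})",
        f"seed_used={result.seed_used}",
        f"final_time={result.final_time}",
        f"extant_richness={len(result.occupancy['species_id'].unique())}",
        f"clade_extinct={result.clade_extinct}",
        f"events_logged={len(result.events)}",
    ]
    for snap in result.snapshots:
        lines.append(
            f"t={snap.time} richness={int(snap.richness.sum())} r_lat_rich={snap.r_lat_rich:.4f}"
        )
    (out / "run.log").write_text("\n".join(lines) + "\n")
    return out


def read_occupancy(path) -> pd.DataFrame:
    """Read and validate a long-format occupancy table."""
    df = pd.read_csv(path)
    missing = [c for c in OCCUPANCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: occupancy table is missing columns {missing}")
    return df
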